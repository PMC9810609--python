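"""Normalized crossover landscapes, hotspot activity, and section statistics.

Breakpoint calls only localize each crossover to a bracketing marker pair,
and raw call counts are not comparable across cohorts of different size.
Both problems are handled by normalizing to the seed-scored genetic length
of the interval: each OK call carries genetic mass total_cM / n_ok, spread
uniformly over its bracketing interval when binning (so the landscape
respects mapping resolution), while hotspot and section membership use the
breakpoint midpoint (a single decision per call).  The resulting landscape
integrates exactly to total_cM.

Hotspot activity is the fraction of crossovers falling in the hotspot,
converted to cM/Mb with the hotspot's physical length.  Section comparison
between two cohorts (e.g. wild type vs a mismatch-repair mutant) relates
per-section relative activity (mutant / wild type, both in cM/Mb) to local
polymorphism density via Spearman rank correlation with a two-sided p-value
from the t approximation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .crossovers import CohortResult
from .errors import InputError, QCError
from .genotyping import MarkerTable, SNP
from .regions import IntervalSpec, RegionSet

log = logging.getLogger(__name__)


@dataclass
class Landscape:
    """Binned crossover rate (cM/Mb) over an interval."""

    interval: IntervalSpec
    bin_edges: np.ndarray  # length n_bins + 1, absolute coordinates
    values: np.ndarray  # cM/Mb per bin
    total_cm: float
    n_co: int

    @property
    def bin_widths_bp(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    def integral_cm(self) -> float:
        return float(np.sum(self.values * self.bin_widths_bp / 1e6))


def build_landscape(
    calls: CohortResult,
    interval: IntervalSpec,
    total_cm: float,
    bin_width: int = 200,
) -> Landscape:
    """Accumulate OK calls into fixed-width bins normalized to total_cM.

    Each OK call contributes total_cM / n_ok, spread uniformly over its
    bracketing marker interval; bin values are in cM/Mb.  The last bin is
    truncated at the interval end, so the landscape integrates to total_cM
    by construction.
    """
    if total_cm <= 0:
        raise InputError("total_cm must be positive")
    if bin_width < 1:
        raise InputError("bin_width must be >= 1")
    ok = calls.ok_calls
    if not ok:
        raise QCError("no OK crossover calls to build a landscape from")

    edges = np.arange(interval.start, interval.end, bin_width, dtype=float)
    edges = np.append(edges, float(interval.end))
    widths = np.diff(edges)
    mass = np.zeros(len(widths))
    per_call = total_cm / len(ok)
    for c in ok:
        lo, hi = float(c.left_pos), float(c.right_pos)
        lo = max(lo, float(interval.start))
        hi = min(hi, float(interval.end))
        if hi <= lo:
            raise InputError(f"call {c.sample_id!r}: degenerate bracketing interval")
        overlap = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)
        mass += per_call * overlap / (hi - lo)
    values = mass / (widths / 1e6)
    return Landscape(interval, edges, values, total_cm, len(ok))


def hotspot_activity(calls: CohortResult, hotspots: RegionSet, total_cm: float) -> pd.DataFrame:
    """Per-hotspot crossover share and normalized activity.

    share = fraction of OK breakpoint midpoints inside the hotspot;
    activity = share x total_cM / hotspot length (Mb).
    """
    if total_cm <= 0:
        raise InputError("total_cm must be positive")
    ok = calls.ok_calls
    n_ok = len(ok)
    mids = np.array([c.midpoint for c in ok], dtype=float)
    rows = []
    for h in hotspots:
        inside = int(((mids >= h.start) & (mids < h.end)).sum()) if n_ok else 0
        share = inside / n_ok if n_ok else 0.0
        rows.append(
            {
                "name": h.name,
                "start": h.start,
                "end": h.end,
                "n_co": inside,
                "share": share,
                "cm_per_mb": share * total_cm / h.length_mb,
            }
        )
    return pd.DataFrame(rows)


def polymorphism_density(markers: MarkerTable, region: IntervalSpec, snps_only: bool = False) -> float:
    """Markers per kilobase inside a region (SNPs + InDels by default)."""
    if region.length_bp <= 0:
        raise InputError("zero-length region")
    pos = markers.positions
    sel = (pos >= region.start) & (pos < region.end)
    if snps_only:
        sel &= markers.kinds == SNP
    return float(sel.sum()) / (region.length_bp / 1000.0)


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho via the t approximation with n-2 df."""
    if n < 3:
        raise InputError("spearman p-value requires n >= 3")
    if abs(rho) >= 1.0:
        return 0.0
    t = abs(rho) * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(min(1.0, 2.0 * stats.t.sf(t, n - 2)))


def spearman_t(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties and a t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise InputError("spearman_t requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("spearman_t is undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(abs(rho) - 1.0) < 1e-12:  # snap floating-point |rho| ~ 1 of perfect rankings
        rho = math.copysign(1.0, rho)
    return rho, spearman_pvalue(rho, n)


@dataclass
class SectionStats:
    name: str
    start: int
    end: int
    density_per_kb: float
    wt_n_co: int
    mut_n_co: int
    wt_cm_per_mb: float
    mut_cm_per_mb: float
    relative_activity: float | None
    excluded: bool
    reason: str = ""


def section_compare(
    wt: CohortResult,
    wt_total_cm: float,
    mut: CohortResult,
    mut_total_cm: float,
    sections: RegionSet,
    markers: MarkerTable,
    interval: IntervalSpec | None = None,
    snps_only: bool = False,
) -> tuple[pd.DataFrame, float, float]:
    """Compare per-section crossover activity between two cohorts.

    Sections must tile the analysis interval.  Each cohort's activity per
    section comes from its own normalized landscape (cM/Mb); sections with
    zero crossovers in either cohort are excluded.  Returns the per-section
    table plus the Spearman rho and two-sided p between polymorphism density
    and relative activity (mutant / wild type) over retained sections.
    """
    iv = interval or markers.interval
    sections.require_tiling(iv)

    wt_act = hotspot_activity(wt, sections, wt_total_cm).set_index("name")
    mut_act = hotspot_activity(mut, sections, mut_total_cm).set_index("name")

    rows: list[SectionStats] = []
    for s in sections:
        w = wt_act.loc[s.name]
        m = mut_act.loc[s.name]
        density = polymorphism_density(markers, s, snps_only=snps_only)
        excluded = w.n_co == 0 or m.n_co == 0
        reason = "no crossovers in wild type and/or mutant" if excluded else ""
        rows.append(
            SectionStats(
                name=s.name,
                start=s.start,
                end=s.end,
                density_per_kb=density,
                wt_n_co=int(w.n_co),
                mut_n_co=int(m.n_co),
                wt_cm_per_mb=float(w.cm_per_mb),
                mut_cm_per_mb=float(m.cm_per_mb),
                relative_activity=None if excluded else float(m.cm_per_mb / w.cm_per_mb),
                excluded=excluded,
                reason=reason,
            )
        )
    table = pd.DataFrame([vars(r) for r in rows])
    retained = table[~table.excluded]
    if len(retained) < 3:
        raise QCError(f"insufficient sections: only {len(retained)} with crossovers in both cohorts")
    log.info("section_compare: %d/%d sections retained", len(retained), len(table))
    rho, p = spearman_t(retained.density_per_kb.to_numpy(), retained.relative_activity.to_numpy())
    return table, rho, p


def heterozygosity_percent(het_blocks, genome_size_bp: int = 125_000_000) -> float:
    """Percent of the genome covered by heterozygous blocks.

    ``het_blocks`` is an iterable of (chrom, start, end) tuples, 0-based
    half-open and non-overlapping within each chromosome; the genome size
    defaults to the 125 Mb Arabidopsis estimate.
    """
    if genome_size_bp <= 0:
        raise InputError("genome size must be positive")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    total = 0
    for chrom, start, end in het_blocks:
        if end <= start:
            raise InputError(f"block {chrom}:{start}-{end}: end must exceed start")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        total += end - start
    for chrom, blocks in by_chrom.items():
        blocks.sort()
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise InputError(f"overlapping blocks on {chrom}: {s1}-{e1} and {s2}-{e2}")
    return 100.0 * total / genome_size_bp
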