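"""Marker tables, allele counts, and genotype calling.

Genotypes at each polymorphic marker are inferred from the fraction of reads
supporting the reference allele.  Recombinant samples from the fluorescent
selection are expected to be heterozygous on one side of the crossover and
homozygous on the other, so only three informative states exist (plus
NOCALL). Markers with low cohort-level coverage are removed before calling,
mirroring the <30-read coverage filter applied to amplicon sequencing data,
and genotyping uses SNPs only — InDels are retained for polymorphism-density
calculations but excluded from the crossover topology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, QCError
from .regions import IntervalSpec

log = logging.getLogger(__name__)

# genotype state codes (TSV representation: 0, 1, 2, '.')
HOM_REF = 0
HET = 1
HOM_ALT = 2
NOCALL = -1

STATE_NAMES = {HOM_REF: "HOM_REF", HET: "HET", HOM_ALT: "HOM_ALT", NOCALL: "NOCALL"}

SNP = "SNP"
INDEL = "InDel"


@dataclass(frozen=True)
class Marker:
    chrom: str
    pos: int  # 0-based internally; 1-based in VCF I/O
    ref: str
    alt: str
    kind: str = SNP

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise InputError(f"marker at {self.chrom}:{self.pos}: ref equals alt ({self.ref})")
        if self.kind not in (SNP, INDEL):
            raise InputError(f"unknown marker kind {self.kind!r}")


@dataclass(frozen=True)
class MarkerTable:
    """Ordered polymorphic sites distinguishing the two parental accessions."""

    interval: IntervalSpec
    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        pos = self.positions
        if len(pos) and (np.diff(pos) <= 0).any():
            raise InputError("marker positions must be strictly increasing and unique")
        for m in self.markers:
            if not self.interval.contains(m.pos):
                raise InputError(
                    f"marker at {m.chrom}:{m.pos} outside interval "
                    f"{self.interval.name!r} ({self.interval.start}-{self.interval.end})"
                )

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.markers], dtype=np.int64)

    @property
    def kinds(self) -> np.ndarray:
        return np.array([m.kind for m in self.markers])

    def __len__(self) -> int:
        return len(self.markers)

    def subset(self, mask: np.ndarray) -> "MarkerTable":
        kept = tuple(m for m, keep in zip(self.markers, mask) if keep)
        return MarkerTable(self.interval, kept)


@dataclass
class AlleleCounts:
    """Samples x markers matrix of (ref_count, alt_count)."""

    samples: list[str]
    markers: MarkerTable
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.samples), len(self.markers))
        for name, arr in (("ref", self.ref), ("alt", self.alt)):
            if arr.shape != expected:
                raise InputError(f"{name} count matrix shape {arr.shape} != {expected}")
            if (arr < 0).any():
                raise InputError(f"negative {name} counts")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt

    def subset_markers(self, mask: np.ndarray) -> "AlleleCounts":
        return AlleleCounts(self.samples, self.markers.subset(mask), self.ref[:, mask], self.alt[:, mask])


@dataclass(frozen=True)
class GenotypeThresholds:
    """Allele-fraction bands for genotype determination.

    Defaults: depth < ``min_depth`` is a NOCALL; reference-read fraction
    >= 0.9 is homozygous reference, <= 0.1 homozygous alternate, within
    [0.3, 0.7] heterozygous; anything in the ambiguous gaps is a NOCALL.
    Bands are deliberately conservative at the 30x floor while being
    essentially unambiguous at the ~1500x depth typical of amplicon data.
    """

    min_depth: int = 30
    hom_ref_min: float = 0.9
    hom_alt_max: float = 0.1
    het_low: float = 0.3
    het_high: float = 0.7

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise InputError("min_depth must be >= 1")
        if not (0 <= self.hom_alt_max < self.het_low <= self.het_high < self.hom_ref_min <= 1):
            raise InputError("genotype fraction bands must satisfy hom_alt_max < het_low <= het_high < hom_ref_min")


DEFAULT_THRESHOLDS = GenotypeThresholds()


def call_genotype(ref_count: int, alt_count: int, thresholds: GenotypeThresholds = DEFAULT_THRESHOLDS) -> int:
    """Call a single marker genotype from reference/alternate read counts."""
    if ref_count < 0 or alt_count < 0:
        raise InputError("negative read counts")
    g = call_genotypes(np.array([ref_count]), np.array([alt_count]), thresholds)
    return int(g[0])


def call_genotypes(ref: np.ndarray, alt: np.ndarray, thresholds: GenotypeThresholds = DEFAULT_THRESHOLDS) -> np.ndarray:
    """Vectorized genotype calling; shapes of ``ref`` and ``alt`` must match."""
    if (ref < 0).any() or (alt < 0).any():
        raise InputError("negative read counts")
    depth = ref + alt
    out = np.full(ref.shape, NOCALL, dtype=np.int8)
    ok = depth >= thresholds.min_depth
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(depth > 0, ref / np.maximum(depth, 1), np.nan)
    out[ok & (f >= thresholds.hom_ref_min)] = HOM_REF
    out[ok & (f <= thresholds.hom_alt_max)] = HOM_ALT
    out[ok & (f >= thresholds.het_low) & (f <= thresholds.het_high)] = HET
    return out


def filter_markers(
    counts: AlleleCounts,
    min_depth: int = 30,
    max_fraction_nocall: float = 0.2,
    thresholds: GenotypeThresholds | None = None,
) -> tuple[AlleleCounts, pd.DataFrame]:
    """Drop markers with low cohort coverage or a high NOCALL rate.

    A marker is removed when its median depth across samples falls below
    ``min_depth``, or when more than ``max_fraction_nocall`` of the samples
    yield NOCALL at it. Returns the filtered counts and a report listing
    every dropped marker with the reason.
    """
    if min_depth < 1:
        raise InputError("min_depth must be >= 1")
    if len(counts.samples) == 0 or len(counts.markers) == 0:
        raise InputError("empty allele-count matrix")
    thr = thresholds or GenotypeThresholds(min_depth=min_depth)
    depth = counts.depth
    median_depth = np.median(depth, axis=0)
    geno = call_genotypes(counts.ref, counts.alt, thr)
    nocall_rate = (geno == NOCALL).mean(axis=0)

    low_cov = median_depth < min_depth
    noisy = nocall_rate > max_fraction_nocall
    drop = low_cov | noisy

    rows = []
    for j in np.flatnonzero(drop):
        reasons = []
        if low_cov[j]:
            reasons.append(f"median depth {median_depth[j]:.0f} < {min_depth}")
        if noisy[j]:
            reasons.append(f"NOCALL rate {nocall_rate[j]:.2f} > {max_fraction_nocall}")
        m = counts.markers.markers[j]
        rows.append({"chrom": m.chrom, "pos": m.pos, "kind": m.kind, "reason": "; ".join(reasons)})
    report = pd.DataFrame(rows, columns=["chrom", "pos", "kind", "reason"])

    if drop.all():
        raise QCError("no informative markers: all markers failed coverage/quality filters")
    kept = counts.subset_markers(~drop)
    if len(rows):
        log.info("filter_markers: dropped %d of %d markers", len(rows), len(counts.markers))
    return kept, report


def thin_markers(markers: MarkerTable, min_spacing_bp: int) -> MarkerTable:
    """Greedy left-to-right thinning to a minimum inter-marker spacing.

    The first SNP is always kept; each subsequent SNP is kept only if it lies
    at least ``min_spacing_bp`` downstream of the last kept SNP. InDel markers
    are excluded from the genotyping set (they remain available in the
    original table for density calculations).
    """
    if min_spacing_bp < 0:
        raise InputError("min_spacing_bp must be >= 0")
    kept: list[bool] = []
    last = None
    for m in markers.markers:
        if m.kind != SNP:
            kept.append(False)
            continue
        if last is None or m.pos - last >= min_spacing_bp:
            kept.append(True)
            last = m.pos
        else:
            kept.append(False)
    return markers.subset(np.array(kept, dtype=bool))


def genotype_matrix(
    counts: AlleleCounts, thresholds: GenotypeThresholds = DEFAULT_THRESHOLDS
) -> tuple[np.ndarray, pd.DataFrame]:
    """Elementwise genotype calls plus a per-sample NOCALL summary.

    Returns an int8 matrix (samples x markers) of state codes and a DataFrame
    with each sample's NOCALL fraction; samples that are entirely NOCALL are
    flagged.
    """
    if len(counts.samples) == 0 or len(counts.markers) == 0:
        raise InputError("empty allele-count matrix")
    geno = call_genotypes(counts.ref, counts.alt, thresholds)
    nocall_frac = (geno == NOCALL).mean(axis=1)
    summary = pd.DataFrame(
        {
            "sample": counts.samples,
            "nocall_fraction": nocall_frac,
            "all_nocall": nocall_frac == 1.0,
        }
    )
    for s in summary.loc[summary.all_nocall, "sample"]:
        log.warning("sample %s has no callable markers", s)
    return geno, summary
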