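"""Readers and writers for the pipeline's file formats.

Conventions: marker tables travel as VCF (1-based positions), intervals,
hotspots and sections as BED (0-based half-open), landscapes as bedGraph,
everything else as tab-separated tables with a header row and ``#`` comment
lines.  All coordinates are converted to the internal 0-based half-open
convention at this boundary.  Every file written here carries a comment
header with the tool version and, when available, the configuration hash,
so outputs are traceable and byte-identical across re-runs.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .crossovers import OK, STATUSES, CohortResult, CrossoverCall
from .errors import InputError
from .genotyping import HET, HOM_ALT, HOM_REF, INDEL, NOCALL, SNP, AlleleCounts, Marker, MarkerTable
from .landscape import Landscape
from .regions import IntervalSpec, RegionSet
from .seeds import SeedCounts

GT_TO_CHAR = {HOM_REF: "0", HET: "1", HOM_ALT: "2", NOCALL: "."}
CHAR_TO_GT = {v: k for k, v in GT_TO_CHAR.items()}


def header_comments(config_hash: str | None = None) -> list[str]:
    lines = [f"seedtyper v{__version__}"]
    if config_hash:
        lines.append(f"config={config_hash}")
    return lines


def _write_commented(path, comments: list[str], body: str) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write(body)


# ---------------------------------------------------------------------------
# VCF marker tables


def write_markers_vcf(markers: MarkerTable, path, config_hash: str | None = None) -> None:
    iv = markers.interval
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##seedtyper_version={__version__}\n")
        if config_hash:
            fh.write(f"##seedtyper_config={config_hash}\n")
        fh.write(f"##contig=<ID={iv.chrom},length={iv.end}>\n")
        fh.write(f"##seedtyper_interval={iv.name}:{iv.start}-{iv.end}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for m in markers.markers:
            fh.write(f"{m.chrom}\t{m.pos + 1}\t.\t{m.ref}\t{m.alt}\t.\t.\t.\n")


def read_markers_vcf(path, interval: IntervalSpec | None = None) -> MarkerTable:
    """Load a minimal marker VCF (CHROM/POS/REF/ALT); POS converted to 0-based.

    Marker kind is inferred from allele lengths (equal single-base alleles
    are SNPs, anything else an InDel).  The analysis interval is taken from
    the ``##seedtyper_interval`` header or the contig length unless given
    explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"markers VCF not found: {path}")
    vcf = VCF(str(path))
    markers: list[Marker] = []
    chrom = None
    for i, rec in enumerate(vcf, start=1):
        if not rec.ALT:
            raise InputError(f"{path}: record {i}: missing ALT allele")
        chrom = rec.CHROM
        ref, alt = rec.REF, rec.ALT[0]
        kind = SNP if len(ref) == 1 and len(alt) == 1 else INDEL
        markers.append(Marker(chrom, rec.POS - 1, ref, alt, kind))
    if interval is None:
        interval = _interval_from_vcf_header(vcf, chrom, markers, path)
    vcf.close()
    if not markers:
        raise InputError(f"{path}: no marker records")
    return MarkerTable(interval, tuple(markers))


def _interval_from_vcf_header(vcf, chrom, markers, path) -> IntervalSpec:
    for line in vcf.raw_header.splitlines():
        if line.startswith("##seedtyper_interval="):
            spec = line.split("=", 1)[1]
            name, rng = spec.split(":")
            start, end = (int(x) for x in rng.split("-"))
            return IntervalSpec(name, chrom, start, end)
    try:
        length = dict(zip(vcf.seqnames, vcf.seqlens))[chrom]
        return IntervalSpec(chrom, chrom, 0, int(length))
    except Exception:
        if not markers:
            raise InputError(f"{path}: cannot infer interval (no contig header, no records)")
        return IntervalSpec(chrom, chrom, 0, max(m.pos for m in markers) + 1)


# ---------------------------------------------------------------------------
# BED regions


def read_bed(path) -> list[IntervalSpec]:
    """Read named BED intervals (chrom, start, end[, name]); 0-based half-open."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"BED file not found: {path}")
    out: list[IntervalSpec] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer coordinates")
            if end <= start:
                raise InputError(f"{path}:{lineno}: end ({end}) must exceed start ({start})")
            name = fields[3] if len(fields) > 3 else f"region_{lineno}"
            out.append(IntervalSpec(name, chrom, start, end))
    if not out:
        raise InputError(f"{path}: no BED records")
    return out


def read_region_set(path) -> RegionSet:
    return RegionSet(tuple(read_bed(path)))


def write_bed(regions, path, comments: list[str] | None = None) -> None:
    body = "".join(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n" for r in regions)
    _write_commented(path, comments or header_comments(), body)


# ---------------------------------------------------------------------------
# Allele-count tables


def write_counts_tsv(counts: AlleleCounts, path, comments: list[str] | None = None) -> None:
    """Long-format TSV: sample, chrom, pos (1-based), ref_count, alt_count."""
    buf = _io.StringIO()
    buf.write("sample\tchrom\tpos\tref_count\talt_count\n")
    positions = counts.markers.positions
    chroms = [m.chrom for m in counts.markers.markers]
    for i, s in enumerate(counts.samples):
        for j in range(len(positions)):
            buf.write(f"{s}\t{chroms[j]}\t{positions[j] + 1}\t{counts.ref[i, j]}\t{counts.alt[i, j]}\n")
    _write_commented(path, comments or header_comments(), buf.getvalue())


def read_counts_tsv(path, markers: MarkerTable) -> AlleleCounts:
    """Load per-sample, per-marker read counts and align them to a marker table."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"counts TSV not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "chrom", "pos", "ref_count", "alt_count"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    df["pos0"] = df["pos"].astype(int) - 1
    positions = markers.positions
    pos_index = {int(p): j for j, p in enumerate(positions)}
    unknown = set(df.pos0) - set(pos_index)
    if unknown:
        raise InputError(f"{path}: positions not in marker table (1-based): {sorted(p + 1 for p in unknown)[:5]} ...")
    samples = list(dict.fromkeys(df["sample"]))
    s_index = {s: i for i, s in enumerate(samples)}
    ref = np.zeros((len(samples), len(positions)), dtype=np.int64)
    alt = np.zeros_like(ref)
    seen = np.zeros(ref.shape, dtype=bool)
    for row in df.itertuples(index=False):
        i, j = s_index[row.sample], pos_index[int(row.pos0)]
        ref[i, j] = row.ref_count
        alt[i, j] = row.alt_count
        seen[i, j] = True
    if not seen.all():
        missing = int((~seen).sum())
        raise InputError(f"{path}: {missing} sample/marker pairs missing from the table")
    return AlleleCounts(samples, markers, ref, alt)


# ---------------------------------------------------------------------------
# Seed-count tables


def write_seeds_tsv(seed_counts: list[SeedCounts], path, comments: list[str] | None = None) -> None:
    body = "plant_id\tgroup\tN_G\tN_R\tN_T\n" + "".join(
        f"{c.plant_id}\t{c.group}\t{c.n_green}\t{c.n_red}\t{c.n_total}\n" for c in seed_counts
    )
    _write_commented(path, comments or header_comments(), body)


def read_seeds_tsv(path) -> list[SeedCounts]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"seeds TSV not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"plant_id", "group", "N_G", "N_R", "N_T"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    out = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(SeedCounts(str(row.plant_id), str(row.group), int(row.N_G), int(row.N_R), int(row.N_T)))
        except (ValueError, InputError) as e:
            raise InputError(f"{path}: record {idx}: {e}")
    return out


# ---------------------------------------------------------------------------
# Genotype matrices


def write_genotypes_tsv(geno: np.ndarray, samples: list[str], markers: MarkerTable, path, comments=None) -> None:
    """Wide TSV: one row per sample, one column per marker (1-based position)."""
    cols = "\t".join(str(p + 1) for p in markers.positions)
    buf = [f"sample\t{cols}\n"]
    for i, s in enumerate(samples):
        states = "\t".join(GT_TO_CHAR[int(g)] for g in geno[i])
        buf.append(f"{s}\t{states}\n")
    _write_commented(path, comments or header_comments(), "".join(buf))


def read_genotypes_tsv(path, markers: MarkerTable) -> tuple[np.ndarray, list[str], MarkerTable]:
    """Load a genotype matrix; columns may be a (thinned) subset of the markers.

    Returns (matrix, sample ids, marker table restricted to the file's columns).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"genotypes TSV not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample" not in df.columns:
        raise InputError(f"{path}: missing 'sample' column")
    file_pos = np.array([int(c) - 1 for c in df.columns if c != "sample"])
    known = set(int(p) for p in markers.positions)
    missing = [p for p in file_pos if p not in known]
    if missing:
        raise InputError(
            f"{path}: genotype columns at positions (1-based) "
            f"{[p + 1 for p in missing[:5]]} not present in the marker table"
        )
    used = markers.subset(np.isin(markers.positions, file_pos))
    if not np.array_equal(used.positions, file_pos):
        raise InputError(f"{path}: genotype columns must be in increasing position order")
    samples = df["sample"].tolist()
    geno = np.full((len(samples), len(file_pos)), NOCALL, dtype=np.int8)
    for j, col in enumerate(c for c in df.columns if c != "sample"):
        for i, v in enumerate(df[col]):
            if v not in CHAR_TO_GT:
                raise InputError(f"{path}: record {i + 1}: bad genotype state {v!r}")
            geno[i, j] = CHAR_TO_GT[v]
    return geno, samples, used


# ---------------------------------------------------------------------------
# Crossover call tables


def write_calls_tsv(result: CohortResult, path, comments=None) -> None:
    df = result.to_frame()
    body = df.to_csv(sep="\t", index=False, na_rep="NA")
    _write_commented(path, comments or header_comments(), body)


def read_calls_tsv(path) -> CohortResult:
    path = Path(path)
    if not path.exists():
        raise InputError(f"calls TSV not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    required = {"sample_id", "status", "left_pos", "right_pos", "direction"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    calls = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        if row.status not in STATUSES:
            raise InputError(f"{path}: record {idx}: unknown status {row.status!r}")
        if row.status == OK:
            calls.append(
                CrossoverCall(
                    str(row.sample_id), OK, int(row.left_pos), int(row.right_pos), str(row.direction)
                )
            )
        else:
            calls.append(CrossoverCall(str(row.sample_id), row.status))
    return CohortResult(calls)


# ---------------------------------------------------------------------------
# bedGraph landscapes


def write_bedgraph(landscape: Landscape, path, comments=None) -> None:
    extra = [f"total_cm={float(landscape.total_cm)!r}", f"n_co={landscape.n_co}"]
    buf = []
    chrom = landscape.interval.chrom
    for k in range(len(landscape.values)):
        start = int(landscape.bin_edges[k])
        end = int(landscape.bin_edges[k + 1])
        buf.append(f"{chrom}\t{start}\t{end}\t{float(landscape.values[k])!r}\n")
    _write_commented(path, (comments or header_comments()) + extra, "".join(buf))


def read_bedgraph(path, interval: IntervalSpec | None = None) -> Landscape:
    path = Path(path)
    if not path.exists():
        raise InputError(f"bedGraph not found: {path}")
    total_cm, n_co = float("nan"), 0
    rows = []
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("total_cm="):
                    total_cm = float(body.split("=", 1)[1])
                elif body.startswith("n_co="):
                    n_co = int(body.split("=", 1)[1])
                continue
            if not line or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise InputError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = fields[0]
            rows.append((int(fields[1]), int(fields[2]), float(fields[3])))
    if not rows:
        raise InputError(f"{path}: no bedGraph records")
    starts = [r[0] for r in rows]
    ends = [r[1] for r in rows]
    iv = interval or IntervalSpec(chrom, chrom, starts[0], ends[-1])
    edges = np.array(starts + [ends[-1]], dtype=float)
    values = np.array([r[2] for r in rows])
    if np.isnan(total_cm):
        total_cm = float(np.sum(values * np.diff(edges) / 1e6))
    return Landscape(iv, edges, values, total_cm, n_co)


# ---------------------------------------------------------------------------
# Generic tables


def write_table(df: pd.DataFrame, path, comments=None) -> None:
    _write_commented(path, comments or header_comments(), df.to_csv(sep="\t", index=False, na_rep="NA"))
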