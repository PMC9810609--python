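"""End-to-end pipeline: filter -> thin -> genotype -> call -> landscape.

``run_pipeline`` wires the stages together from a :class:`PipelineConfig`,
writes every intermediate and final table under an output directory, and
records a run manifest (tool version, config hash, RNG seed, stage list and
headline numbers) so a run can be audited and reproduced byte-for-byte.
Any stage failure aborts with the stage name attached.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from pathlib import Path

import numpy as np

from . import __version__, io
from .config import PipelineConfig
from .crossovers import call_cohort
from .errors import InputError, SeedtyperError
from .genotyping import filter_markers, genotype_matrix, thin_markers
from .landscape import build_landscape, hotspot_activity, section_compare
from .seeds import recombination_frequency, summarize_groups

log = logging.getLogger(__name__)


@contextmanager
def _stage(name: str, manifest: dict):
    log.info("stage %s: start", name)
    try:
        yield
    except SeedtyperError as e:
        raise type(e)(f"stage {name!r}: {e}") from e
    except Exception as e:  # give the stage name even for unexpected failures
        raise SeedtyperError(f"stage {name!r}: {type(e).__name__}: {e}") from e
    manifest["stages"].append(name)
    log.info("stage %s: done", name)


def _require_input(config: PipelineConfig, key: str) -> str:
    try:
        return config.inputs[key]
    except KeyError:
        raise InputError(f"required input {key!r} missing from config")


def _call_one_cohort(config, markers, counts_path, manifest, out_dir, prefix, chash):
    """filter -> thin -> genotype -> call-co for one cohort; returns the calls."""
    comments = io.header_comments(chash)
    with _stage(f"{prefix}read_counts", manifest):
        counts = io.read_counts_tsv(counts_path, markers)
    with _stage(f"{prefix}filter_markers", manifest):
        counts, report = filter_markers(
            counts, config.min_depth, config.max_fraction_nocall, config.thresholds()
        )
        io.write_table(report, out_dir / f"{prefix}dropped_markers.tsv", comments)
    with _stage(f"{prefix}thin_markers", manifest):
        thinned = thin_markers(counts.markers, config.thin_spacing_bp)
        mask = np.isin(counts.markers.positions, thinned.positions)
        counts = counts.subset_markers(mask)
    with _stage(f"{prefix}genotype", manifest):
        geno, sample_summary = genotype_matrix(counts, config.thresholds())
        io.write_genotypes_tsv(geno, counts.samples, counts.markers, out_dir / f"{prefix}genotypes.tsv", comments)
        io.write_table(sample_summary, out_dir / f"{prefix}sample_qc.tsv", comments)
    with _stage(f"{prefix}call_co", manifest):
        cohort = call_cohort(geno, counts.markers, config.min_flank, counts.samples)
        io.write_calls_tsv(cohort, out_dir / f"{prefix}crossovers.tsv", comments)
    return cohort, counts.markers


def _total_cm(config, seeds_key, override, manifest, prefix) -> float:
    if override is not None:
        return float(override)
    path = config.inputs.get(seeds_key)
    if path is None:
        raise InputError(
            f"need either a configured total_cm or a {seeds_key!r} input to normalize the landscape"
        )
    seeds = io.read_seeds_tsv(path)
    rf = [recombination_frequency(c) for c in seeds]
    total = float(np.mean(rf))
    log.info("%stotal genetic length from %d plants: %.4f cM", prefix, len(rf), total)
    return total


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full seed-typing analysis described by ``config``.

    Returns a result bundle (dict) with the cohort result, landscape,
    hotspot table, and — when a second cohort is configured — the section
    comparison.  All outputs are also written under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    comments = io.header_comments(chash)
    manifest: dict = {
        "tool": "seedtyper",
        "version": __version__,
        "config_hash": chash,
        "rng_seed": config.rng_seed,
        "stages": [],
    }
    bundle: dict = {"manifest": manifest}

    with _stage("read_markers", manifest):
        markers = io.read_markers_vcf(_require_input(config, "markers_vcf"))
    interval = markers.interval

    seeds_path = config.inputs.get("seeds_tsv")
    if seeds_path:
        with _stage("score_seeds", manifest):
            seeds = io.read_seeds_tsv(seeds_path)
            summary = summarize_groups(seeds, interval)
            io.write_table(summary, out_dir / "seed_summary.tsv", comments)
            bundle["seed_summary"] = summary

    total_cm = _total_cm(config, "seeds_tsv", config.total_cm, manifest, "")
    cohort, used_markers = _call_one_cohort(
        config, markers, _require_input(config, "counts_tsv"), manifest, out_dir, "", chash
    )
    bundle["cohort"] = cohort
    manifest["n_attempted"] = cohort.n_attempted
    manifest["n_ok"] = cohort.n_ok
    manifest["success_rate_percent"] = round(cohort.success_rate_percent, 2)
    manifest["total_cm"] = total_cm

    with _stage("landscape", manifest):
        scape = build_landscape(cohort, interval, total_cm, config.bin_width_bp)
        io.write_bedgraph(scape, out_dir / "landscape.bedgraph", comments)
        bundle["landscape"] = scape

    hotspots_path = config.inputs.get("hotspots_bed")
    if hotspots_path:
        with _stage("hotspots", manifest):
            hotspots = io.read_region_set(hotspots_path)
            hotspots.require_within(interval)
            activity = hotspot_activity(cohort, hotspots, total_cm)
            io.write_table(activity, out_dir / "hotspot_activity.tsv", comments)
            bundle["hotspot_activity"] = activity

    mut_counts = config.inputs.get("mut_counts_tsv")
    sections_path = config.inputs.get("sections_bed")
    if mut_counts and sections_path:
        mut_total = _total_cm(config, "mut_seeds_tsv", config.mut_total_cm, manifest, "mut_")
        mut_cohort, _ = _call_one_cohort(config, markers, mut_counts, manifest, out_dir, "mut_", chash)
        manifest["mut_n_ok"] = mut_cohort.n_ok
        manifest["mut_total_cm"] = mut_total
        with _stage("sections", manifest):
            sections = io.read_region_set(sections_path)
            table, rho, p = section_compare(
                cohort, total_cm, mut_cohort, mut_total, sections, markers,
                interval=interval, snps_only=config.snps_only_density,
            )
            io.write_table(table, out_dir / "section_stats.tsv", comments)
            bundle["sections"] = table
            manifest["section_spearman_rho"] = rho
            manifest["section_spearman_p"] = p

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info(
        "pipeline complete: %d stages, success rate %.1f%%",
        len(manifest["stages"]),
        cohort.success_rate_percent,
    )
    return bundle
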