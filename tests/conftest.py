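import numpy as np
import pytest

from seedtyper import IntervalSpec, Marker, MarkerTable, SimParams, simulate_cohort


@pytest.fixture(scope="session")
def chp_interval() -> IntervalSpec:
    return IntervalSpec("ChP", "chr3", 0, 26_300)


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    """A fast, clean cohort: modest size, no sequencing error."""
    return SimParams(
        interval_length_bp=26_300,
        marker_density_per_kb=10.0,
        n_recombinants=60,
        depth_mean=100.0,
        error_rate=0.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def clean_cohort(small_params):
    """(markers, model, truth, counts) for an error-free simulated cohort."""
    return simulate_cohort(small_params)


def toy_markers(positions, interval_end=None, kinds=None, chrom="chr1", name="toy"):
    """Small hand-built marker table at the given 0-based positions."""
    positions = list(positions)
    end = interval_end or max(positions) + 1
    kinds = kinds or ["SNP"] * len(positions)
    iv = IntervalSpec(name, chrom, 0, end)
    markers = tuple(
        Marker(chrom, p, "A", "G" if k == "SNP" else "AT", k) for p, k in zip(positions, kinds)
    )
    return MarkerTable(iv, markers)
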