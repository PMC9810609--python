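"""Synthetic seed-typing experiments with known ground truth.

This module generates the inputs the analysis pipeline consumes — a marker
map for a short interval, a hotspot intensity model, a cohort of selected
single-crossover recombinants, their noisy per-marker allele counts, and
fluorescent seed-class tallies — together with the generating truth, so that
breakpoint recovery and estimator calibration can be tested end to end.

The default geometry emulates a pericentromeric ~26.3 kb interval with up to
~19 polymorphisms/kb, three well-separated kilobase-scale hotspots of
unequal strength, amplicon sequencing at ~1500x depth, and F2 seed
populations of a few thousand seeds with recombinant fractions well below
1%.

Model assumptions (all deliberately minimal):

* each selected recombinant carries exactly one crossover between the
  reporters; the non-fluorescent homolog is non-recombinant — double events
  surface downstream as QC failures, not here;
* marker positions are i.i.d. uniform over the interval;
* read depth per marker is Poisson; sequencing errors are symmetric
  per-read allele miscalls;
* all randomness flows from a single seed recorded in ``SimParams``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .errors import InputError
from .genotyping import HET, HOM_ALT, INDEL, SNP, AlleleCounts, Marker, MarkerTable
from .regions import IntervalSpec

# orientation labels: which side of the crossover is heterozygous
HET_TO_HOM = "HET->HOM"
HOM_TO_HET = "HOM->HET"

# per-operation salts so each draw stream is independent of the others
_SALT_MARKERS = 1
_SALT_RECOMBINANTS = 2
_SALT_COUNTS = 3
_SALT_SEEDS = 4


@dataclass(frozen=True)
class SimParams:
    """Parameters of a synthetic seed-typing experiment.

    ``r_true`` is the recombinant-gamete frequency between the two reporters
    (so the expected single-color seed fraction is r - r^2/2, slightly below
    2 x r/2 because double-recombinant seeds show both colors or neither).
    """

    interval_length_bp: int = 26_300
    marker_density_per_kb: float = 18.7
    indel_fraction: float = 0.1
    n_recombinants: int = 243
    depth_mean: float = 1500.0
    error_rate: float = 0.005
    r_true: float = 0.0048
    n_seeds: int = 4000
    coupling: float = 0.0
    p_het_to_hom: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.interval_length_bp < 1:
            raise InputError("interval_length_bp must be positive")
        if self.marker_density_per_kb < 0:
            raise InputError("marker_density_per_kb must be >= 0")
        if not 0 <= self.indel_fraction <= 1:
            raise InputError("indel_fraction must be in [0, 1]")
        if self.n_recombinants < 1:
            raise InputError("n_recombinants must be positive")
        if self.depth_mean <= 0:
            raise InputError("depth_mean must be positive")
        if not 0 <= self.error_rate < 1:
            raise InputError("error_rate must be in [0, 1)")
        if not 0 <= self.r_true <= 0.5:
            raise InputError("r_true must be in [0, 0.5]")
        if self.n_seeds < 1:
            raise InputError("n_seeds must be positive")
        if self.coupling < 0:
            raise InputError("coupling must be >= 0")
        if not 0 <= self.p_het_to_hom <= 1:
            raise InputError("p_het_to_hom must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InputError(f"unknown SimParams keys: {sorted(unknown)}")
        return cls(**d)

    def rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.rng_seed), salt]))


@dataclass(frozen=True)
class Hotspot:
    start_bp: int
    end_bp: int
    weight: float

    def __post_init__(self) -> None:
        if self.end_bp <= self.start_bp:
            raise InputError("hotspot end must exceed start")
        if self.weight < 0:
            raise InputError("hotspot weight must be >= 0")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass(frozen=True)
class LandscapeModel:
    """Mixture intensity over an interval: uniform hotspots plus uniform background.

    Component weights are relative; sampling normalizes them so the intensity
    integrates to 1.
    """

    interval_length_bp: int
    hotspots: tuple[Hotspot, ...]
    background_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.background_weight < 0:
            raise InputError("background_weight must be >= 0")
        hs = sorted(self.hotspots, key=lambda h: h.start_bp)
        for h in hs:
            if h.start_bp < 0 or h.end_bp > self.interval_length_bp:
                raise InputError("hotspot outside interval")
        for a, b in zip(hs, hs[1:]):
            if b.start_bp < a.end_bp:
                raise InputError("hotspots overlap")
        if self.total_weight <= 0:
            raise InputError("model needs at least one positive weight")
        object.__setattr__(self, "hotspots", tuple(hs))

    @property
    def total_weight(self) -> float:
        return self.background_weight + sum(h.weight for h in self.hotspots)

    def component_probs(self) -> np.ndarray:
        """Normalized mixture weights: hotspots first, background last."""
        w = np.array([h.weight for h in self.hotspots] + [self.background_weight], dtype=float)
        return w / w.sum()

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw crossover positions (continuous, in [0, interval_length))."""
        probs = self.component_probs()
        comp = rng.choice(len(probs), size=n, p=probs)
        pos = rng.uniform(0.0, self.interval_length_bp, size=n)
        for k, h in enumerate(self.hotspots):
            sel = comp == k
            pos[sel] = rng.uniform(h.start_bp, h.end_bp, size=sel.sum())
        return pos


def chp_like_model(interval_length_bp: int = 26_300) -> LandscapeModel:
    """Three separated hotspots of 8.8 / 4.6 / 3.4 kb carrying ~32/60/8% of
    crossovers, over a weak uniform background — the geometry of a highly
    recombining pericentromeric interval."""
    scale = interval_length_bp / 26_300
    geometry = ((1_500, 10_300, 0.31), (12_000, 16_600, 0.585), (19_500, 22_900, 0.08))
    return LandscapeModel(
        interval_length_bp=interval_length_bp,
        hotspots=tuple(Hotspot(int(s * scale), int(e * scale), w) for s, e, w in geometry),
        background_weight=0.025,
    )


@dataclass
class SimTruth:
    """Ground truth for a simulated recombinant cohort."""

    params: SimParams
    markers: MarkerTable
    model: LandscapeModel
    co_positions: np.ndarray  # float, bp within interval
    orientations: np.ndarray  # HET_TO_HOM / HOM_TO_HET per recombinant
    genotypes: np.ndarray  # int8, recombinants x markers
    sample_ids: list[str] = field(default_factory=list)


def make_marker_map(
    params: SimParams,
    chrom: str = "sim1",
    name: str = "sim",
    density_blocks: list[tuple[int, int, float]] | None = None,
) -> MarkerTable:
    """Draw a marker map with uniformly placed, distinct integer positions.

    The marker count is Poisson with mean density x length / 1000; each
    marker is a SNP by default or an InDel with probability
    ``params.indel_fraction``.  ``density_blocks`` — optional non-overlapping
    (start_bp, end_bp, density_per_kb) triples — impose a blockwise density
    profile (regions not covered keep the global density), emulating the
    polymorphism-rich and polymorphism-free patches of real intervals.
    """
    length = params.interval_length_bp
    expected = params.marker_density_per_kb * length / 1000.0
    if density_blocks is not None:
        blocks = sorted(density_blocks)
        for (s1, e1, _), (s2, e2, _) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise InputError("density blocks overlap")
        covered = sum(e - s for s, e, _ in blocks)
        expected = sum(d * (e - s) / 1000.0 for s, e, d in blocks)
        expected += params.marker_density_per_kb * (length - covered) / 1000.0
    if expected < 1:
        raise InputError(
            f"interval too sparse: expected marker count {expected:.3g} < 1 "
            f"(density {params.marker_density_per_kb}/kb over {length} bp)"
        )
    rng = params.rng(_SALT_MARKERS)
    if density_blocks is None:
        n = int(rng.poisson(expected))
        n = min(max(n, 1), length)
        positions = np.sort(rng.choice(length, size=n, replace=False))
    else:
        positions = _blockwise_positions(rng, length, params.marker_density_per_kb, density_blocks)
        n = len(positions)
    is_indel = rng.random(n) < params.indel_fraction
    interval = IntervalSpec(name, chrom, 0, length)
    if n == 0:
        raise InputError("no markers drawn; increase density")
    markers = tuple(
        Marker(chrom, int(p), "A", "AT" if ind else "G", INDEL if ind else SNP)
        for p, ind in zip(positions, is_indel)
    )
    return MarkerTable(interval, markers)


def _blockwise_positions(
    rng: np.random.Generator,
    length: int,
    base_density: float,
    blocks: list[tuple[int, int, float]],
) -> np.ndarray:
    """Distinct integer positions under a piecewise-constant density profile."""
    segments: list[tuple[int, int, float]] = []
    cursor = 0
    for s, e, d in sorted(blocks):
        if s < 0 or e > length:
            raise InputError("density block outside interval")
        if d < 0:
            raise InputError("block density must be >= 0")
        if cursor < s:
            segments.append((cursor, s, base_density))
        segments.append((s, e, d))
        cursor = e
    if cursor < length:
        segments.append((cursor, length, base_density))
    chosen: list[np.ndarray] = []
    for s, e, d in segments:
        mean = d * (e - s) / 1000.0
        if mean <= 0:
            continue
        k = min(int(rng.poisson(mean)), e - s)
        if k:
            chosen.append(rng.choice(np.arange(s, e), size=k, replace=False))
    if not chosen:
        raise InputError("no markers drawn; increase density")
    return np.sort(np.concatenate(chosen))


def density_coupled_weights(markers: MarkerTable, model: LandscapeModel, coupling: float) -> LandscapeModel:
    """Couple hotspot weights to local polymorphism density.

    Each hotspot weight is multiplied by (1 + coupling x density/kb inside
    the hotspot, SNPs + InDels), then the hotspot weights are rescaled to
    preserve their original sum, so the coupling redistributes crossovers
    among hotspots without changing the hotspot/background split.  With
    coupling 0 the model is returned unchanged.
    """
    if coupling < 0:
        raise InputError("coupling must be >= 0")
    if coupling == 0 or not model.hotspots:
        return model
    pos = markers.positions
    raw = []
    for h in model.hotspots:
        n_local = int(((pos >= h.start_bp) & (pos < h.end_bp)).sum())
        density = n_local / (h.length_bp / 1000.0)
        raw.append(h.weight * (1.0 + coupling * density))
    old_sum = sum(h.weight for h in model.hotspots)
    scale = old_sum / sum(raw) if sum(raw) > 0 else 0.0
    new_hotspots = tuple(
        replace(h, weight=w * scale) for h, w in zip(model.hotspots, raw)
    )
    return replace(model, hotspots=new_hotspots)


def simulate_recombinants(params: SimParams, markers: MarkerTable, model: LandscapeModel) -> SimTruth:
    """Draw a cohort of single-crossover recombinants.

    Crossover positions follow the model intensity; orientation (which side
    of the breakpoint is heterozygous) is Bernoulli(``p_het_to_hom``).
    Positions that would leave no marker on one side are redrawn so every
    truth genotype vector contains exactly one transition.
    """
    if model.interval_length_bp != params.interval_length_bp:
        raise InputError("model/interval length mismatch")
    if len(markers) < 2:
        raise InputError("need at least two markers to place a crossover")
    rng = params.rng(_SALT_RECOMBINANTS)
    n = params.n_recombinants
    pos = markers.positions
    lo, hi = pos[0], pos[-1]

    co = model.sample(rng, n)
    # reject draws outside the marker span (no observable transition there)
    bad = (co <= lo) | (co > hi)
    while bad.any():
        co[bad] = model.sample(rng, int(bad.sum()))
        bad = (co <= lo) | (co > hi)

    het_first = rng.random(n) < params.p_het_to_hom
    orientations = np.where(het_first, HET_TO_HOM, HOM_TO_HET)

    before = pos[None, :] < co[:, None]  # marker strictly left of the crossover
    genotypes = np.where(
        het_first[:, None], np.where(before, HET, HOM_ALT), np.where(before, HOM_ALT, HET)
    ).astype(np.int8)
    ids = [f"rec_{i + 1:04d}" for i in range(n)]
    return SimTruth(params, markers, model, co, orientations, genotypes, ids)


def simulate_allele_counts(truth: SimTruth, params: SimParams | None = None) -> AlleleCounts:
    """Overlay Poisson depth and symmetric per-read miscalls on the truth.

    At a heterozygous marker the reference-read probability is 0.5 (miscalls
    are symmetric, so they cancel in expectation); at a homozygous-alternate
    marker it is ``error_rate``; at a homozygous-reference marker it would be
    1 - ``error_rate``.
    """
    p = params or truth.params
    if p.depth_mean <= 0:
        raise InputError("depth_mean must be positive")
    rng = p.rng(_SALT_COUNTS)
    shape = truth.genotypes.shape
    depth = rng.poisson(p.depth_mean, size=shape)
    p_ref = np.full(shape, 0.5)
    p_ref[truth.genotypes == HOM_ALT] = p.error_rate
    p_ref[truth.genotypes == 0] = 1.0 - p.error_rate  # HOM_REF, not produced by default
    ref = rng.binomial(depth, p_ref)
    alt = depth - ref
    return AlleleCounts(list(truth.sample_ids), truth.markers, ref, alt)


def seed_class_probs(r: float) -> tuple[float, float]:
    """(green-only, red-only) seed probabilities for recombinant frequency r.

    Gametes: parental GR and -- each with frequency (1-r)/2; recombinant G-
    and -R each with r/2.  A seed is green-only when neither gamete carries
    the red reporter and at least one carries green:
    p = r^2/4 + r(1-r)/2; red-only is symmetric.
    """
    if not 0 <= r <= 0.5:
        raise InputError("r must be in [0, 0.5]")
    p_single = r * r / 4.0 + r * (1.0 - r) / 2.0
    return p_single, p_single


def simulate_seed_counts(
    params: SimParams,
    plant_id: str = "plant_1",
    group: str = "sim",
    rng: np.random.Generator | None = None,
):
    """Multinomial seed-class draw for one plant: (N_G, N_R, N_T)."""
    from .seeds import SeedCounts  # local import to avoid a cycle

    p_g, p_r = seed_class_probs(params.r_true)
    rng = rng if rng is not None else params.rng(_SALT_SEEDS)
    n_g, n_r, _ = rng.multinomial(params.n_seeds, [p_g, p_r, 1.0 - p_g - p_r])
    return SeedCounts(plant_id=plant_id, group=group, n_green=int(n_g), n_red=int(n_r), n_total=params.n_seeds)


def simulate_seed_plants(params: SimParams, n_plants: int, group: str = "sim") -> list:
    """Independent seed-class draws for a set of biological replicates."""
    if n_plants < 1:
        raise InputError("n_plants must be positive")
    rng = params.rng(_SALT_SEEDS)
    return [
        simulate_seed_counts(params, plant_id=f"{group}_plant_{i + 1:02d}", group=group, rng=rng)
        for i in range(n_plants)
    ]


def simulate_cohort(params: SimParams, model: LandscapeModel | None = None) -> tuple[MarkerTable, LandscapeModel, SimTruth, AlleleCounts]:
    """Convenience wrapper: marker map -> (density-coupled) model -> cohort -> counts."""
    markers = make_marker_map(params)
    base = model or chp_like_model(params.interval_length_bp)
    coupled = density_coupled_weights(markers, base, params.coupling)
    truth = simulate_recombinants(params, markers, coupled)
    counts = simulate_allele_counts(truth)
    return markers, coupled, truth, counts
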