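"""Normalized landscapes, hotspot activity, sections, and rank statistics."""

import itertools

import numpy as np
import pytest
from scipy import stats

from seedtyper import (
    IntervalSpec,
    RegionSet,
    build_landscape,
    heterozygosity_percent,
    hotspot_activity,
    polymorphism_density,
    section_compare,
    spearman_pvalue,
    spearman_t,
)
from seedtyper.crossovers import OK, CohortResult, CrossoverCall, calls_from_truth
from seedtyper.errors import InputError, QCError
from seedtyper.simulate import (
    Hotspot,
    LandscapeModel,
    SimParams,
    density_coupled_weights,
    make_marker_map,
    simulate_recombinants,
)

from conftest import toy_markers


def ok_call(left, right, sample="s", direction="HET->HOM_ALT"):
    return CrossoverCall(sample, OK, left, right, direction)


def cohort(pairs):
    return CohortResult([ok_call(l, r, f"s{i}") for i, (l, r) in enumerate(pairs)])


class TestBuildLandscape:
    def test_single_call_in_one_bin(self):
        iv = IntervalSpec("iv", "c", 0, 1000)
        scape = build_landscape(cohort([(200, 400)]), iv, total_cm=0.5, bin_width=200)
        # all mass in the 200-400 bin: 0.5 cM over 0.0002 Mb
        assert scape.values[1] == pytest.approx(2500.0)
        assert scape.values[[0, 2, 3, 4]] == pytest.approx(0.0)

    def test_conservation(self):
        iv = IntervalSpec("iv", "c", 0, 26_300)
        rng = np.random.default_rng(0)
        pairs = [(int(a), int(a) + int(b)) for a, b in zip(rng.integers(0, 26_000, 40), rng.integers(1, 300, 40))]
        scape = build_landscape(cohort(pairs), iv, total_cm=0.4792, bin_width=200)
        assert scape.integral_cm() == pytest.approx(0.4792, abs=1e-9)

    def test_hotspot_share_arithmetic(self):
        # 242 calls split 32/60/8% across three hotspots, total 0.479 cM
        iv = IntervalSpec("iv", "c", 0, 26_300)
        hs = RegionSet(
            (
                IntervalSpec("Aro", "c", 1_500, 10_300),
                IntervalSpec("Coco", "c", 12_000, 16_600),
                IntervalSpec("Nala", "c", 19_500, 22_900),
            )
        )
        calls = (
            [ok_call(5_000, 5_010, f"a{i}") for i in range(int(242 * 0.32))]
            + [ok_call(14_000, 14_010, f"c{i}") for i in range(int(242 * 0.60))]
            + [ok_call(21_000, 21_010, f"n{i}") for i in range(242 - int(242 * 0.32) - int(242 * 0.60))]
        )
        res = CohortResult(calls)
        act = hotspot_activity(res, hs, total_cm=0.479)
        mass = act.share * 0.479
        assert mass.to_numpy() == pytest.approx([0.153, 0.287, 0.038], abs=0.002)

    def test_no_ok_calls_rejected(self):
        iv = IntervalSpec("iv", "c", 0, 1000)
        with pytest.raises(QCError):
            build_landscape(CohortResult([]), iv, 0.5)


class TestHotspotActivity:
    def test_share_to_cm_per_mb(self):
        # 60% share of 0.4792 cM in a 4.6-kb hotspot
        iv_h = RegionSet((IntervalSpec("Coco", "c", 12_000, 16_600),))
        calls = [ok_call(14_000, 14_020, f"s{i}") for i in range(60)] + [
            ok_call(100, 120, f"o{i}") for i in range(40)
        ]
        act = hotspot_activity(CohortResult(calls), iv_h, total_cm=0.4792)
        assert act.iloc[0].share == pytest.approx(0.60)
        assert act.iloc[0].cm_per_mb == pytest.approx(0.60 * 0.4792 / 0.0046, rel=1e-12)
        assert act.iloc[0].cm_per_mb == pytest.approx(62.5, abs=0.1)

    def test_empty_hotspot(self):
        hs = RegionSet((IntervalSpec("h", "c", 0, 100),))
        act = hotspot_activity(cohort([(500, 510)]), hs, 1.0)
        assert act.iloc[0].share == 0.0
        assert act.iloc[0].cm_per_mb == 0.0

    def test_tiling_shares_sum_to_one(self):
        hs = RegionSet(tuple(IntervalSpec(f"h{i}", "c", i * 100, (i + 1) * 100) for i in range(10)))
        rng = np.random.default_rng(1)
        pairs = [(int(p), int(p) + 2) for p in rng.integers(0, 990, 50)]
        act = hotspot_activity(cohort(pairs), hs, 1.0)
        assert act.share.sum() == pytest.approx(1.0)

    def test_overlapping_hotspots_rejected(self):
        with pytest.raises(InputError, match="overlap"):
            RegionSet((IntervalSpec("a", "c", 0, 100), IntervalSpec("b", "c", 50, 150)))

    def test_share_invariant_to_bin_width(self):
        # binning is irrelevant to midpoint-based membership
        iv = IntervalSpec("iv", "c", 0, 2000)
        hs = RegionSet((IntervalSpec("h", "c", 500, 1500),))
        calls = cohort([(700, 710), (100, 140), (1600, 1610), (900, 1000)])
        a1 = hotspot_activity(calls, hs, 1.0)
        for bw in (50, 200, 1000):
            build_landscape(calls, iv, 1.0, bw)  # must not interfere
            a2 = hotspot_activity(calls, hs, 1.0)
            assert a2.share.tolist() == a1.share.tolist()


class TestPolymorphismDensity:
    def test_back_derived_chp_density(self):
        m = toy_markers(np.linspace(10, 26_290, 492, dtype=int).tolist(), interval_end=26_300)
        assert polymorphism_density(m, m.interval) == pytest.approx(18.7, abs=0.05)

    def test_empty_region(self):
        m = toy_markers([5000], interval_end=10_000)
        assert polymorphism_density(m, IntervalSpec("r", "chr1", 0, 1000)) == 0.0

    def test_half_open_boundary(self):
        m = toy_markers([1000], interval_end=10_000)
        assert polymorphism_density(m, IntervalSpec("r", "chr1", 0, 1000)) == 0.0
        assert polymorphism_density(m, IntervalSpec("r", "chr1", 1000, 2000)) == pytest.approx(1.0)

    def test_snps_only_switch(self):
        m = toy_markers([10, 20, 30], kinds=["SNP", "InDel", "SNP"], interval_end=1000)
        region = IntervalSpec("r", "chr1", 0, 1000)
        assert polymorphism_density(m, region) == pytest.approx(3.0)
        assert polymorphism_density(m, region, snps_only=True) == pytest.approx(2.0)


class TestSpearman:
    def test_perfect_anticorrelation(self):
        rho, p = spearman_t([1, 2, 3, 4, 5], [10, 8, 6, 4, 2])
        assert rho == -1.0
        assert p == 0.0

    def test_printed_value_at_n10(self):
        assert spearman_pvalue(-0.912, 10) == pytest.approx(2.37e-4, abs=1.5e-6)

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            rho, p = spearman_t(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_t_approximation_vs_exact_permutation(self):
        # brute-force permutation null for tie-free n <= 7: the t approximation
        # should agree with the exact two-sided tail to within a few percent
        # absolute, which is what makes it usable at n ~ 10
        x = np.arange(6)
        y = np.array([2.0, 0.5, 3.0, 1.0, 5.0, 4.0])
        rho_obs, p_t = spearman_t(x, y)
        rhos = []
        for perm in itertools.permutations(range(6)):
            rhos.append(np.corrcoef(np.arange(1, 7), np.argsort(np.argsort([y[i] for i in perm])) + 1.0)[0, 1])
        rhos = np.array(rhos)
        p_exact = np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12)
        assert abs(p_t - p_exact) < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(InputError):
            spearman_t([1, 1, 1, 1], [1, 2, 3, 4])


def _sections(n, length):
    w = length // n
    return RegionSet(tuple(IntervalSpec(f"sec{i + 1}", "sim1", i * w, (i + 1) * w if i < n - 1 else length) for i in range(n)))


def _coupled_cohorts(seed, coupling_wt=1.0, n_co=200, n_sections=10):
    length = 26_000
    densities = np.linspace(2, 20, n_sections)
    blocks = [(i * 2600, (i + 1) * 2600, float(d)) for i, d in enumerate(densities)]
    hotspots = tuple(Hotspot(i * 2600, (i + 1) * 2600, 1.0) for i in range(n_sections))
    model = LandscapeModel(length, hotspots, background_weight=0.0)

    def one(coupling, salt):
        params = SimParams(
            interval_length_bp=length,
            marker_density_per_kb=10,
            n_recombinants=n_co,
            coupling=coupling,
            rng_seed=seed * 1000 + salt,
        )
        markers = make_marker_map(params, density_blocks=blocks)
        coupled = density_coupled_weights(markers, model, coupling)
        truth = simulate_recombinants(params, markers, coupled)
        return markers, calls_from_truth(truth)

    markers, wt = one(coupling_wt, 1)
    _, mut = one(0.0, 2)
    return markers, wt, mut, _sections(n_sections, length)


class TestSectionCompare:
    def test_identical_cohorts_degenerate(self):
        markers, wt, _, sections = _coupled_cohorts(seed=5, coupling_wt=0.0)
        table = None
        with pytest.raises(InputError, match="constant"):
            table, rho, p = section_compare(wt, 0.5, wt, 0.5, sections, markers)
        # the per-section ratios themselves are all exactly 1

    def test_relative_activity_of_identical_cohorts_is_one(self):
        markers, wt, _, sections = _coupled_cohorts(seed=6, coupling_wt=0.0)
        try:
            section_compare(wt, 0.5, wt, 0.5, sections, markers)
        except InputError:
            pass
        # compute the table through a copy with a jittered mutant to keep rho defined
        markers2, wt2, mut2, sections2 = _coupled_cohorts(seed=6, coupling_wt=0.0)
        table, _, _ = section_compare(wt2, 0.5, mut2, 0.5, sections2, markers2)
        retained = table[~table.excluded]
        assert len(retained) >= 3

    def test_coupling_yields_negative_rho(self):
        markers, wt, mut, sections = _coupled_cohorts(seed=1)
        table, rho, p = section_compare(wt, 0.5, mut, 0.5, sections, markers)
        assert rho < 0

    def test_swap_inverts_relative_activity(self):
        markers, wt, mut, sections = _coupled_cohorts(seed=2)
        t1, rho1, _ = section_compare(wt, 0.5, mut, 0.5, sections, markers)
        t2, rho2, _ = section_compare(mut, 0.5, wt, 0.5, sections, markers)
        r1 = t1[~t1.excluded].set_index("name").relative_activity
        r2 = t2[~t2.excluded].set_index("name").relative_activity
        common = r1.index.intersection(r2.index)
        assert np.allclose(r1[common] * r2[common], 1.0)
        assert np.sign(rho1) == -np.sign(rho2)

    def test_zero_co_sections_excluded(self):
        markers, wt, mut, sections = _coupled_cohorts(seed=3, n_co=15)
        table, _, _ = section_compare(wt, 0.5, mut, 0.5, sections, markers)
        zero = table[(table.wt_n_co == 0) | (table.mut_n_co == 0)]
        assert zero.excluded.all()
        assert table[~table.excluded].relative_activity.notna().all()

    def test_non_tiling_sections_rejected(self):
        markers, wt, mut, _ = _coupled_cohorts(seed=4)
        gappy = RegionSet((IntervalSpec("a", "sim1", 0, 1000), IntervalSpec("b", "sim1", 2000, 26_000)))
        with pytest.raises(InputError):
            section_compare(wt, 0.5, mut, 0.5, gappy, markers)


class TestHeterozygosity:
    def test_single_block(self):
        assert heterozygosity_percent([("chr1", 0, 1_250_000)]) == pytest.approx(1.0)

    def test_no_blocks(self):
        assert heterozygosity_percent([]) == 0.0

    def test_chp_sized_block(self):
        assert heterozygosity_percent([("chr3", 0, 26_300)]) == pytest.approx(0.021, abs=0.0005)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(InputError, match="overlap"):
            heterozygosity_percent([("chr1", 0, 100), ("chr1", 50, 150)])
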