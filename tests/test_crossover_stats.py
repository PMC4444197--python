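import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import ccsvsim as c
from ccsvsim.crossover_stats import TREATMENTS


def brute_force_friedman_permutation_p(values: np.ndarray) -> float:
    """Independent oracle: exhaustive enumeration over all per-subject
    rearrangements, recomputing ranks from the raw values each time."""
    n, k = values.shape

    def stat_surrogate(matrix):
        ranks = sps.rankdata(matrix, axis=1)
        colsums = ranks.sum(axis=0)
        return float(((colsums - n * (k + 1) / 2.0) ** 2).sum())

    observed = stat_surrogate(values)
    count = total = 0
    for combo in itertools.product(itertools.permutations(range(k)), repeat=n):
        rearranged = np.stack([values[i, list(p)] for i, p in enumerate(combo)])
        if stat_surrogate(rearranged) >= observed - 1e-9:
            count += 1
        total += 1
    return count / total


def brute_force_signflip_p(x, y):
    """Independent oracle: exact two-sided signed-rank p by enumerating all
    2^m sign patterns of the nonzero differences."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    m = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=m)
    ]
    ws = np.array(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    return min(1.0, 2.0 * min(p_ge, p_le))


class TestDescriptives:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3, 4, 5], (3.0, 2.0, 4.0, 1.0, 5.0)),
            ([7.0], (7.0, 7.0, 7.0, 7.0, 7.0)),
            ([2.5] * 6, (2.5, 2.5, 2.5, 2.5, 2.5)),
        ],
    )
    def test_examples(self, values, expected):
        d = c.descriptives(values)
        assert (d.median, d.q25, d.q75, d.min, d.max) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            c.descriptives([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_order_invariant(self, values):
        d = c.descriptives(values)
        assert d.min <= d.q25 <= d.median <= d.q75 <= d.max


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        data = np.tile(np.arange(6.0)[:, None], (1, 5))
        res = c.friedman_test(data)
        assert res.statistic == 0.0
        assert res.p_omnibus == 1.0

    def test_perfect_ordering_closed_form(self):
        """Every subject ranking the 5 treatments identically: chi2 = 48."""
        data = np.tile(np.arange(5.0), (12, 1)) + np.arange(12.0)[:, None]
        res = c.friedman_test(data)
        assert res.statistic == pytest.approx(48.0)
        assert res.df == 4

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_chi2_path_matches_scipy(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(10, 4))
        mine = c.friedman_test(data)
        ref = sps.friedmanchisquare(*(data[:, j] for j in range(4)))
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_omnibus == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_exact_permutation_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(4, 3))
        mine = c.friedman_test(data, p_method="permutation")
        assert mine.n_resamples == 6**4
        assert mine.p_omnibus == pytest.approx(brute_force_friedman_permutation_p(data))

    def test_monte_carlo_permutation_close_to_exhaustive(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(4, 3))
        exact = brute_force_friedman_permutation_p(data)
        mc = c.friedman_test(
            data, p_method="permutation", max_exact=10, n_resamples=4000, seed=11
        )
        # 3-sigma binomial Monte-Carlo band around the exhaustive value
        assert mc.p_omnibus == pytest.approx(
            exact, abs=3 * math.sqrt(exact * (1 - exact) / 4000) + 1e-3
        )

    def test_statistic_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(8, 5))
        base = c.friedman_test(data).statistic
        # strictly increasing transform applied per subject
        transformed = np.stack(
            [np.exp(row) if i % 2 else row**3 + 5 * row for i, row in enumerate(data)]
        )
        assert c.friedman_test(transformed).statistic == pytest.approx(base)

    def test_incomplete_or_tiny_matrix_rejected(self):
        with pytest.raises(ValueError):
            c.friedman_test(np.array([[1.0, np.nan], [2.0, 3.0]]))
        with pytest.raises(ValueError):
            c.friedman_test(np.array([[1.0, 2.0]]))


class TestWilcoxon:
    def test_identical_columns_degenerate(self):
        w, p, degenerate = c.wilcoxon_exact([1, 2, 3], [1, 2, 3])
        assert p == 1.0 and degenerate

    def test_all_same_sign_tail(self):
        """Twelve same-sign differences: exact two-sided p = 2 * 2^-12."""
        _, p, _ = c.wilcoxon_exact(np.arange(1.0, 13.0), np.zeros(12))
        assert p == pytest.approx(2 * 0.5**12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 10))
        _, p, _ = c.wilcoxon_exact(x, y)
        assert p == pytest.approx(brute_force_signflip_p(x, y))

    def test_matches_sign_flip_enumeration_with_ties(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0])
        y = np.array([2.0, 2.0, 3.0, 1.0, 4.0, 4.0, 4.0, 6.0])  # zeros and ties
        _, p, _ = c.wilcoxon_exact(x, y)
        assert p == pytest.approx(brute_force_signflip_p(x, y))

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 12))
        _, p, _ = c.wilcoxon_exact(x, y)
        assert p == pytest.approx(sps.wilcoxon(x, y, method="exact").pvalue)


class TestHolm:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.3], [0.3]),
            ([0.05, 0.05, 0.05], [0.15, 0.15, 0.15]),
            ([0.04, 0.01], [0.04, 0.02]),
        ],
    )
    def test_hand_computed_step_down(self, raw, expected):
        assert c.holm_adjust(raw) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            c.holm_adjust([0.5, 1.2])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        raw = rng.uniform(size=10)
        ref = multipletests(raw, method="holm")[1]
        assert c.holm_adjust(raw) == pytest.approx(ref)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_never_decreases_and_preserves_ranking(self, raw):
        adj = c.holm_adjust(raw)
        assert np.all(adj >= np.asarray(raw) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(raw, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestGenerator:
    def test_shape_and_completeness(self):
        ds = c.simulate_crossover_dataset(
            c.REFERENCE_VARIABLES["MAP"]["locations"], 5.0, n_subjects=12, seed=0
        )
        assert ds.values.shape == (12, 5)
        assert ds.treatments == TREATMENTS
        assert np.all(np.isfinite(ds.values))

    def test_zero_spread_reproduces_locations(self):
        locs = c.REFERENCE_VARIABLES["MAP"]["locations"]
        ds = c.simulate_crossover_dataset(locs, 0.0, n_subjects=4, seed=1)
        for t in TREATMENTS:
            assert np.all(ds.column(t) == locs[t])

    def test_lognormal_medians_recover_locations_at_large_n(self):
        # n chosen so the 5% band is >= 3 sigma for a sample median with the
        # combined log-scale sd of 0.58: SE = 1.253*sigma/sqrt(n)
        spec = c.REFERENCE_VARIABLES["PaO2"]
        ds = c.simulate_crossover_dataset(
            spec["locations"],
            spec["spreads"],
            n_subjects=2000,
            subject_sd=spec["subject_sd"],
            distribution=spec["distribution"],
            seed=123,
        )
        for t in TREATMENTS:
            assert np.median(ds.column(t)) == pytest.approx(
                spec["locations"][t], rel=0.05
            )

    def test_seed_reproducibility(self):
        kwargs = dict(n_subjects=12, subject_sd=1.0, seed=7)
        a = c.simulate_crossover_dataset(c.REFERENCE_VARIABLES["MAP"]["locations"], 3.0, **kwargs)
        b = c.simulate_crossover_dataset(c.REFERENCE_VARIABLES["MAP"]["locations"], 3.0, **kwargs)
        assert np.array_equal(a.values, b.values)


class TestAnalyzeTable:
    def test_constant_dataset(self):
        ds = c.CrossoverDataset(np.full((6, 5), 40.0))
        report = c.analyze_table(ds)
        assert report.friedman.p_omnibus == 1.0
        assert all(d.median == 40.0 for d in report.descriptives.values())
        assert all(r.degenerate for r in report.friedman.pairwise)

    def test_pairwise_count_is_ten(self):
        rng = np.random.default_rng(0)
        ds = c.CrossoverDataset(rng.normal(size=(12, 5)))
        report = c.analyze_table(ds)
        assert len(report.friedman.pairwise) == 10
        mat = report.pairwise_matrix()
        assert mat.notna().sum().sum() == 10

    def test_built_in_decrement_drives_smallest_p(self):
        """A large IPPV_last drop built into the generator should surface as
        the smallest adjusted p-values involving IPPV_last."""
        locs = dict(zip(TREATMENTS, (40.0, 40.0, 40.0, 40.0, 15.0)))
        ds = c.simulate_crossover_dataset(locs, 2.0, n_subjects=12, subject_sd=1.0, seed=21)
        report = c.analyze_table(ds)
        best = min(report.friedman.pairwise, key=lambda r: r.p_adjusted)
        assert "IPPV_last" in best.pair

    def test_conover_alternative_available(self):
        rng = np.random.default_rng(3)
        ds = c.CrossoverDataset(rng.normal(size=(10, 5)))
        report = c.analyze_table(ds, posthoc="conover")
        assert len(report.friedman.pairwise) == 10
        assert all(0.0 <= r.p_adjusted <= 1.0 for r in report.friedman.pairwise)


class TestPower:
    def test_strong_effect_has_high_power_null_has_alpha(self):
        locs_effect = dict(zip(TREATMENTS, (20.0, 49.0, 54.0, 46.0, 23.0)))
        power = c.estimate_power(locs_effect, 5.0, n_subjects=12, n_sims=100, seed=5)
        assert power > 0.9
        locs_null = dict(zip(TREATMENTS, (40.0,) * 5))
        null_rate = c.estimate_power(locs_null, 5.0, n_subjects=12, n_sims=200, seed=6)
        assert null_rate <= 0.1
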