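import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from intescreen import (BETA_CAP, MarginalFitTable, build_collection,
                        fit_collection, fit_marginal, force_include, rank_mean,
                        rank_variant, select_threshold, select_top)
from intescreen.marginal import _bernoulli_loglik
from conftest import make_study


def grid_search_mle(x, y, span=8.0, cap=BETA_CAP):
    """Independent 2-D oracle: iteratively refined grid search over
    (intercept, slope) maximizing the Bernoulli log-likelihood."""
    a_lo, a_hi = -span, span
    b_lo, b_hi = -cap, cap
    best = (0.0, 0.0)
    for _ in range(6):
        aa = np.linspace(a_lo, a_hi, 61)
        bb = np.linspace(b_lo, b_hi, 61)
        A, B = np.meshgrid(aa, bb, indexing="ij")
        eta = A.ravel()[None, :] + np.outer(x, B.ravel())
        ll = _bernoulli_loglik(eta, y)
        i = int(np.argmax(ll))
        best = (A.ravel()[i], B.ravel()[i])
        da, db = aa[1] - aa[0], bb[1] - bb[0]
        a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
        b_lo, b_hi = max(-cap, best[1] - 2 * db), min(cap, best[1] + 2 * db)
    return best


def make_fit_table(beta, gene_ids=None, study_ids=None):
    beta = np.asarray(beta, dtype=float)
    d, M = beta.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(d)]
    study_ids = study_ids or [f"s{m}" for m in range(M)]
    z = np.zeros_like(beta)
    return MarginalFitTable(gene_ids=gene_ids, study_ids=study_ids, beta0=z,
                           beta=beta, loglik=z - 1.0, pvalue=z + 0.5,
                           converged=np.ones_like(beta, dtype=bool),
                           separated=np.zeros_like(beta, dtype=bool),
                           loglik0=np.full(M, -1.0))


class TestFitMarginal:
    def test_symmetric_groups_give_zero(self):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        x = x / x.std(ddof=1)
        fit = fit_marginal(x, np.array([0, 1, 0, 1]))
        assert abs(fit.beta) < 1e-8 and abs(fit.beta0) < 1e-8
        assert fit.converged and not fit.separated

    def test_perfect_separation_capped(self):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        x = x / x.std(ddof=1)
        fit = fit_marginal(x, np.array([0, 0, 1, 1]))
        assert fit.separated and not fit.converged
        assert abs(fit.beta) == pytest.approx(BETA_CAP)

    @pytest.mark.parametrize("seed", range(8))
    def test_grid_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 9)
        x = rng.standard_normal(n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = rng.integers(0, 2, n)
        while y.sum() in (0, n):
            y = rng.integers(0, 2, n)
        fit = fit_marginal(x, y)
        a, b = grid_search_mle(x, y)
        if not fit.separated:
            assert fit.beta == pytest.approx(b, abs=1e-3)
            assert fit.beta0 == pytest.approx(a, abs=1e-3)
        else:
            assert abs(b) >= BETA_CAP - 1e-3

    def test_statsmodels_cross_check(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.standard_normal(40)
        x = (x - x.mean()) / x.std(ddof=1)
        y = (rng.random(40) < 1 / (1 + np.exp(-0.8 * x))).astype(int)
        fit = fit_marginal(x, y)
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        assert fit.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.beta0 == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_loglik_bounds(self, rng):
        ds = make_study(rng, n=30, genes=[f"g{i}" for i in range(20)])
        fits = fit_collection(build_collection([ds]))
        ll0 = fits.loglik0[0]
        assert np.all(fits.loglik[:, 0] <= 1e-12)
        assert np.all(fits.loglik[:, 0] >= ll0 - 1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_marginal(np.array([-1.0, 0.0, 1.0]), np.array([1, 1, 1]))


class TestRanking:
    def test_single_study_reduces_to_slope_magnitude(self):
        beta = np.array([[0.5], [-0.9], [0.1], [0.7]])
        rt = rank_mean(make_fit_table(beta))
        assert list(rt.rank) == [3, 1, 4, 2]

    def test_sign_discordant_gene(self):
        beta = np.array([[0.2, -0.2]])
        assert rank_variant(make_fit_table(beta), "mean").statistic[0] == pytest.approx(0.0)
        assert rank_variant(make_fit_table(beta), "max").statistic[0] == pytest.approx(0.2)
        assert rank_variant(make_fit_table(beta), "min").statistic[0] == pytest.approx(0.2)

    def test_l2_triple(self):
        rt = rank_variant(make_fit_table(np.array([[0.3, 0.4]])), "L2")
        assert rt.statistic[0] == pytest.approx(0.5)

    def test_mean_sort_oracle(self):
        beta = np.array([[0.1, 0.2, 0.3], [-0.5, -0.4, -0.6], [0.0, 0.1, -0.1],
                         [1.0, 0.2, 0.3], [0.4, 0.4, 0.4]])
        rt = rank_mean(make_fit_table(beta))
        expected_stat = [abs(row.sum() / 3) for row in beta]
        order = sorted(range(5), key=lambda i: (-expected_stat[i], i))
        expected_rank = [0] * 5
        for r, i in enumerate(order, start=1):
            expected_rank[i] = r
        np.testing.assert_allclose(rt.statistic, expected_stat, atol=1e-12)
        assert list(rt.rank) == expected_rank

    @pytest.mark.parametrize("kind", ["mean", "L2", "max", "min"])
    def test_variant_formula_oracle(self, rng, kind):
        beta = rng.normal(0, 0.5, size=(10, 4))
        stat = rank_variant(make_fit_table(beta), kind).statistic
        for j in range(10):
            row = beta[j]
            ref = {"mean": abs(row.mean()), "L2": np.sqrt((row ** 2).sum()),
                   "max": np.abs(row).max(), "min": np.abs(row).min()}[kind]
            assert stat[j] == pytest.approx(ref, abs=1e-12)

    def test_partial_availability_uses_available_studies(self):
        beta = np.array([[0.6, np.nan, np.nan], [0.3, 0.3, 0.3]])
        rt = rank_mean(make_fit_table(beta))
        assert list(rt.K) == [1, 3]
        np.testing.assert_allclose(rt.statistic, [0.6, 0.3])

    def test_unknown_kind(self):
        with pytest.raises(ValueError, match="unknown ranking"):
            rank_variant(make_fit_table(np.zeros((2, 2))), "median")

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_statistic_order_relations(self, seed):
        """For any slope table: all statistics are nonnegative magnitudes,
        |mean| <= max <= L2 and min <= max, and ranks are a permutation."""
        r = np.random.default_rng(seed)
        beta = r.normal(0, 1, size=(r.integers(1, 12), r.integers(1, 5)))
        stats = {k: rank_variant(make_fit_table(beta), k)
                 for k in ("mean", "L2", "max", "min")}
        for rt in stats.values():
            assert np.all(rt.statistic >= 0)
            assert sorted(rt.rank) == list(range(1, beta.shape[0] + 1))
        assert np.all(stats["mean"].statistic <= stats["max"].statistic + 1e-12)
        assert np.all(stats["max"].statistic <= stats["L2"].statistic + 1e-12)
        assert np.all(stats["min"].statistic <= stats["max"].statistic + 1e-12)

    def test_m1_all_variants_same_order(self, rng):
        beta = rng.normal(0, 0.5, size=(15, 1))
        orders = [tuple(rank_variant(make_fit_table(beta), k).rank)
                  for k in ("mean", "L2", "max", "min")]
        assert len(set(orders)) == 1

    def test_sign_flip_equivariance(self, rng):
        genes = [f"g{i}" for i in range(6)]
        studies = [make_study(rng, f"s{m}", n=25, genes=genes) for m in range(3)]
        from dataclasses import replace
        flipped = []
        for ds in studies:
            X = ds.X.copy()
            X[:, 2] *= -1
            flipped.append(replace(ds, X=X))
        f1 = fit_collection(build_collection(studies))
        f2 = fit_collection(build_collection(flipped))
        np.testing.assert_allclose(f2.beta[2], -f1.beta[2], atol=1e-8)
        for kind in ("mean", "L2", "max", "min"):
            np.testing.assert_allclose(rank_variant(f1, kind).statistic,
                                       rank_variant(f2, kind).statistic, atol=1e-8)


class TestSelection:
    @pytest.fixture
    def rt50(self, rng):
        return rank_mean(make_fit_table(rng.normal(0, 0.5, size=(50, 3))))

    def test_zero_threshold_selects_all(self, rt50):
        assert len(select_threshold(rt50, 0.0)) == 50

    def test_above_max_selects_none(self, rt50):
        assert select_threshold(rt50, rt50.statistic.max() + 1) == []

    def test_threshold_filter_oracle(self, rt50):
        gamma = np.sort(rt50.statistic)[-10]
        got = set(select_threshold(rt50, gamma))
        expected = {g for g, s in zip(rt50.gene_ids, rt50.statistic) if s >= gamma}
        assert got == expected

    def test_threshold_monotone_and_nested(self, rt50):
        prev = None
        for gamma in np.linspace(0, rt50.statistic.max() + 0.1, 12):
            sel = set(select_threshold(rt50, gamma))
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_top_fraction_arithmetic(self, rng):
        rt = rank_mean(make_fit_table(rng.normal(size=(200, 2))))
        assert len(select_top(rt, 0.10)) == 20
        assert len(select_top(rt, 1.0)) == 200
        assert len(select_top(rt, 7)) == 7

    def test_top_fractions_nested(self, rt50):
        s5, s10, s20 = (set(select_top(rt50, f)) for f in (0.05, 0.10, 0.20))
        assert s5 <= s10 <= s20

    def test_force_bottom_gene_grows_selection(self, rt50):
        bottom = rt50.gene_ids[int(np.argmax(rt50.rank))]
        rt = force_include(rt50, [bottom])
        sel = select_top(rt, 10)
        assert len(sel) == 11 and bottom in sel

    def test_force_top_gene_is_noop(self, rt50):
        top = rt50.gene_ids[int(np.argmin(rt50.rank))]
        assert select_top(force_include(rt50, [top]), 10) == select_top(rt50, 10)

    def test_forced_subset_of_every_selection(self, rt50, rng):
        forced = list(rng.choice(rt50.gene_ids, 5, replace=False))
        rt = force_include(rt50, forced)
        for gamma in rng.uniform(0, rt50.statistic.max() * 1.2, 10):
            assert set(forced) <= set(select_threshold(rt, gamma))
        for frac in (0.05, 0.3, 0.9):
            assert set(forced) <= set(select_top(rt, frac))

    def test_force_unknown_gene(self, rt50):
        with pytest.raises(ValueError, match="nope"):
            force_include(rt50, ["nope"])
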