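import numpy as np
import pandas as pd
import pytest
from scipy import stats

from blastasym import synthetic_data as sd
from blastasym.nb_axis_test import (
    BlastomereAsymmetryTest,
    bh_fdr,
    fit_axis,
    fit_null,
    fold_change,
    lrt_pvalue,
    multi_axis_fit,
    nb_loglik,
    run_tests,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def grid_profile_loglik(r, s, groups, log_alphas, beta_span=2.5, n_beta=601):
    """Exhaustive profile: for each dispersion, maximize each group's
    log-mean on a dense grid; NB pmf evaluated through scipy.  Groups are
    independent given the dispersion, so the per-group maxima add."""
    best_ll, best_alpha = -np.inf, None
    uniq = np.unique(groups)
    centers = [np.log(max(r[groups == g].sum(), 0.25) / s[groups == g].sum())
               for g in uniq]
    for alpha in np.concatenate(([0.0], np.exp(log_alphas))):
        total = 0.0
        for g, c in zip(uniq, centers):
            rr, ss = r[groups == g], s[groups == g]
            betas = np.linspace(c - beta_span, c + beta_span, n_beta)
            mu = ss[None, :] * np.exp(betas)[:, None]
            if alpha == 0.0:
                ll = stats.poisson.logpmf(rr[None, :], mu).sum(axis=1)
            else:
                k = 1.0 / alpha
                ll = stats.nbinom.logpmf(rr[None, :], k, k / (k + mu)).sum(axis=1)
            total += ll.max()
        if total > best_ll:
            best_ll, best_alpha = total, alpha
    return best_ll, best_alpha


def bh_oracle(p):
    """Hand step-up BH: q_(i) = min_{k >= i} m p_(k) / k, order restored."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = min(1.0, running)
    return q


ORACLE_LOG_ALPHAS = np.linspace(np.log(1e-6), np.log(1e4), 801)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class TestNBLoglik:
    def test_poisson_limit_closed_form(self):
        # log pmf of Poisson(2) at r=2: 2 ln 2 - 2 - ln 2 = ln 2 - 2
        ll = nb_loglik([2], [1.0], [2.0], alpha=0.0)
        assert ll == pytest.approx(np.log(2) - 2, abs=1e-12)

    def test_matches_nb2_pmf(self):
        # size 1/alpha = 2, p = 1/(1 + alpha mu) = 0.5
        ll = nb_loglik([3], [1.0], [2.0], alpha=0.5)
        assert ll == pytest.approx(stats.nbinom.logpmf(3, 2, 0.5), rel=1e-12)

    @pytest.mark.parametrize("r,mu,alpha", [
        ([0, 1, 7], [2.0, 2.0, 2.0], 0.3),
        ([5], [5.0], 0.0),
        ([2, 2], [0.5, 9.0], 2.0),
    ])
    def test_log_probability_nonpositive(self, r, mu, alpha):
        assert nb_loglik(r, np.ones(len(r)), mu, alpha) <= 0.0

    def test_nonfinite_inputs_rejected(self):
        with pytest.raises(ValueError):
            nb_loglik([1], [1.0], [np.inf], 0.1)
        with pytest.raises(ValueError):
            nb_loglik([1], [1.0], [1.0], np.nan)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class TestFitNull:
    def test_zero_variance_data(self):
        s = np.full(8, 2_000_000.0)
        fit = fit_null(np.full(8, 40.0), s)
        assert fit.alpha == 0.0  # no overdispersion
        assert fit.betas[0] == pytest.approx(np.log(40 / 2e6), abs=1e-8)

    def test_offset_absorbs_sizes(self):
        s = np.array([1e6, 2e6, 4e6, 8e6])
        k = 2e-5
        fit = fit_null(k * s, s)
        assert fit.betas[0] == pytest.approx(np.log(k), abs=1e-6)

    def test_matches_grid_search(self):
        r = np.array([1, 2, 3, 4, 10, 12, 14, 16], dtype=float)
        s = np.full(8, 1.0)
        fit = fit_null(r, s)
        ll_grid, alpha_grid = grid_profile_loglik(
            r, s, np.zeros(8, dtype=int), ORACLE_LOG_ALPHAS
        )
        assert fit.loglik >= ll_grid - 1e-9
        assert fit.loglik == pytest.approx(ll_grid, abs=5e-3)
        assert fit.alpha == pytest.approx(alpha_grid, rel=0.02)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_null([3], [1.0])


class TestFitAxis:
    def test_identical_sides_degenerate_to_null(self):
        r = np.array([3, 7, 5, 9, 3, 7, 5, 9], dtype=float)
        s = np.full(8, 1.0)
        side = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        alt = fit_axis(r, s, side)
        null = fit_null(r, s)
        assert alt.loglik == pytest.approx(null.loglik, abs=1e-6)
        assert alt.betas[0] == pytest.approx(alt.betas[1], abs=1e-4)

    def test_poisson_group_means(self):
        s = np.full(8, 1e6)
        r = np.array([10.0] * 4 + [40.0] * 4)
        side = np.array([0] * 4 + [1] * 4)
        fit = fit_axis(r, s, side)
        assert fit.alpha == 0.0
        assert fit.betas[0] == pytest.approx(np.log(10 / 1e6), abs=1e-8)
        assert fit.betas[1] == pytest.approx(np.log(40 / 1e6), abs=1e-8)

    def test_matches_grid_search_fourfold(self):
        rng = np.random.default_rng(3)
        s = rng.lognormal(np.log(1e6), 0.2, 8)
        side = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        mu = 30 * s / 1e6 * np.where(side, 4.0, 1.0)
        r = rng.negative_binomial(10, 10 / (10 + mu)).astype(float)
        fit = fit_axis(r, s, side)
        ll_grid, alpha_grid = grid_profile_loglik(r, s, side, ORACLE_LOG_ALPHAS)
        assert fit.loglik >= ll_grid - 1e-9
        assert fit.loglik == pytest.approx(ll_grid, abs=5e-3)

    def test_one_sided_axis_rejected(self):
        with pytest.raises(ValueError):
            fit_axis([1, 2], [1.0, 1.0], [1, 1])


class TestMultiAxis:
    @pytest.fixture()
    def eight(self):
        rng = np.random.default_rng(9)
        s = np.full(8, 1e6)
        r = rng.poisson(50, 8).astype(float)
        a1 = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        a2 = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        return r, s, a1, a2

    def test_duplicated_axis_collapses_to_single(self, eight):
        r, s, a1, _ = eight
        double = multi_axis_fit(r, s, [a1, a1])
        single = fit_axis(r, s, a1)
        assert double.loglik == pytest.approx(single.loglik, abs=1e-6)
        assert double.df_design == 1

    def test_two_orthogonal_axes_have_df_2(self, eight):
        r, s, a1, a2 = eight
        fit = multi_axis_fit(r, s, [a1, a2])
        assert fit.df_design == 2

    def test_nesting_of_likelihoods(self, eight):
        r, s, a1, a2 = eight
        ll_null = fit_null(r, s).loglik
        ll_a1 = fit_axis(r, s, a1).loglik
        ll_both = multi_axis_fit(r, s, [a1, a2]).loglik
        assert ll_a1 >= ll_null - 1e-6
        assert ll_both >= ll_a1 - 1e-6


# ---------------------------------------------------------------------------
# LRT, BH, fold change
# ---------------------------------------------------------------------------

class TestLRT:
    def test_identical_fits(self):
        assert lrt_pvalue(-10.0, -10.0, 1) == (0.0, 1.0)

    def test_chi2_quantile(self):
        stat, p = lrt_pvalue(-10.0, -10.0 + 3.841459 / 2, 1)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_zero_stat_df2(self):
        assert lrt_pvalue(-3.0, -3.0, 2)[1] == 1.0

    def test_optimizer_failure_clamps_with_warning(self):
        with pytest.warns(RuntimeWarning):
            stat, p = lrt_pvalue(-1.0, -1.5, 1)
        assert stat == 0.0 and p == 1.0


class TestBH:
    def test_hand_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.04, 0.05])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.05, 0.05])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)

    def test_single_p(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(21)
        for n in (1, 5, 50, 400):
            p = np.round(rng.random(n), 3)  # rounding forces ties
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestFoldChange:
    def test_four_fold(self):
        fold, pole = fold_change([40, 40], [10, 10])
        assert fold == 4.0 and pole == 0

    def test_tie_has_no_pole(self):
        fold, pole = fold_change([5, 15], [10, 10])
        assert fold == 1.0 and pole is None

    def test_scale_invariance(self):
        f1, _ = fold_change([40, 44], [10, 12])
        f2, _ = fold_change([400, 440], [100, 120])
        assert f1 == pytest.approx(f2)

    def test_zero_side_is_infinite(self):
        fold, pole = fold_change([0, 0], [10, 10])
        assert np.isinf(fold) and pole == 1

    def test_both_zero_undefined(self):
        fold, pole = fold_change([0], [0])
        assert np.isnan(fold) and pole is None


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

class TestRunTests:
    def test_identical_counts_yield_no_calls(self, tiny_meta):
        counts = pd.DataFrame(100, index=[f"g{i}" for i in range(20)],
                              columns=tiny_meta.index)
        res = run_tests(counts, tiny_meta)
        assert (res["q"] > 0.9).all()
        assert (res["lrt_stat"] < 1e-6).all()

    def test_null_simulation_controls_fdr(self):
        config = sd.SimConfig(seed=77, n_genes=200, n_embryos=4,
                              frac_asymmetric_av=0.0)
        counts, meta, _ = sd.simulate(config)
        res = run_tests(counts, meta)
        frac = (res["q"] < 0.05).groupby(res["axis"]).mean()
        se = np.sqrt(0.05 * 0.95 / 200)
        assert (frac <= 0.05 + 3 * se).all()

    def test_recovers_planted_fourfold_vegetal_gene(self, small_sim):
        counts, meta, truth, _ = small_sim
        res = run_tests(counts, meta, axes=("av",))
        av = res.set_index("gene_id")
        planted = truth[(truth["axis"] == "av") & (truth["true_fold"] > 3)
                        & (truth["true_fold"] < 40)]
        assert len(planted) > 0
        hits = av.loc[planted["gene_id"]]
        assert (hits["q"] < 0.05).mean() >= 0.8
        ratio = hits["fold"].to_numpy() / planted["true_fold"].to_numpy()
        ok = (ratio < 1.5) & (ratio > 1 / 1.5)
        assert ok.mean() >= 0.8
        agree = hits["enriched_pole"].to_numpy() == planted["enriched_pole"].to_numpy()
        assert agree.all()

    def test_dv_permutation_leaves_av_unchanged(self, small_sim):
        counts, meta, _, _ = small_sim
        rng = np.random.default_rng(4)
        shuffled = meta.copy()
        for _, grp in meta.groupby("embryo_id"):
            idx = grp.index.to_numpy()
            shuffled.loc[idx, "dv"] = meta.loc[rng.permutation(idx), "dv"].to_numpy()
        base = run_tests(counts, meta, axes=("av",), relaxed=True)
        perm = run_tests(counts, shuffled, axes=("av",), relaxed=True)
        np.testing.assert_allclose(base["p"], perm["p"], rtol=1e-10)
        np.testing.assert_allclose(base["fold"], perm["fold"], rtol=1e-10)

    def test_per_embryo_mode_runs_each_embryo(self, small_sim):
        counts, meta, _, _ = small_sim
        res = run_tests(counts, meta, axes=("av",), mode="per_embryo")
        assert set(res["embryo_id"]) == set(meta["embryo_id"])
        # BH is applied within each embryo separately
        for _, grp in res.groupby("embryo_id"):
            ok = grp[grp["converged"]]
            np.testing.assert_allclose(
                ok["q"].to_numpy(), bh_oracle(ok["p"].to_numpy()), atol=1e-12
            )

    def test_pooled_power_at_least_single_embryo(self, small_sim):
        counts, meta, truth, _ = small_sim
        pooled = run_tests(counts, meta, axes=("av",))
        single = run_tests(counts, meta, axes=("av",), mode="per_embryo")
        planted = set(truth.loc[truth["axis"] == "av", "gene_id"])
        pooled_rate = (pooled[pooled["gene_id"].isin(planted)]["q"] < 0.05).mean()
        single_rate = (single[single["gene_id"].isin(planted)]["q"] < 0.05).mean()
        assert pooled_rate >= single_rate

    def test_multi_axis_combination_rows(self, small_sim):
        counts, meta, _, _ = small_sim
        res = run_tests(counts, meta, axes=[("av", "dv")])
        assert set(res["axis"]) == {"av+dv"}
        assert (res["df"] == 2).all()
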