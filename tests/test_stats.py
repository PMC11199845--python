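import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from wallfollow.stats import (aicc, dunnett_t3, fit_negative_binomial_glm,
                              kruskal_wallis, model_average_full)


def permutation_kw_p(groups, n_perm=20000, seed=0):
    """Permutation null of the tie-corrected H statistic."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    obs = kruskal_wallis(groups).H
    ranks = sps.rankdata(pooled)  # rank multiset is permutation-invariant
    rng = np.random.default_rng(seed)
    perm = ranks[np.argsort(rng.random((n_perm, len(pooled))), axis=1)]
    edges = np.cumsum([0] + sizes)
    N = len(pooled)
    stat = np.zeros(n_perm)
    for a, b in zip(edges[:-1], edges[1:]):
        rs = perm[:, a:b].sum(axis=1)
        stat += rs ** 2 / (b - a)
    stat = 12.0 / (N * (N + 1)) * stat - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    stat /= 1 - ((counts ** 3 - counts).sum()) / (N ** 3 - N)
    return float((stat >= obs - 1e-12).mean())


class TestKruskalWallis:
    def test_identical_groups_null(self):
        r = kruskal_wallis([np.ones(4), np.ones(5), np.ones(3)])
        assert r.H == 0.0
        assert r.p_value == 1.0

    def test_hand_computed_example(self):
        r = kruskal_wallis([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        assert r.H == pytest.approx(2.4)
        assert r.df == 1
        assert r.tie_correction == 1.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        groups = [np.round(rng.normal(m, 1, 12), 1) for m in (0, 0.5, 1.0)]
        r = kruskal_wallis(groups)
        H, p = sps.kruskal(*groups)
        assert r.H == pytest.approx(H, rel=1e-12)
        assert r.p_value == pytest.approx(p, rel=1e-12)

    def test_tied_data_p_close_to_permutation_null(self):
        rng = np.random.default_rng(7)
        groups = [np.round(rng.normal(m, 1, 25), 0)
                  for m in (0.0, 0.3, 0.6)]
        r = kruskal_wallis(groups)
        p_perm = permutation_kw_p(groups, n_perm=20000, seed=1)
        assert abs(r.p_value - p_perm) < 0.015

    @given(st.lists(st.lists(st.integers(-100, 100), min_size=3, max_size=12),
                    min_size=2, max_size=4))
    @settings(max_examples=40, deadline=None)
    def test_monotone_transform_invariance(self, groups):
        # grid-valued data so the exp transform stays injective in floats
        gs = [np.array(g, dtype=float) / 2.0 for g in groups]
        r1 = kruskal_wallis(gs)
        r2 = kruskal_wallis([np.exp(g / 25.0) for g in gs])
        assert r1.H == pytest.approx(r2.H, rel=1e-9, abs=1e-9)


class TestDunnettT3:
    def test_equal_groups_null(self):
        g = np.array([1.0, 1.0, 1.0])
        out = dunnett_t3([g, g.copy()])
        assert out[0].statistic == 0.0
        assert out[0].p_adjusted == pytest.approx(1.0)

    def test_two_groups_reduce_to_welch(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 2, 14)
        out = dunnett_t3([a, b])
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert out[0].statistic == pytest.approx(t, rel=1e-12)
        assert out[0].p_adjusted == pytest.approx(p, rel=1e-9)

    def test_family_adjustment_never_decreases_p(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, s, 8) for m, s in
                  [(0, 1), (0.5, 2), (1, 0.5), (0, 3)]]
        for c in dunnett_t3(groups):
            assert c.p_adjusted >= c.p_unadjusted - 1e-15


class TestNegativeBinomial:
    def test_intercept_only_recovers_log_mean(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(4.0, 400)
        fit = fit_negative_binomial_glm(y)
        assert fit.coefficients.loc["intercept", "estimate"] == \
            pytest.approx(np.log(y.mean()), abs=1e-4)

    def test_all_zero_response_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_negative_binomial_glm(np.zeros(20))

    def test_non_integer_response_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fit_negative_binomial_glm(np.array([1.0, 2.5, 3.0]))

    def test_poisson_limit(self):
        # equidispersed data: NB coefficients approach the Poisson GLM fit
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        x = rng.normal(size=500)
        y = rng.poisson(np.exp(0.5 + 0.7 * x))
        X = pd.DataFrame({"x": x})
        nb = fit_negative_binomial_glm(y, X)
        pois = sm.GLM(y, sm.add_constant(x),
                      family=sm.families.Poisson()).fit()
        assert nb.coefficients["estimate"].to_numpy() == \
            pytest.approx(pois.params, abs=0.02)

    def test_simulation_recovery(self):
        # known coefficients, dispersion 2 (alpha = 0.5), n = 500
        rng = np.random.default_rng(6)
        beta = np.array([1.0, 0.5, -0.3])
        hits = 0
        reps = 30
        for _ in range(reps):
            X = rng.normal(size=(500, 2))
            mu = np.exp(beta[0] + X @ beta[1:])
            size = 2.0
            y = rng.negative_binomial(size, size / (size + mu))
            fit = fit_negative_binomial_glm(y, pd.DataFrame(X, columns=["a", "b"]))
            est = fit.coefficients["estimate"].to_numpy()
            se = fit.coefficients["se"].to_numpy()
            if np.all(np.abs(est - beta) <= 2 * se):
                hits += 1
        assert hits / reps >= 0.80


def _gaussian_fitter(y, X):
    """OLS-with-known-aicc fitter for averaging tests."""
    import statsmodels.api as sm
    Xm = sm.add_constant(np.ones((len(y), 0)) if X is None
                         else X.to_numpy(), has_constant="add")
    res = sm.OLS(np.asarray(y, dtype=float), Xm).fit()
    from wallfollow.stats import NBGlmFit
    names = ["intercept"] + (list(X.columns) if X is not None else [])
    k = Xm.shape[1] + 1  # + residual variance
    coef = pd.DataFrame({"estimate": res.params, "se": res.bse}, index=names)
    return NBGlmFit(coefficients=coef, dispersion=np.inf, alpha=0.0,
                    log_likelihood=res.llf, aicc=aicc(res.llf, k, len(y)),
                    n=len(y), k_params=k)


class TestModelAveraging:
    def _data(self, n=60, seed=8):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = rng.poisson(np.exp(0.8 + 0.6 * X["a"].to_numpy()))
        return y, X

    def test_single_candidate_is_identity(self):
        y, X = self._data()
        res = model_average_full(y, X[["a"]], candidates=[("a",)])
        assert res.candidates["weight"].tolist() == [1.0]
        fit = fit_negative_binomial_glm(y, X[["a"]])
        assert res.averaged_coefficients.loc["a", "estimate"] == \
            pytest.approx(fit.coefficients.loc["a", "estimate"])

    def test_weights_sum_to_one_and_equal_aicc_splits(self):
        y, X = self._data()
        # duplicated predictor -> two candidates with identical AICc
        X2 = X[["a"]].copy()
        X2["a2"] = X2["a"]
        res = model_average_full(y, X2, candidates=[("a",), ("a2",)])
        assert res.candidates["weight"].sum() == pytest.approx(1.0)
        assert res.candidates["weight"].tolist() == pytest.approx([0.5, 0.5])

    def test_full_average_matches_brute_force(self):
        y, X = self._data(n=80)
        res = model_average_full(y, X, fitter=_gaussian_fitter,
                                 delta_threshold=np.inf)
        # independent recomputation of weights and full-averaged estimates
        import itertools
        fits, aiccs = [], []
        for r in range(4):
            for cand in itertools.combinations(list("abc"), r):
                f = _gaussian_fitter(y, X[list(cand)] if cand else None)
                fits.append((cand, f))
                aiccs.append(f.aicc)
        d = np.array(aiccs) - min(aiccs)
        w = np.exp(-d / 2)
        w /= w.sum()
        assert res.candidates["weight"].to_numpy() == pytest.approx(w)
        for term in ["intercept", "a", "b", "c"]:
            manual = sum(
                wi * (f.coefficients.loc[term, "estimate"]
                      if term in f.coefficients.index else 0.0)
                for (cand, f), wi in zip(fits, w))
            assert res.averaged_coefficients.loc[term, "estimate"] == \
                pytest.approx(manual, rel=1e-9, abs=1e-12)

    def test_small_sample_candidate_dropped(self):
        y, X = self._data(n=6)
        with pytest.warns(UserWarning, match="dropping candidate"):
            res = model_average_full(y, X, fitter=_gaussian_fitter,
                                     candidates=[(), ("a", "b", "c")])
        assert len(res.candidates) == 1
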