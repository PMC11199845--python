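import numpy as np
import pandas as pd
import pytest

from wallfollow.phylo import (NewickError, Phylogeny, bm_covariance,
                              clade_summaries, estimate_lambda, pgls_fit,
                              read_newick, read_newick_string,
                              _gls_profile_loglik)
from wallfollow.simulate import TraitSimConfig, simulate_bm_traits

BASIC = "((A:1,B:1):1,C:2);"


def balanced_tree(depth: int, total: float = 1.0) -> Phylogeny:
    """Ultrametric balanced binary tree with 2**depth tips."""
    def build(d, labels):
        if d == 0:
            return f"{labels[0]}:{total / depth}"
        half = len(labels) // 2
        bl = total / depth
        left = build(d - 1, labels[:half])
        right = build(d - 1, labels[half:])
        if d == depth:
            return f"({left},{right});"
        return f"({left},{right}):{bl}"
    labels = [f"t{i}" for i in range(2 ** depth)]
    return read_newick_string(build(depth, labels))


class TestNewickIO:
    def test_parse_and_depths(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text(BASIC + "\n")
        phy = read_newick(p)
        assert sorted(phy.tip_labels) == ["A", "B", "C"]
        C = phy.vcv()
        assert C.loc["A", "A"] == pytest.approx(2.0)  # root height
        assert C.loc["A", "B"] == pytest.approx(1.0)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    def test_round_trip_topology(self):
        phy = read_newick_string(BASIC)
        again = read_newick_string(phy.to_newick())
        assert again.vcv().to_numpy() == pytest.approx(phy.vcv().to_numpy())

    def test_malformed_string_raises(self):
        with pytest.raises(NewickError):
            read_newick_string("((A:1,B:1):1")

    def test_missing_branch_length_rejected(self):
        with pytest.raises(NewickError, match="branch length"):
            read_newick_string("((A:1,B):1,C:2);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(NewickError, match="duplicate"):
            read_newick_string("((A:1,A:1):1,C:2);")


class TestBmCovariance:
    def test_lambda_scaling(self):
        phy = read_newick_string(BASIC)
        full = bm_covariance(phy, 1.0)
        half = bm_covariance(phy, 0.5)
        none = bm_covariance(phy, 0.0)
        assert full.loc["A", "B"] == pytest.approx(1.0)
        assert half.loc["A", "B"] == pytest.approx(0.5)
        assert none.loc["A", "B"] == 0.0
        for m in (full, half, none):
            assert np.diag(m.to_numpy()) == pytest.approx([2.0, 2.0, 2.0])

    def test_star_tree_diagonal(self):
        phy = read_newick_string("(A:2,B:2,C:2,D:2);")
        C = bm_covariance(phy, 0.7).to_numpy()
        assert C == pytest.approx(np.diag([2.0] * 4))

    def test_psd_for_admissible_lambda(self):
        phy = balanced_tree(4)
        for lam in (0.0, 0.3, 1.0):
            w = np.linalg.eigvalsh(bm_covariance(phy, lam).to_numpy())
            assert w.min() > -1e-10

    def test_out_of_range_lambda_rejected(self):
        phy = read_newick_string(BASIC)
        with pytest.raises(ValueError):
            bm_covariance(phy, 1.2)


class TestLambdaEstimation:
    def test_star_tree_returns_zero(self):
        phy = read_newick_string("(A:2,B:2,C:2,D:2,E:2);")
        y = pd.Series([0.1, 1.0, -0.5, 2.0, 0.3], index=list("ABCDE"))
        est = estimate_lambda(phy, y)
        assert est.lambda_hat == 0.0
        assert est.lrt_p_vs_zero == 1.0

    def test_matches_fine_grid_search(self):
        phy = balanced_tree(4)
        traits = simulate_bm_traits(TraitSimConfig(tree=phy, lambda_true=0.7,
                                                   seed=3))
        y = traits["trait"]
        est = estimate_lambda(phy, y)
        C = phy.vcv().to_numpy()
        grid = np.linspace(0, 1, 1001)
        lls = [_gls_profile_loglik(y.to_numpy(), C, g)[0] for g in grid]
        lam_grid = grid[int(np.argmax(lls))]
        assert abs(est.lambda_hat - lam_grid) < 1e-3  # grid spacing limited
        assert est.log_likelihood >= max(lls) - 1e-9

    def test_recovery_and_shuffle(self):
        phy = balanced_tree(5)
        hats, shuf = [], []
        rng = np.random.default_rng(0)
        for s in range(25):
            y = simulate_bm_traits(TraitSimConfig(tree=phy, lambda_true=1.0,
                                                  seed=s))["trait"]
            hats.append(estimate_lambda(phy, y).lambda_hat)
            ys = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            shuf.append(estimate_lambda(phy, ys).lambda_hat)
        assert np.median(hats) >= 0.9
        assert np.median(shuf) <= 0.1

    def test_optimality_against_boundaries(self):
        phy = balanced_tree(3)
        y = simulate_bm_traits(TraitSimConfig(tree=phy, lambda_true=0.5,
                                              seed=9))["trait"]
        est = estimate_lambda(phy, y)
        C = phy.vcv().to_numpy()
        for lam in (0.0, 1.0):
            assert est.log_likelihood >= \
                _gls_profile_loglik(y.to_numpy(), C, lam)[0] - 1e-9

    def test_affine_invariance(self):
        phy = balanced_tree(4)
        y = simulate_bm_traits(TraitSimConfig(tree=phy, lambda_true=0.8,
                                              seed=11))["trait"]
        e1 = estimate_lambda(phy, y)
        e2 = estimate_lambda(phy, 3.0 * y + 7.0)
        assert e2.lambda_hat == pytest.approx(e1.lambda_hat, abs=1e-5)
        assert e2.sigma2_hat == pytest.approx(9.0 * e1.sigma2_hat, rel=1e-4)

    def test_zero_variance_flagged(self):
        phy = read_newick_string("(A:2,B:2,C:2,D:2);")
        y = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("ABCD"))
        with pytest.raises(ValueError, match="variance"):
            estimate_lambda(phy, y)


class TestPgls:
    def test_lambda_zero_reduces_to_weighted_ols(self):
        phy = balanced_tree(4)
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(size=16), index=phy.tip_labels)
        y = 2.0 + 1.5 * x + pd.Series(rng.normal(scale=0.3, size=16),
                                      index=phy.tip_labels)
        fit = pgls_fit(phy, y, x.to_frame("x"), lam=0.0)
        # ultrametric tree: diag(C) constant, so weighted OLS == OLS
        import statsmodels.api as sm
        ols = sm.OLS(y.to_numpy(),
                     sm.add_constant(x.to_numpy())).fit()
        assert fit.coefficients["estimate"].to_numpy() == \
            pytest.approx(ols.params, rel=1e-9)

    def test_perfect_fit(self):
        phy = balanced_tree(3)
        x = pd.Series(np.arange(8.0), index=phy.tip_labels)
        fit = pgls_fit(phy, 2.0 * x, x.to_frame("x"), lam=1.0)
        assert fit.coefficients.loc["x", "estimate"] == pytest.approx(2.0)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_slope_recovery_under_bm(self):
        phy = balanced_tree(5)
        hits, reps = 0, 25
        for s in range(reps):
            x = simulate_bm_traits(TraitSimConfig(tree=phy, lambda_true=1.0,
                                                  seed=1000 + s))["trait"]
            noise = simulate_bm_traits(TraitSimConfig(
                tree=phy, lambda_true=1.0, sigma2=0.25, seed=2000 + s))["trait"]
            y = 1.5 * x + noise
            fit = pgls_fit(phy, y, x.to_frame("x"), lam="ml")
            b = fit.coefficients.loc["x", "estimate"]
            se = fit.coefficients.loc["x", "se"]
            if abs(b - 1.5) <= 2 * se:
                hits += 1
        assert hits / reps >= 0.8

    def test_rank_deficiency_rejected(self):
        phy = balanced_tree(3)
        x = pd.Series(np.arange(8.0), index=phy.tip_labels)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            pgls_fit(phy, x, X, lam=0.5)


class TestCladeSummaries:
    def _trials(self):
        rng = np.random.default_rng(5)
        rows = []
        for clade, mu in [("A", 100), ("B", 180), ("C", 150), ("D", 110)]:
            for _ in range(12):
                rows.append({"clade": clade,
                             "wf_distance_sl": rng.normal(mu, 20),
                             "wf_time_pct": rng.uniform(40, 90)})
        return pd.DataFrame(rows)

    def test_single_clade_skips_comparisons(self):
        df = self._trials()
        out = clade_summaries(df[df.clade == "B"])
        assert out["comparisons"] == {}
        assert out["summary"].shape[0] == 1

    def test_summary_matches_groupby_oracle(self):
        df = self._trials()
        out = clade_summaries(df)
        for clade in "ABCD":
            expect = df.loc[df.clade == clade, "wf_distance_sl"].mean()
            assert out["summary"].loc[clade, ("wf_distance_sl", "mean")] == \
                pytest.approx(expect)

    def test_shifted_clade_detected(self):
        df = self._trials()
        out = clade_summaries(df)
        kw = out["comparisons"]["wf_distance_sl"]["kruskal_wallis"]
        assert kw.p_value < 0.01
        means = out["summary"][("wf_distance_sl", "mean")]
        assert means.idxmax() == "B"

    def test_small_clade_excluded_with_warning(self):
        df = self._trials()
        df = pd.concat([df, pd.DataFrame([{"clade": "E",
                                           "wf_distance_sl": 1.0,
                                           "wf_time_pct": 1.0}])])
        with pytest.warns(UserWarning, match="excluding"):
            out = clade_summaries(df)
        assert "E" not in out["summary"].index
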