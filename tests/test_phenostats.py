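"""Regression-report identities, published-table derivations, and the
surrounding fold-change / correlation / group-test utilities."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tyquant import phenostats, synthgen
from tyquant.phenostats import (
    derived_stats,
    expression_correlation,
    fit_survival_model,
    fold_change_ddct,
    stress_tests,
    weight_ratio,
)


def random_pheno(n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "survival45": rng.normal(50, 15, n),
            "tula": rng.uniform(60, 80, n),
            "ta2": rng.uniform(0.5, 1.5, n),
        }
    )


def partial_by_residual_regression(df, response, target, other):
    """Oracle: correlate residuals of y~other and x~other."""
    y, x, z = (df[c].to_numpy() for c in (response, target, other))
    Z = np.column_stack([np.ones_like(z), z])
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    return float(np.corrcoef(ry, rx)[0, 1])


class TestFitSurvivalModel:
    @pytest.mark.parametrize("seed", range(5))
    def test_report_identities_on_random_data(self, seed):
        df = random_pheno(8, seed)
        rep = fit_survival_model(df)
        for p in rep.predictors:
            assert p.VIF == pytest.approx(1.0 / p.tolerance)
            assert p.partial == pytest.approx(
                p.t / np.sqrt(p.t**2 + rep.df_resid), abs=1e-12
            )
            assert p.part == pytest.approx(
                p.t * np.sqrt((1 - rep.R2) / rep.df_resid), abs=1e-12
            )
        assert rep.adj_R2 == pytest.approx(
            1 - (1 - rep.R2) * (rep.n - 1) / rep.df_resid, abs=1e-12
        )
        assert rep.F == pytest.approx(
            (rep.R2 / 2) / ((1 - rep.R2) / rep.df_resid), abs=1e-8
        )
        assert rep.R == pytest.approx(np.sqrt(rep.R2))

    @pytest.mark.parametrize("seed", range(5))
    def test_partial_matches_residual_regression_oracle(self, seed):
        df = random_pheno(10, 100 + seed)
        rep = fit_survival_model(df)
        assert rep.predictor("tula").partial == pytest.approx(
            partial_by_residual_regression(df, "survival45", "tula", "ta2"), abs=1e-10
        )
        assert rep.predictor("ta2").partial == pytest.approx(
            partial_by_residual_regression(df, "survival45", "ta2", "tula"), abs=1e-10
        )

    def test_response_equal_to_predictor_limit(self):
        rng = np.random.default_rng(0)
        x1 = rng.uniform(0, 1, 12)
        df = pd.DataFrame({"survival45": x1, "tula": x1, "ta2": rng.uniform(0, 1, 12)})
        rep = fit_survival_model(df)
        assert rep.R2 == pytest.approx(1.0)
        assert abs(rep.predictor("tula").partial) == pytest.approx(1.0)

    def test_noiseless_published_equation_recovered(self):
        df = synthgen.simulate_phenotypes(8, noise_sd=0.0, seed=21)
        rep = fit_survival_model(df)
        assert rep.predictor("tula").B == pytest.approx(-2.39)
        assert rep.predictor("ta2").B == pytest.approx(69.98)
        assert rep.intercept == pytest.approx(152.43)
        assert rep.R2 == pytest.approx(1.0)

    def test_collinear_design_rejected(self):
        df = pd.DataFrame(
            {"survival45": [1.0, 2, 3, 4, 5, 6], "tula": [1.0, 2, 3, 4, 5, 6],
             "ta2": [2.0, 4, 6, 8, 10, 12]}
        )
        with pytest.raises(ValueError):
            fit_survival_model(df)

    def test_empirical_coefficient_spread_tracks_published_SEs(self):
        """At noise_sd = the published SE of estimate, coefficient SDs over
        replicates should be on the order of the printed standard errors."""
        bs = []
        for rep in range(200):
            df = synthgen.simulate_phenotypes(8, noise_sd=9.19, seed=40_000 + rep)
            fit = fit_survival_model(df)
            bs.append((fit.predictor("tula").B, fit.predictor("ta2").B))
        bs = np.asarray(bs)
        # printed SEs: 0.51 (TULA) and 25.98 (Ta2); same order of magnitude
        assert 0.2 < bs[:, 0].std(ddof=1) < 2.0
        assert 10.0 < bs[:, 1].std(ddof=1) < 80.0


class TestDerivedStats:
    def test_published_model_row(self):
        """R2=0.815, k=2, n=8 reproduce the printed F and adjusted R2."""
        d = derived_stats(0.815, 2, 8, [-4.69, 2.69])
        assert d["F"] == pytest.approx(11.014, abs=5e-4)
        assert d["adj_R2"] == pytest.approx(0.741, abs=5e-4)

    def test_published_coefficient_row(self):
        d = derived_stats(0.815, 2, 8, [-4.69, 2.69])
        assert d["partials"][0] == pytest.approx(-0.90, abs=5e-3)
        assert d["partials"][1] == pytest.approx(0.77, abs=5e-3)
        assert d["parts"][0] == pytest.approx(-0.90, abs=5e-3)
        assert d["parts"][1] == pytest.approx(0.52, abs=5e-3)

    def test_df_guard(self):
        with pytest.raises(ValueError):
            derived_stats(0.5, 2, 3, [1.0, 1.0])


class TestWeightRatio:
    def test_published_weights(self):
        w1, w2, ratio = weight_ratio((-0.90, 0.77))
        assert w1 == pytest.approx(0.81)
        assert w2 == pytest.approx(0.5929)
        assert round(ratio, 2) == 1.37

    def test_equal_partials_ratio_one(self):
        assert weight_ratio((0.4, -0.4))[2] == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert weight_ratio((0.5, 0.25))[2] == pytest.approx(4.0)

    def test_zero_partial_flagged(self):
        assert weight_ratio((0.5, 0.0))[2] is None


class TestFoldChange:
    @pytest.mark.parametrize(
        "cts,expected",
        [((20, 20, 20, 20), 1.0), ((19, 20, 22, 22), 2.0), ((20, 18, 22, 18), 4.0)],
    )
    def test_known_values(self, cts, expected):
        assert fold_change_ddct(*cts) == pytest.approx(expected)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError):
            fold_change_ddct(0, 20, 20, 20)


class TestExpressionCorrelation:
    def test_anchor_correlates_with_itself(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(
            rng.uniform(1, 10, (3, 5)), index=["spt23", "g1", "g2"],
        )
        expr.loc["g1"] = expr.loc["spt23"] * 2 + 1  # perfectly correlated
        expr.loc["g2"] = -expr.loc["spt23"]
        res = expression_correlation(expr, "spt23")
        assert res.loc["g1", "r2"] == pytest.approx(1.0) and res.loc["g1", "sign"] == 1
        assert res.loc["g2", "r2"] == pytest.approx(1.0) and res.loc["g2", "sign"] == -1
        assert bool(res.loc["g1", "flag"]) and bool(res.loc["g2", "flag"])

    def test_zero_variance_gene_undefined(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [5.0, 5, 5, 5]], index=["spt23", "flat"]
        )
        res = expression_correlation(expr, "spt23")
        assert not bool(res.loc["flat", "defined"]) and not bool(res.loc["flat", "flag"])

    def test_independent_gene_flag_rate_matches_permutation_oracle(self):
        """With n=4 samples the R2>0.7 flag fires for |r|>~0.837; estimate the
        null rate by permutation and compare to the simulated flag rate."""
        rng = np.random.default_rng(7)
        anchor = rng.normal(size=4)
        flags = 0
        trials = 400
        for _ in range(trials):
            g = rng.normal(size=4)
            r = np.corrcoef(anchor, g)[0, 1]
            flags += (r * r) > 0.7
        sim_rate = flags / trials
        perm_hits = 0
        perms = list(itertools.permutations(range(4)))
        g = rng.normal(size=4)
        for p in perms:
            r = np.corrcoef(anchor, g[list(p)])[0, 1]
            perm_hits += (r * r) > 0.7
        perm_rate = perm_hits / len(perms)
        assert abs(sim_rate - perm_rate) < 0.15


class TestStressTests:
    def test_identical_groups_boundary(self):
        rep = stress_tests({"wt": [5, 5, 5], "mut": [5, 5, 5], "oe": [5, 5, 5]})
        assert rep.kruskal_p == 1.0
        assert (rep.pairwise["wilcoxon_p_bh"] == 1.0).all()

    def test_bh_hand_example(self):
        # BH on (0.01, 0.02, 0.04) -> (0.03, 0.03, 0.04)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        groups = {
            "a": rng.normal(10, 1, 6),
            "b": rng.normal(10, 1, 6),
            "c": rng.normal(15, 1, 6),  # 5 sigma shift
        }
        rep = stress_tests(groups)
        assert rep.kruskal_p < 0.05
        kw = stats.kruskal(*groups.values())  # scipy as direct cross-check
        assert rep.kruskal_p == pytest.approx(float(kw.pvalue))

    def test_bh_monotone_and_never_decreases(self):
        rng = np.random.default_rng(9)
        groups = {g: rng.normal(10 + i, 2, 5) for i, g in enumerate("abcd")}
        rep = stress_tests(groups)
        pw = rep.pairwise.sort_values("wilcoxon_p")
        assert (pw["wilcoxon_p_bh"].to_numpy() >= pw["wilcoxon_p"].to_numpy() - 1e-12).all()
        assert (np.diff(pw["wilcoxon_p_bh"].to_numpy()) >= -1e-12).all()
        assert (np.diff(pw.sort_values("dunn_p")["dunn_p_bh"].to_numpy()) >= -1e-12).all()

    def test_dunn_z_matches_manual_computation(self):
        groups = {"a": [1.0, 2, 3], "b": [4.0, 5, 6], "c": [7.0, 8, 9]}
        rep = stress_tests(groups)
        # no ties: var_base = N(N+1)/12 = 9*10/12 = 7.5; mean ranks 2, 5, 8
        row = rep.pairwise.set_index(["group_a", "group_b"]).loc[("a", "b")]
        expected_z = (2 - 5) / np.sqrt(7.5 * (1 / 3 + 1 / 3))
        assert row["dunn_z"] == pytest.approx(expected_z)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError):
            stress_tests({"a": [1, 2], "b": [1, 2, 3]})
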