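"""Regression models, heteroskedasticity tests, influence diagnostics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.stats.diagnostic as smd
from hypothesis import given, settings, strategies as st
from scipy import stats

from neotheta import outcome, synth


def _df(x, y, extra=None):
    d = {"y": y, "x": x}
    if extra is not None:
        d["z"] = extra
    return pd.DataFrame(d)


class TestOutlierScreen:
    def test_small_sample_masking_is_the_documented_behaviour(self):
        """(10,12,11,13,200): the outlier inflates the SD enough to
        stay below mean + 3·SD, so it is kept."""
        tbl = pd.DataFrame({"participant_id": list("abcde"),
                            "prod12": [10, 12, 11, 13, 200]})
        out, removed = outcome.remove_vocab_outliers(tbl)
        assert removed == []
        assert len(out) == 5

    def test_outlier_beyond_bound_removed(self):
        # a single extreme among equals reaches z = (n−1)/√n including
        # itself; that exceeds 3 only for n ≥ 12 (11/√12 ≈ 3.18)
        vals = [10.0] * 11 + [10000.0]
        tbl = pd.DataFrame({"participant_id": [f"p{i}" for i in range(12)],
                            "prod12": vals})
        out, removed = outcome.remove_vocab_outliers(tbl)
        assert removed == ["p11"]
        assert len(out) == 11

    def test_equal_values_none_removed(self):
        tbl = pd.DataFrame({"participant_id": list("abcd"),
                            "prod12": [5, 5, 5, 5]})
        out, removed = outcome.remove_vocab_outliers(tbl)
        assert removed == [] and len(out) == 4

    def test_value_exactly_at_bound_kept(self):
        # solve for the value that sits exactly at mean + 3·SD of the
        # group that includes it (needs n ≥ 12 so z = 3 is reachable)
        base = pd.Series([10.0] * 13 + [12.0])
        from scipy.optimize import brentq

        def gap(v):
            s = pd.concat([base, pd.Series([v])], ignore_index=True)
            return v - (s.mean() + 3 * s.std(ddof=1))

        v = brentq(gap, 13.0, 1e6)
        at_bound = v - 1e-6  # at the bound up to solver tolerance
        tbl = pd.DataFrame({"participant_id": [f"p{i}" for i in range(15)],
                            "prod12": list(base) + [at_bound]})
        out, removed = outcome.remove_vocab_outliers(tbl)
        assert removed == []  # strict ">" at the bound
        tbl.loc[14, "prod12"] = v + 1.0
        out, removed = outcome.remove_vocab_outliers(tbl)
        assert removed == ["p14"]


class TestLinearModel:
    def test_matches_normal_equations_oracle(self, rng):
        x = rng.normal(size=40)
        z = rng.normal(size=40)
        y = 1.0 + 0.5 * x - 1.2 * z + rng.normal(size=40)
        rep = outcome.fit_linear_model(_df(x, y, z), "y", ["x", "z"])
        X = np.column_stack([np.ones(40), x, z])
        beta_hat = np.linalg.pinv(X) @ y
        assert rep.coef["x"] == pytest.approx(beta_hat[1], abs=1e-8)
        assert rep.coef["z"] == pytest.approx(beta_hat[2], abs=1e-8)

    def test_single_predictor_identities(self, rng):
        """Beta = sign(b)·R, F = t², R² = r² for univariate models."""
        x = rng.normal(size=30)
        y = -0.6 * x + rng.normal(size=30)
        rep = outcome.fit_linear_model(_df(x, y), "y", ["x"])
        r, _ = stats.pearsonr(x, y)
        assert rep.beta["x"] == pytest.approx(r, abs=1e-9)
        assert abs(rep.beta["x"]) == pytest.approx(rep.R, abs=1e-9)
        assert rep.r_square == pytest.approx(r ** 2, abs=1e-9)
        t = rep._results.tvalues["x"]
        assert rep.F == pytest.approx(t ** 2, rel=1e-9)
        assert rep.p_model == pytest.approx(rep.p_coef["x"], rel=1e-9)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0),
           st.floats(0.1, 20.0))
    def test_standardization_invariance(self, sx, shift, sy):
        rng = np.random.default_rng(2024)
        x = rng.normal(size=25)
        y = 0.7 * x + rng.normal(size=25)
        base = outcome.fit_linear_model(_df(x, y), "y", ["x"])
        scaled = outcome.fit_linear_model(_df(sx * x + shift, sy * y),
                                          "y", ["x"])
        assert scaled.beta["x"] == pytest.approx(base.beta["x"], abs=1e-9)
        assert scaled.R == pytest.approx(base.R, abs=1e-9)
        assert scaled.F == pytest.approx(base.F, rel=1e-7)
        assert scaled.p_model == pytest.approx(base.p_model, rel=1e-6)

    def test_perfect_fit_handled(self):
        x = np.arange(10.0)
        rep = outcome.fit_linear_model(_df(x, x), "y", ["x"])
        assert rep.beta["x"] == pytest.approx(1.0)
        assert rep.r_square == pytest.approx(1.0)
        assert 0 < rep.p_model <= 1e-20

    def test_collinear_design_rejected(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            outcome.fit_linear_model(_df(x, rng.normal(size=20), 2 * x),
                                     "y", ["x", "z"])

    def test_listwise_deletion_is_per_model(self):
        tbl = pd.DataFrame({
            "y": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0],
            "x": [0.1, 0.3, 0.2, np.nan, 0.5, 0.4, 0.6],
        })
        rep = outcome.fit_linear_model(tbl, "y", ["x"])
        assert rep.n == 5


class TestFStatisticIdentities:
    def test_f_from_reported_r(self):
        assert outcome.f_from_r(0.484, 22) == pytest.approx(6.110, abs=0.02)
        assert outcome.f_from_r(0.491, 24) == pytest.approx(6.988, abs=0.02)
        assert outcome.f_from_r(0.724, 20) == pytest.approx(19.830, abs=0.02)

    def test_bonferroni(self):
        assert outcome.bonferroni(0.05, 2) == 0.025
        assert outcome.bonferroni(0.05, 1) == 0.05
        assert outcome.bonferroni(0.05, 5) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            outcome.bonferroni(0.05, 0)


class TestHeteroskedasticityTests:
    def _fit(self, rng, n=60, het=0.0):
        x = rng.normal(size=n)
        noise = rng.normal(size=n) * (1.0 + het * np.abs(x))
        y = 1.0 + 2.0 * x + noise
        return outcome.fit_linear_model(_df(x, y), "y", ["x"])

    def test_breusch_pagan_matches_statsmodels(self, rng):
        rep = self._fit(rng, het=0.5)
        X = sm.add_constant(rep._data[["x"]])
        ours = outcome.breusch_pagan(rep)
        ref = smd.het_breuschpagan(rep._results.resid, X)
        assert ours[0] == pytest.approx(ref[0], rel=1e-10)
        assert ours[1] == pytest.approx(ref[1], rel=1e-10)
        ours_ess = outcome.breusch_pagan(rep, variant="ess")
        ref_ess = smd.het_breuschpagan(rep._results.resid, X, robust=False)
        assert ours_ess[0] == pytest.approx(ref_ess[0], rel=1e-10)

    def test_white_matches_statsmodels(self, rng):
        rep = self._fit(rng, het=0.5)
        X = sm.add_constant(rep._data[["x"]])
        ours = outcome.white_test(rep)
        ref = smd.het_white(rep._results.resid, X)
        assert ours[0] == pytest.approx(ref[0], rel=1e-10)
        assert ours[1] == pytest.approx(ref[1], rel=1e-10)

    def test_white_reduces_to_bp_on_restricted_aux(self, rng):
        rep = self._fit(rng)
        aux = rep._data[["x"]].to_numpy()
        restricted = outcome._lm_het_test(rep._results.resid, aux)
        assert restricted == outcome.breusch_pagan(rep)

    def test_single_predictor_chi2_dfs(self, rng):
        rep = self._fit(rng, het=1.5, n=400)
        bp_stat, bp_p = outcome.breusch_pagan(rep)
        assert bp_p == pytest.approx(stats.chi2.sf(bp_stat, 1))
        w_stat, w_p = outcome.white_test(rep)
        assert w_p == pytest.approx(stats.chi2.sf(w_stat, 2))

    def test_homoskedastic_calibration(self):
        hits = 0
        for s in range(200):
            rep = self._fit(np.random.default_rng(s), n=400, het=0.0)
            hits += outcome.breusch_pagan(rep)[1] <= 0.05
        assert 0.015 <= hits / 200 <= 0.10

    def test_power_against_heteroskedastic_alternatives(self):
        """BP detects variance monotone in x; only White (which carries
        the x² auxiliary term) detects variance symmetric in x."""
        bp_hits = white_hits = bp_blind = 0
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            x = np.abs(rng.normal(size=2000))
            y = 1.0 + 2.0 * x + rng.normal(size=2000) * x  # var ∝ x²
            rep = outcome.fit_linear_model(_df(x, y), "y", ["x"])
            bp_hits += outcome.breusch_pagan(rep)[1] < 0.001
            xs = rng.normal(size=2000)  # symmetric design
            ys = 1.0 + 2.0 * xs + rng.normal(size=2000) * np.abs(xs)
            rep2 = outcome.fit_linear_model(_df(xs, ys), "y", ["x"])
            white_hits += outcome.white_test(rep2)[1] < 0.001
            bp_blind += outcome.breusch_pagan(rep2)[1] < 0.001
        assert bp_hits >= 19
        assert white_hits >= 19
        assert bp_blind <= 5  # symmetric alternative invisible to BP

    def test_degenerate_residuals(self):
        x = np.arange(8.0)
        rep = outcome.fit_linear_model(_df(x, 2 * x), "y", ["x"])
        assert outcome.breusch_pagan(rep) == (0.0, 1.0)


class TestInfluence:
    def test_mean_leverage_identity(self, rng):
        x = rng.normal(size=27)
        y = 0.4 * x + rng.normal(size=27)
        rep = outcome.fit_linear_model(_df(x, y), "y", ["x"])
        diag = outcome.influence_diagnostics(rep)
        assert diag["mean_leverage"] == pytest.approx(2.0 / 27.0)
        assert round(diag["mean_leverage"], 2) == 0.07
        assert diag["leverage"].sum() == pytest.approx(2.0, abs=1e-9)

    def test_duplicating_rows_halves_leverage(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        rep1 = outcome.fit_linear_model(_df(x, y), "y", ["x"])
        d1 = outcome.influence_diagnostics(rep1)
        rep2 = outcome.fit_linear_model(
            _df(np.tile(x, 2), np.tile(y, 2)), "y", ["x"])
        d2 = outcome.influence_diagnostics(rep2)
        np.testing.assert_allclose(d2["leverage"][:15], d1["leverage"] / 2.0,
                                   atol=1e-10)

    def test_influence_rule_is_strict(self, rng):
        x = np.concatenate([rng.normal(size=18), [6.0]])
        y = x + rng.normal(size=19)
        rep = outcome.fit_linear_model(_df(x, y), "y", ["x"])
        diag = outcome.influence_diagnostics(rep)
        assert diag["influential_index"]  # the planted extreme is flagged
        # a factor placing the bound exactly at the maximum leverage
        # flags nothing (strict ">")
        factor = diag["leverage"].max() / diag["mean_leverage"]
        diag2 = outcome.influence_diagnostics(rep, leverage_factor=factor)
        assert diag2["influential_index"] == []

    def test_refit_without_removals_is_identical(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        tbl = _df(x, y)
        rep = outcome.fit_linear_model(tbl, "y", ["x"], model_id="3")
        again = outcome.refit_without_influential(tbl, "y", ["x"], [],
                                                  model_id="3'")
        assert again.n == rep.n
        assert again.F == pytest.approx(rep.F)


class TestPearson:
    def test_identity_and_permutation(self, rng):
        x = rng.normal(size=50)
        r, p, n = outcome.pearson_correlation(x, x)
        assert r == pytest.approx(1.0)
        r2, _, _ = outcome.pearson_correlation(x, rng.permutation(x))
        assert abs(r2) < 0.3

    def test_reported_r_to_p_mapping(self):
        assert outcome.p_from_r(0.497, 27) == pytest.approx(0.008, abs=0.001)

    def test_zero_variance_sentinel(self):
        r, p, n = outcome.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r) and np.isnan(p)

    def test_pairwise_complete(self):
        r, p, n = outcome.pearson_correlation([1, 2, 3, np.nan, 5],
                                              [2, 4, 6, 8, np.nan])
        assert n == 3 and r == pytest.approx(1.0)


class TestPathAnalysis:
    def _patterned_table(self, rng):
        """29-participant cohort with the reported missingness pattern:
        22 contribute at 12 months, 27 at 18 months, 20 at both."""
        n = 29
        x = rng.normal(0.2, 0.3, size=n)
        tbl = pd.DataFrame({
            "participant_id": [f"P{i:02d}" for i in range(n)],
            "discrimination_0m": x,
            "comp12": np.round(30 + 15 * (0.5 * x / 0.3
                                          + rng.normal(size=n))),
            "prod12": np.round(30 + 15 * rng.normal(size=n)).clip(0),
            "comp18": np.round(60 + 20 * (0.4 * x / 0.3
                                          + rng.normal(size=n))),
            "prod18": np.round(60 + 20 * rng.normal(size=n)).clip(0),
        })
        tbl.loc[22:, ["comp12", "prod12"]] = np.nan       # 22 with 12-mo data
        tbl.loc[:1, ["comp18", "prod18"]] = np.nan        # 27 with 18-mo data
        return tbl

    def test_per_model_sample_sizes_follow_attrition(self, rng):
        report = outcome.run_path_analysis(self._patterned_table(rng),
                                           screen_outliers=False)
        assert [report.models[m].n for m in "123456"] == [22, 22, 27, 27,
                                                          20, 20]
        assert report.adjusted_alpha == 0.025

    def test_posthoc_models_emitted_per_rules(self, rng):
        tbl = self._patterned_table(rng)
        # plant an influential case in the 18-month models
        tbl.loc[10, "discrimination_0m"] = 2.5
        report = outcome.run_path_analysis(tbl, screen_outliers=False)
        assert report.influential_ids
        assert "3'" in report.posthoc and "4'" in report.posthoc
        # influential cases come from the 18-month fits, so each removal
        # shrinks the 18-month sample one-for-one
        assert report.posthoc["3'"].n == 27 - len(report.influential_ids)
        # 5'/6' appear only when a predictor was dropped but one survived
        for mid in ("5", "6"):
            rep = report.models[mid]
            kept = [x_ for x_ in rep.independents
                    if rep.p_coef[x_] <= report.adjusted_alpha]
            if kept and len(kept) < 2:
                assert mid + "'" in report.posthoc
                assert report.posthoc[mid + "'"].independents == tuple(kept)

    def test_edges_and_table_outputs(self, rng):
        report = outcome.run_path_analysis(self._patterned_table(rng),
                                           screen_outliers=False)
        table = report.table()
        assert {"model", "R", "F", "p", "n"} <= set(table.columns)
        edges = report.edges()
        assert any(e["from"] == "discrimination_0m" and e["to"] == "comp12"
                   for e in edges)
        assert "comp18~prod18" in report.correlations

    def test_recovery_of_generating_beta_on_synthetic_cohorts(self):
        """Mean standardized beta over replicates tracks the generating
        β = 0.484 (small attenuation from count rounding)."""
        ests = []
        for s in range(60):
            cfg = synth.SimConfig(n_participants=22, p_obs_12=1.0,
                                  p_obs_18=1.0)
            tbl = synth.simulate_outcome_table(cfg, s)
            rep = outcome.fit_linear_model(tbl, "comp12",
                                           ["discrimination_0m"], "1")
            ests.append(rep.beta["discrimination_0m"])
        assert np.mean(ests) == pytest.approx(0.484, abs=0.06)
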