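"""Analysis catalogue, adjustment methods, risk difference, forest table."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import steppedwedge as sw
from steppedwedge.analyses import (AdjustmentSpec, build_design,
                                   prepare_population)
from steppedwedge.design import CONTROL, INTERVENTION
from steppedwedge.glmm import DesignMatrices


class TestCatalogueFidelity:
    """Each model code carries exactly its documented structure."""

    @pytest.mark.parametrize(
        "code, population, timing, time_trend, season, exposure, random",
        [
            ("A", "full", "actual", "linear", True, "none", "intercept"),
            ("B", "calendar_matched", "actual", "none", False, "none", "intercept"),
            ("C", "full", "actual", "linear", True, "none", "intercept+intervention"),
            ("D", "randomisation_phase", "actual", "linear", True, "none", "intercept"),
            ("E", "full", "planned", "linear", True, "none", "intercept"),
            ("F", "full", "actual", "linear", True, "none", "intercept+time"),
            ("G", "full", "actual", "linear", True, "linear", "intercept"),
            ("H", "full", "actual", "spline", True, "none", "intercept"),
            ("I", "full", "actual", "spline", True, "spline", "intercept"),
            ("J", "full", "actual", "categorical_3mo", False, "none", "intercept"),
            ("K", "full", "actual", "categorical_3mo", False, "spline", "intercept"),
        ],
    )
    def test_model_spec_fields(self, code, population, timing, time_trend,
                               season, exposure, random):
        spec = sw.MODEL_CATALOGUE[code]
        assert spec.population == population
        assert spec.timing == timing
        assert spec.time_trend == time_trend
        assert spec.season is season
        assert spec.exposure == exposure
        assert spec.random == random

    def test_adjustment_covariate_lists(self):
        afd = AdjustmentSpec.of("AFD")
        assert list(afd.covariates) == ["age", "sex", "simd"]
        for m in ("AMC", "APS", "IPTW"):
            cov = list(AdjustmentSpec.of(m).covariates)
            assert len(cov) == 13
            assert set(cov) == set(sw.FULL_COVARIATES)
        assert AdjustmentSpec.of("none").covariates == ()
        with pytest.raises(ValueError, match="unknown adjustment"):
            AdjustmentSpec.of("matching")


class TestDesignAssembly:
    def test_model_a_columns(self, derived_replica, design):
        dm = build_design(derived_replica, design, sw.MODEL_CATALOGUE["A"])
        assert dm.columns == ["intercept", "intervention", "season_Spring",
                              "season_Summer", "season_Autumn", "time"]

    def test_model_b_has_no_time_or_season(self, replica, design):
        spec = sw.MODEL_CATALOGUE["B"]
        pop = prepare_population(replica, design, spec)
        dm = build_design(pop, design, spec)
        assert dm.columns == ["intercept", "intervention"]

    def test_model_j_categorical_time_no_season(self, derived_replica, design):
        dm = build_design(derived_replica, design, sw.MODEL_CATALOGUE["J"])
        assert not any(c.startswith("season") for c in dm.columns)
        periods = [c for c in dm.columns if c.startswith("period_")]
        assert len(periods) == 7   # 8 three-month bins, first as reference
        assert "time" not in dm.columns

    def test_spline_models_column_counts(self, derived_replica, design):
        dm_h = build_design(derived_replica, design, sw.MODEL_CATALOGUE["H"])
        assert sum(c.startswith("time_ns") for c in dm_h.columns) == 4
        dm_i = build_design(derived_replica, design, sw.MODEL_CATALOGUE["I"])
        assert sum(c.startswith("exposure_ns") for c in dm_i.columns) == 4

    def test_planned_timing_changes_conditions(self, replica, design):
        a = prepare_population(replica, design, sw.MODEL_CATALOGUE["A"])
        e = prepare_population(replica, design, sw.MODEL_CATALOGUE["E"])
        diff = (a["condition"].to_numpy() != e["condition"].to_numpy()).sum()
        assert diff > 0
        cross_p = a["site"].map(design.planned_crossover_day)
        cross_a = a["site"].map(design.actual_crossover_day)
        between = ((a["day"] >= np.minimum(cross_a, cross_p))
                   & (a["day"] < np.maximum(cross_a, cross_p)))
        assert diff == int(between.sum())


class TestPropensity:
    def test_weight_identities(self):
        p = np.array([0.5, 0.2, 0.8])
        Z = np.array([1.0, 0.0, 1.0])
        w = Z / p + (1 - Z) / (1 - p)
        assert w[0] == 2.0
        assert np.isclose(w[1], 1.25)
        assert (w >= 1).all()

    def test_no_confounding_gives_flat_propensity(self, small_cohort, design):
        work = prepare_population(small_cohort, design, sw.MODEL_CATALOGUE["A"])
        ps = sw.estimate_propensity(work)
        # covariates are independent of condition in the generator
        assert np.std(ps.logit_p) < 0.15
        unadj = sw.run_analysis(small_cohort, design, "A", "none", method="laplace")
        aps = sw.run_analysis(small_cohort, design, "A", "APS", method="laplace", ps=ps)
        assert abs(np.log(aps.effect["estimate"]) - np.log(unadj.effect["estimate"])) < 0.05

    def test_single_condition_population_rejected(self, replica, design):
        validation = replica[replica["day"] < design.validation_end_day]
        work = sw.derive(validation, design)
        with pytest.raises(ValueError, match="both conditions"):
            sw.estimate_propensity(work)

    def test_iptw_group_constant_weights_leave_or_unchanged(self):
        """If weights are constant within condition, the 2x2 sufficiency of
        the unadjusted logistic model leaves the intervention OR unchanged."""
        rng = np.random.default_rng(6)
        n, C = 4000, 7
        ci = rng.integers(0, C, n)
        z = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < expit(-3.5 + 0.7 * z)).astype(float)
        X = np.column_stack([np.ones(n), z])
        names = ["intercept", "intervention"]
        base = sw.fit_logistic_glmm(DesignMatrices(
            X=X, columns=names, y=y, cluster_index=ci,
            cluster_labels=list(range(C))), method="laplace")
        w = np.where(z == 1, 1.8, 1.3)
        weighted = sw.fit_logistic_glmm(DesignMatrices(
            X=X, columns=names, y=y, cluster_index=ci,
            cluster_labels=list(range(C)), weights=w), method="laplace")
        assert np.isclose(weighted.beta["intervention"],
                          base.beta["intervention"], atol=1e-5)


class TestRunAnalysis:
    def test_null_dataset_recovers_or_near_one(self, design):
        params = sw.CohortParams(safety_baseline_logit=float(logit(0.02)))
        df = sw.generate_parametric(design, params, n=8000, seed=17)
        fit = sw.run_analysis(df, design, "B", "none", method="laplace")
        assert fit.effect["ci_low"] < 1.0 < fit.effect["ci_high"]

    def test_full_grid_enumeration(self, small_cohort, design):
        """The complete code x adjustment grid yields 55 labelled results."""
        results = sw.run_suite(small_cohort, design, method="laplace")
        assert len(results) == 55
        labels = {f.label for f in results}
        assert len(labels) == 55
        assert "A" in labels and "K-IPTW" in labels
        assert all(f.effect["scale"] == "OR" for f in results)

    def test_adjustment_reduces_bias_under_confounding_drift(self, design):
        """With covariate means drifting over time and affecting the outcome,
        covariate-adjusted before/after LOS estimates sit closer to the
        generating truth than unadjusted ones, on average over replicates.
        The before/after comparison (code B) is the vulnerable one: it has no
        model-based time adjustment to absorb the drift."""
        rng = np.random.default_rng(99)
        truth = np.log(0.78)
        err = {m: [] for m in ("none", "AMC", "APS", "IPTW")}
        for rep in range(25):
            params = sw.CohortParams(
                confounding_drift={"age": 0.02, "hx_ihd": 0.004},
                los_log_sd=0.5, seed=int(rng.integers(2**31)))
            df = sw.generate_parametric(design, params, n=2500)
            # make the drifting covariates affect LOS directly
            df["los_hours"] = df["los_hours"] * np.exp(
                0.01 * (df["age"] - 59) + 0.3 * df["hx_ihd"])
            for m in err:
                fit = sw.run_analysis(df, design, "B", m, outcome="los")
                err[m].append(np.log(fit.effect["estimate"]) - truth)
        mean_abs = {m: np.mean(np.abs(v)) for m, v in err.items()}
        assert mean_abs["AMC"] < mean_abs["none"]
        assert mean_abs["APS"] < mean_abs["none"]
        assert mean_abs["IPTW"] < mean_abs["none"]


class TestRiskDifference:
    def _fit_and_dm(self, df, design, code="A", method="laplace"):
        spec = sw.MODEL_CATALOGUE[code].for_outcome("safety")
        pop = prepare_population(df, design, spec)
        dm = build_design(pop, design, spec)
        fit = sw.fit_logistic_glmm(dm, method=method)
        return fit, dm

    def test_null_fit_gives_zero_rd(self, design):
        rng = np.random.default_rng(8)
        df = sw.generate_parametric(design, n=4000, seed=8)
        fit, dm = self._fit_and_dm(df, design)
        fit.beta["intervention"] = 0.0
        rd, lo, hi = sw.approximate_risk_difference(fit, dm)
        assert rd == 0.0
        assert lo < 0 < hi

    def test_homogeneous_population_closed_form(self, design):
        """With no covariates, the average marginal effect equals
        p1 - p0 where logit p1 = logit p0 + log OR."""
        rng = np.random.default_rng(9)
        n, C = 6000, 7
        ci = rng.integers(0, C, n)
        z = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < expit(-3.0 + 0.8 * z)).astype(float)
        dm = DesignMatrices(
            X=np.column_stack([np.ones(n), z]), columns=["intercept", "intervention"],
            y=y, cluster_index=ci, cluster_labels=list(range(C)))
        fit = sw.fit_logistic_glmm(dm, method="laplace")
        rd, lo, hi = sw.approximate_risk_difference(fit, dm)
        b0, b1 = fit.beta["intercept"], fit.beta["intervention"]
        closed = 100 * (expit(b0 + b1) - expit(b0))
        assert np.isclose(rd, closed, atol=1e-9)
        assert np.sign(rd) == np.sign(b1)


class TestForestTable:
    def _mk(self, label, est, lo, hi, scale="OR"):
        from steppedwedge.glmm import FitResult
        beta = pd.Series([np.log(est)], index=["intervention"])
        cov = pd.DataFrame([[0.01]], index=["intervention"], columns=["intervention"])
        f = FitResult(beta=beta, cov_beta=cov, random_effect_sd={}, loglik=0.0,
                      converged=True, n_used=100, method="Laplace")
        f.effect = {"scale": scale, "estimate": est, "ci_low": lo, "ci_high": hi}
        f.label = label
        return f

    def test_single_row_and_scale_column(self):
        tab = sw.forest_table([self._mk("A", 1.5, 0.9, 2.5)])
        assert len(tab) == 1
        mixed = sw.forest_table([
            self._mk("A", 1.5, 0.9, 2.5, "OR"),
            self._mk("A", 0.8, 0.7, 0.9, "GMR"),
        ])
        assert set(mixed["scale"]) == {"OR", "GMR"}

    def test_divergence_flag_for_non_overlapping_cis(self):
        tab = sw.forest_table([
            self._mk("A", 2.0, 1.0, 4.0),
            self._mk("B", 0.5, 0.3, 0.8),     # CI entirely below A's
            self._mk("D", 1.8, 0.9, 3.5),
        ])
        flags = dict(zip(tab["label"], tab["divergent"]))
        assert flags["B"] and not flags["D"] and not flags["A"]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sw.forest_table([])
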