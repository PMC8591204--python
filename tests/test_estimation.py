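import numpy as np
import pandas as pd
import pytest

import meropk as mp
from meropk.estimation import (
    CovariateEffect,
    EstimationError,
    ModelStructure,
    _ofv_core,
    _params_from_model,
    _prepare,
    final_structure,
)

from _oracles import quadrature_ofv_1subject, wls_deviance
from conftest import add_decoy_covariates


def _one_subject_dataset(times, dv, dose=1000.0, t_inf=3.0, crcl=49.7, lpm=3.7):
    rows = [dict(ID=1, TIME=0.0, AMT=dose, RATE=dose / t_inf, EVID=1, MDV=1,
                 DV=np.nan, CRCL=crcl, LPM=lpm, BLQ=0)]
    for t, y in zip(times, dv):
        rows.append(dict(ID=1, TIME=t, AMT=0.0, RATE=0.0, EVID=0, MDV=0,
                         DV=y, CRCL=crcl, LPM=lpm, BLQ=0))
    return mp.PKDataset(pd.DataFrame(rows))


class TestFoceObjective:
    def test_zero_bsv_equals_weighted_least_squares(self, model, cohort):
        """With all omegas zero the FOCE objective is the fixed-effects
        WLS deviance, computed here by an independently coded closed form."""
        frozen = model.replace(omega_CL=0.0, omega_Vc=0.0, omega_Vp=0.0)
        ofv = mp.foce_objective(frozen, cohort)
        expected = 0.0
        for sid, g in cohort.df.groupby("ID"):
            obs = g[(g["EVID"] == 0) & (g["TIME"] > 0)]
            dose = g[g["EVID"] == 1].iloc[0]
            cov = mp.CovariateVector(crcl=obs["CRCL"].iloc[0], lpm=obs["LPM"].iloc[0])
            p = mp.typical_params(frozen, cov)
            r = mp.DosingRegimen(dose["AMT"], dose["AMT"] / dose["RATE"], 24.0)
            f = mp.concentration_single_dose(p, r, obs["TIME"].to_numpy())
            expected += wls_deviance(obs["DV"].to_numpy(), f,
                                     frozen.sigma_add, frozen.sigma_prop)
        assert ofv == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("omega", [0.1, 0.3, 0.5])
    def test_matches_quadrature_oracle_one_subject(self, model, omega):
        """FOCE-I vs exact marginal -2 log L by adaptive quadrature, one
        subject with BSV on CL only and additive error."""
        times = np.array([3.33, 4.0, 5.0, 6.0, 8.0])
        cov = mp.CovariateVector(crcl=49.7, lpm=3.7)
        toy = model.replace(omega_CL=omega, omega_Vc=0.0, omega_Vp=0.0,
                            sigma_add=0.5, sigma_prop=0.0)
        typ = mp.typical_params(toy, cov)
        r = mp.DosingRegimen(1000, 3.0, 24.0)
        truth = mp.concentration_single_dose(
            mp.StructuralParams(typ.CL * np.exp(0.2), typ.Vc, typ.Vp, typ.Q), r, times)
        rng = np.random.default_rng(17)
        dv = truth + 0.5 * rng.standard_normal(len(times))
        data = _one_subject_dataset(times, dv)

        ofv = mp.foce_objective(toy, data)

        def conc_of_eta(eta):
            p = mp.StructuralParams(typ.CL * np.exp(eta), typ.Vc, typ.Vp, typ.Q)
            return mp.concentration_single_dose(p, r, times)

        oracle = quadrature_ofv_1subject(dv, times, conc_of_eta, omega, 0.5)
        assert ofv == pytest.approx(oracle, abs=0.1)

    def test_mdv_rows_ignored(self, model, cohort):
        base = mp.foce_objective(model, cohort)
        df = cohort.df.copy()
        extra = df[(df["ID"] == 1) & (df["EVID"] == 0)].iloc[[3]].copy()
        extra["MDV"] = 1
        extra["DV"] = 999.0
        df = pd.concat([df, extra]).sort_values(["ID", "TIME"], kind="stable")
        assert mp.foce_objective(model, mp.PKDataset(df.reset_index(drop=True))) \
            == pytest.approx(base, abs=1e-9)

    def test_subject_relabeling_invariance(self, model, cohort):
        base = mp.foce_objective(model, cohort)
        df = cohort.df.copy()
        relabel = {sid: 1000 - sid for sid in df["ID"].unique()}
        df["ID"] = df["ID"].map(relabel)
        assert mp.foce_objective(model, mp.PKDataset(df)) == pytest.approx(base, abs=1e-6)

    def test_degenerate_residual_model_rejected(self, model, cohort):
        broken = model.replace(sigma_add=0.0, sigma_prop=0.0)
        with pytest.raises(EstimationError):
            mp.foce_objective(broken, cohort)


class TestFit:
    def test_descent_from_truth(self, model, cohort):
        """Starting the optimiser at the data-generating parameters can only
        decrease the objective."""
        truth_ofv = mp.foce_objective(model, cohort)
        res = mp.fit(cohort, model, compute_rse=False)
        assert res.ofv <= truth_ofv + 1e-6
        assert res.converged

    def test_estimates_reasonable_and_shrinkage_bounded(self, model, cohort):
        res = mp.fit(cohort, model, compute_rse=False)
        assert 0.5 * 7.35 < res.estimates["CL"] < 2 * 7.35
        assert res.model is not None
        for v in res.shrinkage.values():
            assert 0.0 <= v <= 100.0
        assert res.ebes.shape == (30, 3)

    def test_rse_available_on_demand(self, model, cohort):
        res = mp.fit(cohort, model)
        assert res.rse is not None
        assert all(v > 0 for v in res.rse.values())
        # typical clearance is well identified in this design
        assert res.rse["CL"] < 30.0

    def test_rich_design_tightens_fixed_effects(self, model):
        """Consistency: a larger cohort with wider covariate spread recovers
        the fixed effects much more tightly than the 30-subject study."""
        from meropk.synthesis import LognormalSpec

        spec = mp.CohortSpec(
            n_subjects=150, n_alt_dose=0,
            crcl_non_crrt=LognormalSpec(69.6, 32.0, 151.0),
            lpm_non_crrt=LognormalSpec(3.62, 2.2, 6.0),
            crcl_crrt=LognormalSpec(43.4, 25.0, 75.0),
            lpm_crrt=LognormalSpec(3.83, 2.5, 5.9),
        )
        data = mp.simulate_dataset(spec, model, seed=77)
        res = mp.fit(data, model, compute_rse=False)
        truth = _params_from_model(model)
        for k in ("CL", "Vc", "Q", "Vp"):
            assert res.estimates[k] == pytest.approx(truth[k], rel=0.12)
        for k in ("beta_CRCL_CL", "beta_LPM_Vc"):
            assert res.estimates[k] == pytest.approx(truth[k], rel=0.25)


class TestCompareNested:
    def test_threshold_logic(self):
        full = mp.FitResult({}, ModelStructure(), ofv=100.0, converged=True, message="")
        red1 = mp.FitResult({}, ModelStructure(), ofv=104.0, converged=True, message="")
        delta, sig = mp.compare_nested(full, red1, df=1)
        assert delta == pytest.approx(4.0) and sig

        red2 = mp.FitResult({}, ModelStructure(), ofv=105.0, converged=True, message="")
        delta, sig = mp.compare_nested(full, red2, df=2)
        assert delta == pytest.approx(5.0) and not sig

    def test_unsupported_df_rejected(self):
        f = mp.FitResult({}, ModelStructure(), ofv=0.0, converged=True, message="")
        with pytest.raises(ValueError):
            mp.compare_nested(f, f, df=3)


class TestStepwise:
    def test_no_candidates_returns_base_model(self, model, cohort):
        res, trace = mp.stepwise_covariate_search(cohort, [], model)
        assert trace.steps == []
        assert res.structure.effects == ()

    def test_missing_column_rejected(self, model, cohort):
        with pytest.raises(EstimationError, match="NOPE"):
            mp.stepwise_covariate_search(cohort, [("NOPE", "CL")], model)

    def test_decoys_rarely_included_under_null(self, model):
        """Type-I error (scaled down): on cohorts simulated WITHOUT any
        covariate effects, noise covariates are almost never selected."""
        null_model = model.replace(theta2=0.0, theta4=0.0)
        false_inclusions = 0
        n_seeds = 8
        for seed in range(n_seeds):
            spec = mp.CohortSpec(n_subjects=12, n_alt_dose=0)
            data = add_decoy_covariates(
                mp.simulate_dataset(spec, null_model, seed=300 + seed),
                seed=400 + seed)
            _, trace = mp.stepwise_covariate_search(
                data, [("D1", "CL"), ("D2", "Vc"), ("D3", "CL")], null_model)
            false_inclusions += len(trace.included())
        # nominal rate ~1% per decoy test; allow generous Monte-Carlo slack
        assert false_inclusions <= 2


class TestBootstrap:
    def test_identity_resample_collapses_to_point_estimates(self, model, cohort):
        res = mp.fit(cohort, model, compute_rse=False)
        table = mp.bootstrap(cohort, res, n_boot=1, seed=0, resample=False)
        for name in res.structure.parameter_names():
            assert table.loc[name, "median"] == pytest.approx(
                res.estimates[name], rel=5e-2)
            assert table.loc[name, "ci_low"] == pytest.approx(
                table.loc[name, "ci_high"])

    def test_same_seed_identical_resamples(self, model, cohort):
        res = mp.fit(cohort, model, compute_rse=False)
        a = mp.bootstrap(cohort, res, n_boot=3, seed=42)
        b = mp.bootstrap(cohort, res, n_boot=3, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_ci_covers_truth_at_moderate_width(self, model, cohort):
        """Scaled-down CI check: the bootstrap interval for typical CL covers
        the generating value and is meaningfully wide."""
        res = mp.fit(cohort, model, compute_rse=False)
        table = mp.bootstrap(cohort, res, n_boot=25, seed=5)
        lo, hi = table.loc["CL", "ci_low"], table.loc["CL", "ci_high"]
        assert lo < 7.35 < hi
        assert (hi - lo) / 7.35 > 0.05
        assert table.attrs["failed_fraction"] <= 0.2
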