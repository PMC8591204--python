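import numpy as np
import pandas as pd
import pytest

import meropk as mp
from meropk.popmodel import CovariateDomainError
from meropk.pta import RENAL_GROUPS, STANDARD_MIC_GRID, _ss_profiles


def _typical_profile(model, regimen, dt=mp.MINUTE, crcl=49.7, lpm=3.7):
    p = mp.typical_params(model, mp.CovariateVector(crcl=crcl, lpm=lpm))
    return mp.steady_state_profile(p, regimen, dt=dt)


class TestPDTarget:
    def test_validation(self):
        with pytest.raises(ValueError):
            mp.PDTarget(mic=0.0)
        with pytest.raises(ValueError):
            mp.PDTarget(mic=1.0, fu=0.0)
        with pytest.raises(ValueError):
            mp.PDTarget(mic=1.0, fraction_pct=0.0)

    def test_threshold_and_label(self):
        t = mp.PDTarget(mic=2.0, fraction_pct=100, mic_multiplier=4)
        assert t.threshold == 8.0
        assert "4x" in t.label


class TestFtAboveMic:
    def test_extreme_mics(self, model):
        t_grid, conc = _typical_profile(model, mp.DosingRegimen(1000, 3.0, 8.0, None))
        low = mp.ft_above_mic(t_grid, conc, mp.PDTarget(mic=1e-9), 8.0)
        assert low == pytest.approx(100.0)
        high = mp.ft_above_mic(t_grid, conc, mp.PDTarget(mic=1e6), 8.0)
        assert high == 0.0

    def test_minute_grid_vs_fine_grid_brute_force(self, model):
        """Minute grid + linear crossing refinement vs 0.1-second sampling."""
        reg = mp.DosingRegimen(1000, 0.5, 8.0, None)
        target = mp.PDTarget(mic=4.0, fraction_pct=40)
        t_grid, conc = _typical_profile(model, reg)
        pct_minute = mp.ft_above_mic(t_grid, conc, target, 8.0)
        dt_fine = 0.1 / 3600.0
        tf, cf = _typical_profile(model, reg, dt=dt_fine)
        pct_fine = 100.0 * np.mean(0.98 * cf > target.threshold)
        assert pct_minute == pytest.approx(pct_fine, abs=0.05)

    def test_full_interval_target_equals_trough_check(self, model):
        """100% fT>MIC holds iff the free trough exceeds the threshold."""
        reg = mp.DosingRegimen(2000, 3.0, 8.0, None)
        t_grid, conc = _typical_profile(model, reg)
        trough_free = 0.98 * conc.min()
        just_below = mp.PDTarget(mic=trough_free * 0.999, fraction_pct=100)
        just_above = mp.PDTarget(mic=trough_free * 1.001, fraction_pct=100)
        assert mp.ft_above_mic(t_grid, conc, just_below, 8.0) == pytest.approx(100.0)
        assert mp.ft_above_mic(t_grid, conc, just_above, 8.0) < 100.0


class TestSimulatePta:
    def test_degenerate_population_is_step_function(self, model):
        frozen = model.replace(omega_CL=0, omega_Vc=0, omega_Vp=0)
        reg = mp.DosingRegimen(1000, 0.5, 8.0, None)
        res = mp.simulate_pta(frozen, (60, 60.000001), 3.7, reg,
                              [mp.PDTarget(mic=m_) for m_ in (0.1, 64.0)],
                              n=200, seed=1)
        assert {r.pta for r in res} <= {0.0, 1.0}

    def test_monotone_in_mic(self, model):
        reg = mp.DosingRegimen(1000, 0.5, 8.0, None)
        targets = [mp.PDTarget(mic=m_, fraction_pct=40) for m_ in STANDARD_MIC_GRID]
        res = mp.simulate_pta(model, (50, 90), 3.7, reg, targets, n=500, seed=3)
        ptas = [r.pta for r in res]
        assert all(a >= b for a, b in zip(ptas, ptas[1:]))

    def test_monotone_in_dose_and_interval_with_crn(self, model):
        """Common random numbers: more drug or shorter interval never hurts."""
        rng = np.random.default_rng(5)
        draws = (rng.random(500), rng.standard_normal((500, 3)))
        target = [mp.PDTarget(mic=4.0, fraction_pct=40)]
        def pta(dose, tau):
            reg = mp.DosingRegimen(dose, 0.5, tau, None)
            return mp.simulate_pta(model, (50, 90), 3.7, reg, target,
                                   draws=draws)[0].pta
        assert pta(2000, 8.0) >= pta(1000, 8.0) >= pta(500, 8.0)
        assert pta(1000, 8.0) >= pta(1000, 12.0)

    def test_seed_reproducibility(self, model):
        reg = mp.DosingRegimen(1000, 3.0, 8.0, None)
        t = [mp.PDTarget(mic=1.0, fraction_pct=100)]
        a = mp.simulate_pta(model, (90, 130), 3.7, reg, t, n=300, seed=9)[0].pta
        b = mp.simulate_pta(model, (90, 130), 3.7, reg, t, n=300, seed=9)[0].pta
        assert a == b

    def test_inadmissible_flow_rejected(self, model):
        reg = mp.DosingRegimen(1000, 0.5, 8.0, None)
        with pytest.raises(CovariateDomainError):
            mp.simulate_pta(model, (50, 90), 0.5, reg,
                            [mp.PDTarget(mic=1.0)], n=50, seed=1)


class TestRecommendedRegimenPta:
    def test_point_mass_mic_reduces_to_simulate_pta(self, model):
        """A one-MIC distribution and a one-regimen policy reproduce the
        plain uniform-CRCL simulation."""
        reg = mp.DosingRegimen(1000, 0.5, 8.0, None)
        policy = mp.RenalDosingPolicy(breakpoints=(), regimens=(reg,))
        crcl_sampler = lambda k, r: r.uniform(50, 90, k)
        table = mp.recommended_regimen_pta(
            model, policy, [(4.0, 1.0)], n=800, seed=21,
            crcl_sampler=crcl_sampler,
            targets_spec=((40.0, 1.0),),
        )
        marginal = table[table["mic"].isna()]["pta"].iloc[0]
        rng = np.random.default_rng(21)
        draws = (rng.random(800), rng.standard_normal((800, 3)))
        direct = mp.simulate_pta(model, (50, 90), 3.7, reg,
                                 [mp.PDTarget(mic=4.0, fraction_pct=40)],
                                 n=800, seed=21)[0].pta
        assert marginal == pytest.approx(direct, abs=0.05)

    def test_policy_bands_and_validation(self):
        policy = mp.recommended_policy()
        assert policy.regimen_for(5.0).tau == 24.0
        assert policy.regimen_for(20.0).dose == 500.0
        assert policy.regimen_for(40.0).tau == 12.0
        assert policy.regimen_for(120.0).tau == 8.0
        with pytest.raises(ValueError):
            mp.RenalDosingPolicy(breakpoints=(10.0, 5.0),
                                 regimens=tuple([mp.DosingRegimen(500, 0.5, 8)] * 3))

    def test_stratified_rows_and_negative_frequency_rejected(self, model):
        with pytest.raises(ValueError):
            mp.recommended_regimen_pta(model, mp.recommended_policy(),
                                       [(1.0, -0.5)], n=10, seed=1)
        table = mp.recommended_regimen_pta(
            model, mp.recommended_policy(), [(0.5, 0.5), (8.0, 0.5)],
            n=400, seed=2, targets_spec=((40.0, 1.0),))
        assert set(table["mic"].dropna()) == {0.5, 8.0}
        assert table["pta"].between(0, 1).all()


class TestRegimenGridSearch:
    def test_single_cell_grid_matches_simulate_pta(self, model):
        table = mp.regimen_grid_search(
            model, groups=[(50, 90)], doses=[1000], infusion_times=[0.5],
            intervals=[8.0], mics=[4.0], targets_spec=((40.0, 1.0),),
            n=400, seed=31,
        )
        assert len(table) == 1
        rng = np.random.default_rng(31)
        draws = (rng.random(400), rng.standard_normal((400, 3)))
        ref = mp.simulate_pta(model, (50, 90), 3.7,
                              mp.DosingRegimen(1000, 0.5, 8.0, None),
                              [mp.PDTarget(mic=4.0, fraction_pct=40)],
                              draws=draws)[0]
        assert table["pta"].iloc[0] == pytest.approx(ref.pta)

    def test_prolonged_infusion_helps_full_interval_targets(self, model):
        """Paired (common-random-numbers) contrast: a 3-h infusion attains
        100% fT>MIC at least as often as a 0.5-h infusion of the same dose."""
        table = mp.regimen_grid_search(
            model, groups=[(50, 90), (90, 130)], doses=[1000, 2000],
            infusion_times=[0.5, 3.0], intervals=[8.0],
            mics=[0.5, 1.0, 2.0], targets_spec=((100.0, 1.0),),
            n=400, seed=41,
        )
        wide = table.pivot_table(index=["group_low", "dose_mg", "mic"],
                                 columns="tinf_h", values="pta")
        assert np.all(wide[3.0] >= wide[0.5] - 1e-12)

    def test_full_published_grid_runs_at_scale(self, model):
        """The complete factorial (6 groups x 3 doses x 2 infusions x 2
        intervals x 9 MICs x 3 targets) at n=1000 completes in one go."""
        table = mp.regimen_grid_search(model, n=1000, seed=51)
        assert len(table) == 6 * 3 * 2 * 2 * 9 * 3
        assert table["pta"].between(0, 1).all()
        assert (table["optimal"] == (table["pta"] >= 0.90)).all()


class TestFlowRateSensitivity:
    def test_reference_flow_reproduces_default(self, model):
        table = mp.flow_rate_sensitivity(
            model, flows=[3.7], groups=[(50, 90)], doses=[1000],
            intervals=[8.0], mics=[4.0], n=300, seed=61,
        )
        rng = np.random.default_rng(61)
        draws = (rng.random(300), rng.standard_normal((300, 3)))
        ref = mp.simulate_pta(model, (50, 90), 3.7,
                              mp.DosingRegimen(1000, 0.5, 8.0, None),
                              [mp.PDTarget(mic=4.0, fraction_pct=40)],
                              draws=draws)[0].pta
        assert table["pta"].iloc[0] == pytest.approx(ref)

    def test_higher_flow_prolongs_elimination_half_life(self, model):
        """Analytic check: larger Vc at fixed CL stretches the terminal phase."""
        t_lo = mp.half_lives(mp.typical_params(
            model, mp.CovariateVector(crcl=70, lpm=2.0)))[1]
        t_hi = mp.half_lives(mp.typical_params(
            model, mp.CovariateVector(crcl=70, lpm=6.0)))[1]
        assert t_hi > t_lo

    def test_flow_raises_pta_with_common_random_numbers(self, model):
        table = mp.flow_rate_sensitivity(
            model, flows=[2.0, 4.0], groups=[(50, 90)], doses=[1000],
            intervals=[12.0], mics=[4.0], n=1000, seed=71,
        )
        wide = table.pivot_table(index="mic", columns="lpm", values="pta")
        assert wide[4.0].iloc[0] > wide[2.0].iloc[0]
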