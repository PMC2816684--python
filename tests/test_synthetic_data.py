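"""Kinetic model: closed-form correctness, dilution ceiling, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methylerase import synthetic_data as sd
from methylerase.errors import CalibrationError, DegenerateLocusError
from methylerase.params import ConditionSpec, KineticParams, LocusSpec

from conftest import dilution_only_params


def make_locus(**kw):
    base = dict(nucleosome_id="x", replication_time_min=10.0,
                tss_distance_bp=100.0, induction_class="alpha",
                arrest_excess_log2=0.5, baseline_fraction=0.3)
    base.update(kw)
    return LocusSpec(**base)


class TestTrajectory:
    def test_replication_halves_exactly(self, cca):
        # dilution-only: M(0) = 0.8 drops to exactly 0.4 at the fork passage
        locus = make_locus(baseline_fraction=0.8, arrest_excess_log2=0.0)
        m = sd.methylation_trajectory(locus, dilution_only_params(), cca)
        grid = np.asarray(cca.time_grid_min)
        assert np.all(m[grid < 10.0] == 0.8)
        assert np.all(m[grid >= 10.0] == 0.4)
        assert m[grid < 10.0][-1] / m[grid >= 10.0][0] == 2.0

    def test_no_replication_no_dynamics(self):
        locus = make_locus(baseline_fraction=0.8, arrest_excess_log2=0.0)
        cond = sd.cca_condition(replication_enabled=False)
        m = sd.methylation_trajectory(locus, dilution_only_params(), cond)
        assert np.all(m == 0.8)

    def test_closed_form_matches_fine_step_integration(self):
        # brute-force ODE oracle: Heun integration at dt = 0.001 min
        params = dilution_only_params(k_dep_mid=0.02, k_dem=0.01)
        locus = make_locus(baseline_fraction=0.3,
                           arrest_excess_log2=np.log2(1.0 / 0.3),
                           tss_distance_bp=100.0)
        cond = sd.cca_condition(replication_enabled=False)
        m = sd.methylation_trajectory(locus, params, cond)

        def rhs(y):
            return 0.02 * (1 - y) - 0.01 * y

        dt, y, t = 1e-3, 1.0, 0.0
        expected = [y]
        for g in np.asarray(cond.time_grid_min)[1:]:
            for _ in range(int(round((g - t) / dt))):
                k1 = rhs(y)
                y = y + dt * 0.5 * (k1 + rhs(y + dt * k1))
            t = g
            expected.append(y)
        assert np.max(np.abs(m - np.array(expected))) < 1e-6

    def test_sustained_stimulus_holds_arrest_state(self):
        cond = sd.galdex_condition("hold", replication_enabled=False)
        locus = make_locus(induction_class="alpha", arrest_excess_log2=1.2)
        m = sd.methylation_trajectory(locus, sd.default_params(), cond)
        assert np.allclose(m, 0.3 * 2 ** 1.2)

    def test_onset_lag_freezes_demethylation(self):
        params = sd.default_params(demethylation_onset_min=30.0)
        locus = make_locus()
        cond = sd.cca_condition(replication_enabled=False)
        m = sd.methylation_trajectory(locus, params, cond)
        grid = np.asarray(cond.time_grid_min)
        assert np.allclose(m[grid <= 30.0], m[0])
        assert m[-1] < m[0]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        k_dem=st.floats(0.0, 0.2),
        k_dep=st.floats(0.0, 0.2),
        k_remeth=st.floats(0.0, 0.3),
        baseline=st.floats(0.05, 0.9),
        excess_frac=st.floats(0.0, 1.0),
        rep_time=st.floats(0.0, 100.0),
        replicate=st.booleans(),
    )
    def test_trajectory_stays_in_unit_interval(self, k_dem, k_dep, k_remeth,
                                               baseline, excess_frac, rep_time,
                                               replicate):
        excess = excess_frac * np.log2(1.0 / baseline)
        params = KineticParams(k_dem=k_dem, k_dep_mid=k_dep, k_remeth=k_remeth,
                               tie_deposition_to_baseline=False,
                               noise_sigma_log2=0.0, sync_sd_min=0.0)
        locus = make_locus(baseline_fraction=baseline,
                           arrest_excess_log2=excess,
                           replication_time_min=rep_time)
        cond = sd.cca_condition(replication_enabled=replicate)
        m = sd.methylation_trajectory(locus, params, cond)
        assert np.all((m >= 0.0) & (m <= 1.0))

    def test_replication_always_at_least_as_erasing(self, default_params):
        # at equal k_dem, terminal erasure with replication >= without
        for e0 in (0.3, 0.5, 0.8):
            for tr in (12.0, 22.5, 33.0):
                locus = make_locus(arrest_excess_log2=e0, replication_time_min=tr)
                m_rep = sd.methylation_trajectory(
                    locus, default_params, sd.cca_condition())
                m_norep = sd.methylation_trajectory(
                    locus, default_params, sd.cca_condition(replication_enabled=False))
                assert m_rep[-1] <= m_norep[-1] + 1e-12

    def test_jhd2_never_erases_faster(self, default_params):
        # reduced demethylase rate: methylation stays at/above wild type at
        # every time point without replication, and up to the fork with it
        wt = sd.cca_condition("wt", replication_enabled=False)
        mut = sd.cca_condition("jhd2", replication_enabled=False,
                               kdem_multiplier=default_params.jhd2_scale)
        for e0 in (0.2, 0.5, 1.0):
            locus = make_locus(arrest_excess_log2=e0)
            assert np.all(
                sd.methylation_trajectory(locus, default_params, mut)
                >= sd.methylation_trajectory(locus, default_params, wt) - 1e-12)
        wt_r = sd.cca_condition("wt_r")
        mut_r = sd.cca_condition("jhd2_r",
                                 kdem_multiplier=default_params.jhd2_scale)
        locus = make_locus(replication_time_min=25.0)
        grid = np.asarray(wt_r.time_grid_min)
        pre = grid < 25.0
        assert np.all(
            sd.methylation_trajectory(locus, default_params, mut_r)[pre]
            >= sd.methylation_trajectory(locus, default_params, wt_r)[pre] - 1e-12)

    def test_parameter_recovery_from_excess_decay(self, default_params):
        # log-linear fit of the linear-scale excess recovers the total
        # relaxation rate k_dep_eff + k_dem_eff to better than 1%
        locus = make_locus(arrest_excess_log2=0.7)
        cond = sd.cca_condition(replication_enabled=False)
        m = sd.methylation_trajectory(locus, default_params, cond)
        y = m / locus.baseline_fraction - 1.0
        slope = np.polyfit(np.asarray(cond.time_grid_min), np.log(y), 1)[0]
        k_dem_eff = default_params.k_dem
        kappa = k_dem_eff + k_dem_eff * 0.3 / 0.7   # tied deposition
        assert abs(-slope - kappa) / kappa < 0.01


class TestPopulationTrajectory:
    def test_reduces_to_single_cell_without_dispersion(self, cca, quiet_locus,
                                                       default_params):
        p0 = default_params.model_copy(update={"sync_sd_min": 0.0})
        np.testing.assert_array_equal(
            sd.population_trajectory(quiet_locus, p0, cca),
            sd.methylation_trajectory(quiet_locus, p0, cca))

    def test_preserves_endpoints_and_smooths_step(self, cca, quiet_locus):
        sharp = dilution_only_params()
        smeared = dilution_only_params(sync_sd_min=4.0)
        m_sharp = sd.methylation_trajectory(quiet_locus, sharp, cca)
        m_pop = sd.population_trajectory(quiet_locus, smeared, cca)
        # same level before and long after the fork, intermediate in between
        assert m_pop[0] == pytest.approx(m_sharp[0], abs=1e-9)
        assert m_pop[-1] == pytest.approx(m_sharp[-1], rel=1e-6)
        mid = np.asarray(cca.time_grid_min) == 20.0
        assert m_sharp[mid] < m_pop[mid] < m_sharp[0]


class TestMeasure:
    def test_identity_and_twofold(self):
        m = np.full(5, 0.3)
        assert np.allclose(sd.measure(m, 0.3, 0.0, 0), 0.0)
        assert np.allclose(sd.measure(2 * m, 0.3, 0.0, 0), 1.0)

    def test_noise_mean_matches_noiseless_value(self):
        m = np.full(10_000, 0.45)
        sig = sd.measure(m, 0.3, 0.15, 1234)
        noiseless = np.log2(0.45 / 0.3)
        assert abs(sig.mean() - noiseless) < 4 * 0.15 / np.sqrt(10_000)

    def test_zero_methylation_rejected(self):
        with pytest.raises(DegenerateLocusError):
            sd.measure(np.array([0.2, 0.0]), 0.3, 0.0, 0)


class TestOccupancy:
    def test_closed_forms(self):
        grid = (0.0, 10.0, 20.0)
        cond = ConditionSpec(name="c", protocol="CCA", time_grid_min=grid)
        early = make_locus(nucleosome_id="e", replication_time_min=10.0)
        late = make_locus(nucleosome_id="l", replication_time_min=100.0)
        occ = sd.occupancy_trajectory([early, late], cond)
        # t=0: nobody replicated -> 0; t=10: half the panel -> log2(4/3), log2(2/3)
        assert np.allclose(occ[:, 0], 0.0)
        assert occ[0, 1] == pytest.approx(np.log2(4 / 3))
        assert occ[1, 1] == pytest.approx(np.log2(2 / 3))
        both = sd.occupancy_trajectory(
            [early, make_locus(nucleosome_id="e2", replication_time_min=10.0)],
            cond)
        assert np.allclose(both[:, 1:], 0.0)  # all replicated -> ratio 2/2

    def test_panel_mean_linear_scale_is_one(self):
        cond = sd.cca_condition()
        panel = [make_locus(nucleosome_id=f"n{i}", replication_time_min=5 + 3 * i)
                 for i in range(10)]
        occ = sd.occupancy_trajectory(panel, cond, sync_sd_min=4.0)
        assert np.allclose((2.0 ** occ).mean(axis=0), 1.0)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            sd.occupancy_trajectory([], sd.cca_condition())


class TestSimulateExperiment:
    def test_deterministic_and_shaped(self, default_params, cca):
        panel, _ = sd.make_cluster6_panel(20, 10, seed=3)
        a = sd.simulate_experiment(panel, default_params, cca)
        b = sd.simulate_experiment(panel, default_params, cca)
        np.testing.assert_array_equal(a.me3.values, b.me3.values)
        np.testing.assert_array_equal(a.occupancy.values, b.occupancy.values)
        assert a.me3.values.shape == (30, len(cca.time_grid_min))

    def test_duplicate_ids_rejected(self, default_params, cca):
        locus = make_locus()
        with pytest.raises(ValueError, match="duplicate"):
            sd.simulate_experiment([locus, locus], default_params, cca)

    def test_panel_subsetting_preserves_locus_noise(self, default_params, cca):
        panel, _ = sd.make_cluster6_panel(10, 0, seed=3)
        full = sd.simulate_experiment(panel, default_params, cca)
        sub = sd.simulate_experiment(panel[3:6], default_params, cca)
        for rid in sub.me3.ids:
            np.testing.assert_array_equal(sub.me3.row(rid), full.me3.row(rid))

    def test_max_mean_drop_falls_in_s_window(self, default_params):
        # 100 induced early-replicating loci: the steepest panel-mean decline
        # between consecutive samples happens inside the S-phase window
        rng = np.random.default_rng(0)
        panel = [make_locus(nucleosome_id=f"n{i}",
                            replication_time_min=float(rng.uniform(10, 20)))
                 for i in range(100)]
        sim = sd.simulate_experiment(panel, default_params, sd.cca_condition())
        mean_profile = sim.me3.values.mean(axis=0)
        steps = np.diff(mean_profile)
        t_drop = sim.me3.times[1:][np.argmin(steps)]
        lo, hi = default_params.s_phase_window
        assert lo <= t_drop <= hi


class TestCalibration:
    def test_round_trip_reproduces_target(self):
        base = sd.KineticParams(k_dem=0.01, noise_sigma_log2=0.0, seed=0)
        ref = make_locus(replication_time_min=22.5)
        k = sd.calibrate_demethylation_rate(0.75, 90.0, base, ref)
        p = base.model_copy(update={"k_dem": k})
        e_rep = sd._noiseless_erasure(ref, p, sd.cca_condition(), 90.0)
        e_norep = sd._noiseless_erasure(
            ref, p, sd.cca_condition(replication_enabled=False), 90.0)
        assert abs(e_norep / e_rep - 0.75) < 1e-4

    def test_monotone_in_target(self):
        base = sd.KineticParams(k_dem=0.01, noise_sigma_log2=0.0, seed=0)
        ref = make_locus(replication_time_min=22.5)
        ks = [sd.calibrate_demethylation_rate(t, 90.0, base, ref)
              for t in (0.5, 0.65, 0.8)]
        assert ks[0] < ks[1] < ks[2]

    def test_full_residual_target_is_nonidentifiable(self):
        base = sd.KineticParams(k_dem=0.01, noise_sigma_log2=0.0, seed=0)
        with pytest.raises(CalibrationError):
            sd.calibrate_demethylation_rate(1.0, 90.0, base, make_locus())

    def test_unbracketable_target_reported(self):
        base = sd.KineticParams(k_dem=0.01, noise_sigma_log2=0.0, seed=0)
        with pytest.raises(CalibrationError, match="bracket"):
            sd.calibrate_demethylation_rate(0.75, 90.0, base, make_locus(),
                                            bracket=(1.0, 2.0))


class TestValidation:
    def test_dilution_factor_pinned_to_two(self):
        with pytest.raises(ValueError):
            KineticParams(k_dem=0.01, dilution_factor=3.0)

    def test_arrest_fraction_cannot_exceed_one(self):
        with pytest.raises(ValueError):
            make_locus(baseline_fraction=0.8, arrest_excess_log2=1.0)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            ConditionSpec(name="bad", protocol="CCA",
                          time_grid_min=(0.0, 10.0, 5.0))
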