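"""Compartmental simulator: exactness, conservation laws and dose-record
handling."""
import numpy as np
import pytest

from remipkpd import (
    DoseEvent,
    InfusionSchedule,
    build_system,
    merge_dose_records,
    simulate,
    time_to_peak_effect,
)
from remipkpd.system import IDX

from conftest import ode_oracle, random_covariates, random_schedule


class TestSimulate:
    def test_zero_dose_gives_identically_zero_signals(self, ref_system):
        tc = simulate(ref_system, InfusionSchedule([]), np.linspace(0, 60, 20))
        for sig in (tc.cp_art, tc.cven, tc.ce_moaas, tc.ce_bis, tc.ca_metab,
                    tc.cven_metab, tc.cum_dose):
            assert np.all(sig == 0.0)

    def test_bolus_initial_concentration_is_dose_over_v1(self, ref_system):
        tc = simulate(ref_system, InfusionSchedule([DoseEvent(0, 10)]), [0.0, 1.0])
        assert tc.cp_art[0] == pytest.approx(10 / 4.31, rel=1e-3)

    def test_steady_state_infusion(self, ref_system):
        sched = InfusionSchedule([DoseEvent(0, 5000.0, 5000.0)])  # 1 mg/min
        tc = simulate(ref_system, sched, [4000.0])
        assert tc.cp_art[0] == pytest.approx(1 / 1.12, rel=1e-3)
        assert tc.ce_moaas[0] == pytest.approx(tc.cp_art[0], rel=1e-6)
        assert tc.ca_metab[0] == pytest.approx(1 / 0.0665, rel=1e-4)

    def test_linearity_doubling_doses_doubles_concentrations(self, ref_system):
        t = np.linspace(0, 45, 12)
        sched = InfusionSchedule([DoseEvent(0, 5), DoseEvent(5, 20, 10)])
        sched2 = InfusionSchedule([DoseEvent(0, 10), DoseEvent(5, 40, 10)])
        a = simulate(ref_system, sched, t)
        b = simulate(ref_system, sched2, t)
        np.testing.assert_allclose(b.cp_art, 2 * a.cp_art, rtol=1e-10)
        np.testing.assert_allclose(b.ca_metab, 2 * a.ca_metab, rtol=1e-10)

    def test_superposition_of_shifted_boluses(self, ref_system):
        t = np.linspace(10, 60, 11)
        both = simulate(ref_system,
                        InfusionSchedule([DoseEvent(0, 5), DoseEvent(10, 7)]), t)
        first = simulate(ref_system, InfusionSchedule([DoseEvent(0, 5)]), t)
        second = simulate(ref_system, InfusionSchedule([DoseEvent(10, 7)]), t)
        np.testing.assert_allclose(both.ce_moaas,
                                   first.ce_moaas + second.ce_moaas, rtol=1e-10)

    def test_venous_lags_and_never_exceeds_arterial_peak(self, ref_system):
        t = np.linspace(0, 120, 2401)
        tc = simulate(ref_system, InfusionSchedule([DoseEvent(0, 10)]), t)
        assert np.argmax(tc.cven) >= np.argmax(tc.cp_art)
        assert tc.cven.max() <= tc.cp_art.max() + 1e-12

    def test_unsorted_times_rejected(self, ref_system):
        with pytest.raises(ValueError):
            simulate(ref_system, InfusionSchedule([]), [5.0, 1.0])

    def test_matches_adaptive_ode_oracle_on_random_problems(self, ref_system):
        rng = np.random.default_rng(3)
        for _ in range(5):
            sched = random_schedule(rng)
            t = np.sort(rng.uniform(0, 60, 8))
            tc = simulate(ref_system, sched, t, keep_states=True)
            ref = ode_oracle(ref_system, sched, t)
            scale = np.abs(ref).max(axis=0) + 1e-9
            assert np.max(np.abs(tc.states - ref) / scale) < 1e-6


class TestMassBalance:
    def test_dose_is_conserved_and_metabolism_is_complete(self, ref_system):
        rng = np.random.default_rng(11)
        sched = random_schedule(rng)
        t = np.sort(rng.uniform(1, 90, 12))
        tc = simulate(ref_system, sched, t, keep_states=True)
        s = tc.states
        remi = s[:, :3].sum(axis=1) + s[:, IDX["Elim"]]
        np.testing.assert_allclose(remi, tc.cum_dose, rtol=1e-10, atol=1e-10)
        metab = s[:, IDX["Adepot"]:IDX["Am2"] + 1].sum(axis=1) + s[:, IDX["Elim_m"]]
        np.testing.assert_allclose(metab, s[:, IDX["Elim"]], rtol=1e-9, atol=1e-12)

    def test_total_metabolite_equals_dose_at_long_time(self, ref_system):
        tc = simulate(ref_system, InfusionSchedule([DoseEvent(0, 10)]),
                      [3000.0], keep_states=True)
        s = tc.states[0]
        produced = s[IDX["Adepot"]:IDX["Am2"] + 1].sum() + s[IDX["Elim_m"]]
        assert produced == pytest.approx(10.0, rel=1e-6)


class TestTimeToPeakEffect:
    def test_agrees_with_dense_grid_argmax(self, ref_model):
        tp = time_to_peak_effect(ref_model.remi, 0.298)
        system = build_system(ref_model.remi, ref_model.metab, 0.298, 0.145)
        grid = np.arange(0.0, 10.0, 0.001)
        tc = simulate(system, InfusionSchedule([DoseEvent(0, 1)]), grid)
        assert tp == pytest.approx(grid[np.argmax(tc.ce_moaas)], abs=0.01)

    def test_peak_time_vanishes_for_very_fast_equilibration(self, ref_model):
        assert time_to_peak_effect(ref_model.remi, 1e6) < 0.05

    def test_dose_independence(self, ref_model):
        # linear system: peak time does not depend on the bolus size
        system = build_system(ref_model.remi, ref_model.metab, 0.298, 0.145)
        grid = np.arange(0.0, 10.0, 0.001)
        peaks = []
        for dose in (1.0, 50.0):
            tc = simulate(system, InfusionSchedule([DoseEvent(0, dose)]), grid)
            peaks.append(grid[np.argmax(tc.ce_moaas)])
        assert peaks[0] == peaks[1]


class TestMergeDoseRecords:
    def test_merges_contiguous_similar_short_infusions(self):
        # two 30-s infusions at 1.00 and 1.02 mg/min separated by 0.5 s
        sched = InfusionSchedule([
            DoseEvent(0.0, 0.50, 0.5),
            DoseEvent(0.5 + 0.5 / 60, 0.51, 0.5),
        ])
        merged = merge_dose_records(sched)
        assert len(merged) == 1
        ev = merged.events[0]
        assert ev.amount == pytest.approx(1.01)
        assert ev.duration == pytest.approx(1.0 + 0.5 / 60)

    def test_distant_records_unchanged(self):
        sched = InfusionSchedule([DoseEvent(0, 1, 1), DoseEvent(10, 1, 1)])
        assert merge_dose_records(sched) == sched

    def test_rate_difference_criterion(self):
        sched = InfusionSchedule([DoseEvent(0, 0.5, 0.5),
                                  DoseEvent(0.5, 0.6, 0.5)])  # 0.2 mg/min apart
        assert len(merge_dose_records(sched)) == 2

    def test_long_infusions_not_merged(self):
        sched = InfusionSchedule([DoseEvent(0, 3, 3), DoseEvent(3, 3, 3)])
        assert len(merge_dose_records(sched)) == 2

    def test_total_dose_invariant_on_random_schedules(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            t = 0.0
            events = []
            for _ in range(rng.integers(1, 12)):
                dur = float(rng.uniform(0.1, 1.5))
                events.append(DoseEvent(t, float(rng.uniform(0.1, 2)) * dur, dur))
                t += dur + float(rng.uniform(0, 0.02))
            sched = InfusionSchedule(events)
            merged = merge_dose_records(sched)
            assert merged.total_dose == pytest.approx(sched.total_dose, rel=1e-12)

    def test_iterates_until_fixpoint(self):
        # three chained 30-s records collapse to one across two passes
        events = [DoseEvent(i * 0.5, 0.5, 0.5) for i in range(3)]
        merged = merge_dose_records(InfusionSchedule(events))
        assert len(merged) == 1
        assert merged.events[0].duration == pytest.approx(1.5)


class TestBuildSystem:
    def test_zero_state_zero_input_is_stationary(self, ref_system):
        assert np.all(ref_system.A @ np.zeros(12) == 0.0)

    def test_off_diagonal_rates_nonnegative(self, ref_system):
        A = ref_system.A.copy()
        np.fill_diagonal(A, 0.0)
        assert np.all(A >= 0.0)

    def test_rejects_nonpositive_ke0(self, ref_model):
        with pytest.raises(ValueError):
            build_system(ref_model.remi, ref_model.metab, 0.0, 0.145)
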