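import dataclasses
import math

import numpy as np
import pytest

import ventloop as vl
from ventloop.errors import SimulationError
from ventloop.subject import P_ALV_KPA, alveolar_po2_target, pip_pressure


def _vent(rr=20.0, vt=160.0, fio2=25.0, peep=5.0):
    return vl.VentilatorSettings(tidal_volume=vt, respiratory_rate=rr, peep=peep, fio2=fio2)


def _run_fixed(params, vent, insuff, t_end, dt=1.0, state=None, hold=False):
    state = state or vl.initial_state(params, vent)
    while state.time < t_end - 1e-9:
        state = vl.advance(state, params, vent, insuff, dt, breath_hold=hold)
    return state


class TestAlveolarVentilation:
    def test_rr_times_effective_volume(self):
        params = dataclasses.replace(vl.SubjectParams(), vd=60.0)
        assert vl.alveolar_ventilation(_vent(rr=20, vt=160), params) == 2000.0

    def test_zero_during_breath_hold(self):
        params = vl.SubjectParams()
        assert vl.alveolar_ventilation(_vent(), params, breath_hold=True) == 0.0

    def test_dead_space_ventilation_infeasible(self):
        params = dataclasses.replace(vl.SubjectParams(), vd=60.0)
        with pytest.raises(SimulationError):
            vl.alveolar_ventilation(_vent(vt=50), params)


class TestCo2Load:
    def test_metabolic_only_without_insufflation(self):
        params = vl.SubjectParams()
        assert vl.co2_load(0.0, params) == params.vco2_met

    def test_linear_in_iap(self):
        params = dataclasses.replace(vl.SubjectParams(), k_perit=2.0)
        assert vl.co2_load(10.0, params) == params.vco2_met + 20.0
        up0 = vl.co2_load(5.0, params) - params.vco2_met
        up1 = vl.co2_load(10.0, params) - params.vco2_met
        assert up1 == pytest.approx(2 * up0)


class TestAdvance:
    def test_equilibrium_is_fixed_point(self):
        params = vl.SubjectParams()
        vent = _vent()
        state = vl.initial_state(params, vent)
        insuff = vl.InsufflatorSettings(iap_setpoint=0.0)
        nxt = vl.advance(state, params, vent, insuff, 1.0)
        assert nxt.paco2 == pytest.approx(state.paco2, rel=1e-12)

    def test_breath_hold_raises_paco2(self):
        params = vl.SubjectParams()
        vent = _vent()
        state = vl.initial_state(params, vent)
        held = _run_fixed(params, vent, vl.InsufflatorSettings(), 60.0, state=state, hold=True)
        assert held.paco2 > state.paco2

    def test_converges_to_closed_form_steady_state(self):
        params = vl.SubjectParams()
        vent = _vent(rr=25)
        insuff = vl.InsufflatorSettings(iap_setpoint=12.0)
        state = vl.initial_state(params, vent)
        state = _run_fixed(params, vent, insuff, 3600.0, state=state)
        va = vl.alveolar_ventilation(vent, params)
        expected = vl.equilibrium_paco2(vl.co2_load(12.0, params), va)
        assert state.paco2 == pytest.approx(expected, rel=1e-6)

    def test_steady_state_mass_balance_within_1pct(self):
        """Expired CO2 rate equals metabolic production + peritoneal uptake."""
        params = vl.SubjectParams()
        vent = _vent(rr=22)
        for iap in (0.0, 10.0, 20.0):
            insuff = vl.InsufflatorSettings(iap_setpoint=iap)
            state = _run_fixed(params, vent, insuff, 3600.0)
            va = vl.alveolar_ventilation(vent, params)
            expired = va * state.paco2 / P_ALV_KPA  # mL/min
            load = params.vco2_met + params.k_perit * iap
            assert expired == pytest.approx(load, rel=0.01)

    def test_steady_paco2_strictly_decreasing_in_rr(self):
        params = vl.SubjectParams()
        insuff = vl.InsufflatorSettings(iap_setpoint=10.0)
        values = [
            _run_fixed(params, _vent(rr=rr), insuff, 3600.0).paco2
            for rr in (15, 20, 25, 30)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_iap_ramps_at_slew_rate(self):
        params = vl.SubjectParams()  # 5 hPa/s
        vent = _vent()
        state = vl.initial_state(params, vent)
        insuff = vl.InsufflatorSettings(iap_setpoint=12.0)
        state = vl.advance(state, params, vent, insuff, 1.0)
        assert state.iap_actual == pytest.approx(5.0)
        state = vl.advance(state, params, vent, insuff, 1.0)
        assert state.iap_actual == pytest.approx(10.0)
        state = vl.advance(state, params, vent, insuff, 1.0)
        assert state.iap_actual == pytest.approx(12.0)

    def test_halving_dt_changes_trajectory_below_0p1pct(self):
        """Integration convergence: the per-tick update is closed-form, so
        refining dt only re-samples the trajectory."""
        params = vl.SubjectParams()
        vent = _vent()

        def trajectory(dt):
            state = vl.initial_state(params, vent)
            out = {}
            while state.time < 600.0 - 1e-9:
                iap = 14.0 if state.time >= 120.0 else 0.0
                insuff = vl.InsufflatorSettings(iap_setpoint=iap)
                state = vl.advance(state, params, vent, insuff, dt)
                out[round(state.time, 6)] = (state.paco2, state.pao2)
            return out

        a, b = trajectory(1.0), trajectory(0.5)
        shared = sorted(set(a) & set(b))
        assert len(shared) >= 500
        for t in shared:
            assert a[t][0] == pytest.approx(b[t][0], rel=1e-3)
            assert a[t][1] == pytest.approx(b[t][1], rel=1e-3)


class TestObserve:
    def test_ori_endpoints_of_linear_mapping(self):
        params = vl.SubjectParams()
        vent = _vent()
        lo = dataclasses.replace(vl.initial_state(params, vent), pao2=params.pao2_ori_lo)
        hi = dataclasses.replace(lo, pao2=params.pao2_ori_hi)
        assert vl.observe(lo, params, vent).ori == 0.0
        assert vl.observe(hi, params, vent).ori == 1.0

    def test_etco2_is_paco2_minus_gradient(self):
        params = vl.SubjectParams()
        vent = _vent()
        state = vl.initial_state(params, vent)
        s = vl.observe(state, params, vent)
        assert s.etco2 == pytest.approx(state.paco2 - params.et_gradient)

    def test_pip_without_insufflation_is_peep_plus_vt_over_crs(self):
        params = vl.SubjectParams()
        vent = _vent()
        state = vl.initial_state(params, vent)
        s = vl.observe(state, params, vent)
        assert s.pip == pytest.approx(vent.peep + vent.tidal_volume / params.crs0)

    def test_pip_strictly_increases_with_iap(self):
        params = vl.SubjectParams()
        vent = _vent()
        pips = [pip_pressure(vent, params, iap) for iap in (0, 5, 10, 15, 20)]
        assert all(a < b for a, b in zip(pips, pips[1:]))

    def test_spo2_nondecreasing_in_fio2(self):
        params = vl.SubjectParams()
        sats = []
        for fio2 in (21, 30, 40, 60, 100):
            state = _run_fixed(params, _vent(fio2=fio2), vl.InsufflatorSettings(), 600.0)
            sats.append(vl.observe(state, params, _vent(fio2=fio2)).spo2)
        assert all(a <= b for a, b in zip(sats, sats[1:]))

    def test_etco2_flagged_invalid_during_hold(self):
        params = vl.SubjectParams()
        vent = _vent()
        state = dataclasses.replace(
            vl.initial_state(params, vent), breath_hold_active=True
        )
        assert not vl.observe(state, params, vent).etco2_valid

    def test_severinghaus_reference_points(self):
        # canonical curve: ~50% at 26.6 mmHg, >97% at 100 mmHg
        assert vl.severinghaus_spo2(26.6) == pytest.approx(50.0, abs=1.0)
        assert vl.severinghaus_spo2(100.0) > 97.0


class TestNoise:
    def test_noise_off_trajectories_bit_reproducible(self):
        log1 = vl.run_closed_loop(10.0, 300.0, seed=3)
        log2 = vl.run_closed_loop(10.0, 300.0, seed=4)  # seed irrelevant without noise
        assert log1.to_frame().equals(log2.to_frame())

    def test_noisy_runs_reproducible_per_seed(self):
        params = dataclasses.replace(
            vl.SubjectParams(), noise_sd=vl.NoiseLevels(etco2=0.05, spo2=0.2)
        )
        a = vl.run_closed_loop(10.0, 200.0, params, seed=7).to_frame()
        b = vl.run_closed_loop(10.0, 200.0, params, seed=7).to_frame()
        c = vl.run_closed_loop(10.0, 200.0, params, seed=8).to_frame()
        assert a.equals(b)
        assert not a.etco2_kpa.equals(c.etco2_kpa)

    def test_channel_substreams_independent(self):
        """Enabling noise on one channel does not perturb another channel."""
        p1 = dataclasses.replace(vl.SubjectParams(), noise_sd=vl.NoiseLevels(etco2=0.05))
        p2 = dataclasses.replace(
            vl.SubjectParams(), noise_sd=vl.NoiseLevels(etco2=0.05, pip=0.5)
        )
        a = vl.run_closed_loop(10.0, 200.0, p1, seed=7).to_frame()
        b = vl.run_closed_loop(10.0, 200.0, p2, seed=7).to_frame()
        assert np.allclose(a.etco2_kpa, b.etco2_kpa)
        assert not np.allclose(a.pip_hpa, b.pip_hpa)
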