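import numpy as np
import pytest

from cardioem.cells import (CellParams, OharaRudyModel, ReducedModel,
                            apd90, calibrate_gks, pace_to_limit_cycle)

GATE_COLUMNS = slice(9, 30)  # gating variables of the ionic model


class TestIonicModel:
    def test_rest_stability(self):
        m = OharaRudyModel()
        Y = m.initial_state(1)
        v0 = Y[0, 0]
        for _ in range(1000):
            m.step(Y, 1.0, 0.0)
        assert abs(Y[0, 0] - v0) < 1.0

    def test_suprathreshold_stimulus_elicits_action_potential(self):
        m = OharaRudyModel()
        Y = m.initial_state(1)
        trace = m.run_beat(Y, CellParams(cycle_length=500.0), 0.02,
                           record=True)
        assert trace.max() > 0.0
        assert trace[-1] < -80.0

    def test_gates_remain_in_unit_interval(self):
        m = OharaRudyModel()
        Y = m.initial_state(1)
        mins, maxs = np.inf, -np.inf
        for i in range(20000):  # 400 ms at dt = 0.02 covering the upstroke
            istim = -53.0 if i * 0.02 < 1.0 else 0.0
            m.step(Y, 0.02, istim)
            g = Y[0, GATE_COLUMNS]
            mins = min(mins, g.min())
            maxs = max(maxs, g.max())
        assert mins >= -1e-9 and maxs <= 1.0 + 1e-9

    def test_endo_epi_variants_differ_with_endo_longer(self):
        m = OharaRudyModel()
        apds = {}
        for variant in ("endo", "epi"):
            Y = m.initial_state(1, variant)
            p = CellParams(variant=variant)
            for _ in range(3):
                trace = m.run_beat(Y, p, 0.02, record=True)
            apds[variant] = apd90(trace, 0.02)
        assert apds["endo"] > apds["epi"]

    def test_non_finite_state_identified(self):
        m = OharaRudyModel()
        Y = m.initial_state(1)
        Y[0, 5] = np.nan  # poison intracellular calcium
        with pytest.raises(FloatingPointError, match="cai"):
            m.step(Y, 0.02, 0.0, check=True)

    def test_apd_refinement_convergence(self):
        m = OharaRudyModel()
        apds = []
        for dt in (0.005, 0.0025):
            Y = m.initial_state(1)
            trace = m.run_beat(Y, CellParams(), dt, record=True)
            apds.append(apd90(trace, dt))
        assert abs(apds[0] - apds[1]) < 0.5


class TestReducedModel:
    def test_fires_and_recovers(self):
        m = ReducedModel()
        Y = m.initial_state(1)
        trace = m.run_beat(Y, CellParams(model="reduced"), 0.1, record=True)
        assert trace.max() > 0.0
        assert trace[-1] < -80.0

    def test_calcium_transient_follows_activation(self):
        m = ReducedModel()
        Y = m.initial_state(4)
        m.step(Y, 1.0, -80.0)
        for _ in range(120):
            m.step(Y, 1.0, 0.0)
        assert Y[0, m.idx_ca] > 2e-4  # clearly above diastolic


class TestAPD90:
    def test_square_pulse(self):
        dt = 1.0
        vm = np.full(400, -85.0)
        vm[10:210] = 0.0
        assert apd90(vm, dt) == pytest.approx(200.0, abs=1.5)

    def test_invariance_under_voltage_offset(self):
        dt = 1.0
        t = np.arange(500)
        vm = -85 + 125 * np.exp(-((t - 50) / 80.0)**2) * (t > 20)
        assert apd90(vm + 17.0, dt) == pytest.approx(apd90(vm, dt),
                                                     abs=1e-9)

    def test_triangular_repolarization_matches_brute_force(self):
        dt = 0.5
        n = 1200
        vm = np.full(n, -85.0)
        up = 20
        vm[up:up + 2] = 40.0
        ramp = np.linspace(40.0, -85.0, 600)
        vm[up + 2:up + 2 + 600] = ramp
        result = apd90(vm, dt)
        # brute-force scan of the sampled trace
        peak, base = 40.0, -85.0
        level = peak - 0.9 * (peak - base)
        i_up = int(np.argmax(np.diff(vm)))
        below = np.flatnonzero(vm[up:] <= level) + up
        expected = below[0] * dt - i_up * dt
        assert result == pytest.approx(expected, abs=dt)

    def test_no_upstroke_raises(self):
        with pytest.raises(ValueError):
            apd90(np.full(100, -85.0), 1.0)


class TestLimitCycle:
    def test_reduced_model_converges_and_is_idempotent(self):
        p = CellParams(model="reduced")
        r = pace_to_limit_cycle(p, max_beats=50)
        assert r.converged
        r2 = pace_to_limit_cycle(p, max_beats=50, initial_state=r.state)
        assert r2.converged and r2.n_beats <= 2

    def test_attractor_unique_from_different_initial_states(self):
        p = CellParams(model="reduced")
        r1 = pace_to_limit_cycle(p, max_beats=60)
        m = ReducedModel()
        Y0 = m.initial_state(1)
        Y0[0, 1] = 0.4  # perturbed recovery gate
        r2 = pace_to_limit_cycle(p, max_beats=60, initial_state=Y0)
        assert abs(r1.apd90 - r2.apd90) < 1.0


class TestGksCalibration:
    def test_zero_target_returns_unity(self):
        assert calibrate_gks(CellParams(model="reduced"), 0.0) == 1.0

    def test_reduced_model_17_percent_shortening(self):
        p = CellParams(model="reduced")
        m = calibrate_gks(p, 0.17, max_beats=50)
        base = pace_to_limit_cycle(p, max_beats=50)
        import dataclasses
        apex = pace_to_limit_cycle(
            dataclasses.replace(p, gks_scale=m), max_beats=50)
        shortening = 1.0 - apex.apd90 / base.apd90
        assert shortening == pytest.approx(0.17, abs=0.005)

    def test_apd_monotone_in_scale(self):
        p = CellParams(model="reduced")
        apds = []
        for scale in (1.0, 2.0, 4.0, 8.0):
            import dataclasses
            r = pace_to_limit_cycle(
                dataclasses.replace(p, gks_scale=scale), max_beats=50)
            apds.append(r.apd90)
        assert all(a > b for a, b in zip(apds, apds[1:]))

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            calibrate_gks(CellParams(model="reduced"), 0.7)
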