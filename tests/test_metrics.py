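import numpy as np
import pytest

from cardioem.ecg import LEAD_NAMES, LeadTraces
from cardioem.metrics import (ComparisonTable, FrozenCase,
                              beat_stabilization, build_comparison_table,
                              freeze_cases, qt_end_tangent, trace_pearson,
                              twave_amplitude, avpd, twist)


def gaussian_twave(times, center=300.0, width=25.0, amp=2.0):
    return amp * np.exp(-0.5 * ((times - center) / width)**2)


class TestTwaveAmplitude:
    def test_gaussian_bump(self):
        t = np.arange(0.0, 500.0)
        tr = gaussian_twave(t, width=15.0)
        assert twave_amplitude(t, tr, (250, 400)) == pytest.approx(2.0,
                                                                   abs=0.01)

    def test_sign_preserved_for_negative_wave(self):
        t = np.arange(0.0, 500.0)
        tr = -gaussian_twave(t, width=15.0)
        assert twave_amplitude(t, tr, (250, 400)) == pytest.approx(-2.0,
                                                                   abs=0.01)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        t = np.arange(0.0, 500.0)
        tr = rng.standard_normal(len(t)).cumsum() * 0.01
        win = (200.0, 380.0)
        a = twave_amplitude(t, tr, win)
        sel = (t >= win[0]) & (t <= win[1])
        base = tr[(t >= win[0] - 20) & (t < win[0])].mean()
        dev = tr[sel] - base
        assert a == pytest.approx(dev[np.argmax(np.abs(dev))])

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            twave_amplitude(np.arange(10.0), np.zeros(10), (100, 200))


class TestQTEndTangent:
    def test_linear_descent_tangent_is_itself(self):
        t = np.arange(0.0, 400.0)
        tr = np.zeros_like(t)
        ramp = (t >= 280) & (t <= 330)
        tr[t < 280] = np.linspace(0, 1, (t < 280).sum())  # slow rise
        tr[ramp] = np.linspace(1.0, 0.0, ramp.sum())
        assert qt_end_tangent(t, tr, 0.0) == pytest.approx(330.0, abs=1.5)

    def test_time_equivariance(self):
        t = np.arange(0.0, 600.0)
        tr = gaussian_twave(t, center=300.0)
        q1 = qt_end_tangent(t, tr, 0.0)
        tr2 = gaussian_twave(t, center=340.0)
        q2 = qt_end_tangent(t, tr2, 0.0)
        assert q2 - q1 == pytest.approx(40.0, abs=1.0)

    def test_gaussian_matches_dense_grid_search(self):
        t = np.arange(0.0, 600.0, 1.0)
        tr = gaussian_twave(t)
        coarse = qt_end_tangent(t, tr, 0.0)
        td = np.arange(0.0, 600.0, 0.1)
        fine = qt_end_tangent(td, gaussian_twave(td), 0.0)
        assert coarse == pytest.approx(fine, abs=1.0)

    def test_no_descent_rejected(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(ValueError):
            qt_end_tangent(t, t * 0.01, 0.0)  # monotone rise only


class TestPearsonAndStabilization:
    def test_identical_and_negated(self):
        a = np.array([0.3, 1.0, -0.5, 2.0])
        assert trace_pearson(a, a) == pytest.approx(1.0)
        assert trace_pearson(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r = trace_pearson(np.array([1.0, 2.0, 3.0]),
                          np.array([1.0, 2.0, 4.0]))
        assert r == pytest.approx(0.9819805060619659, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            trace_pearson(np.ones(5), np.arange(5.0))

    def test_stabilization_identical_and_offset_beats(self):
        b = np.random.default_rng(12).standard_normal((100, 9))
        ok, rmse = beat_stabilization(b, b)
        assert ok and rmse == 0.0
        ok2, rmse2 = beat_stabilization(b, b + 0.2)
        assert not ok2 and rmse2 == pytest.approx(0.2)

    def test_rmse_matches_direct_formula(self):
        rng = np.random.default_rng(13)
        a = rng.standard_normal((50, 9))
        b = rng.standard_normal((50, 9))
        _, rmse = beat_stabilization(a, b)
        assert rmse == pytest.approx(np.sqrt(np.mean((a - b)**2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            beat_stabilization(np.zeros((10, 9)), np.zeros((11, 9)))


class TestAVPDAndTwist:
    def test_rigid_translation_toward_apex(self):
        pts = np.array([[20.0, 0, 15.0], [0, 20.0, 15.0]])
        disp = np.tile([0, 0, -5.0], (3, 2, 1))  # -z is toward the apex
        tr = avpd(pts, disp)
        assert np.allclose(tr, 5.0)

    def test_translation_toward_base_negative(self):
        pts = np.array([[20.0, 0, 15.0]])
        disp = np.tile([0, 0, 4.0], (2, 1, 1))
        assert np.allclose(avpd(pts, disp), -4.0)

    def test_rotation_is_orthogonal_to_avpd(self):
        pts = np.array([[20.0, 0.0, 15.0]])
        th = np.deg2rad(10.0)
        rot = np.array([20 * np.cos(th) - 20, 20 * np.sin(th), 0.0])
        assert np.allclose(avpd(pts, rot[None, None, :]), 0.0, atol=1e-12)

    def test_rigid_rotation_angle_recovered(self):
        pts = np.array([[20.0, 0.0, -30.0], [0.0, 15.0, -10.0]])
        th = np.deg2rad(10.0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        disp = (pts @ R.T - pts)[None]
        ang = twist(pts, disp)
        # rotation by +10 deg about +z is counterclockwise viewed from
        # +z (the base side), hence +10 with the base-view convention
        assert np.allclose(np.abs(ang), 10.0, atol=1e-9)
        assert np.allclose(ang, ang[0, 0])

    def test_no_deformation_zero_angle(self):
        pts = np.array([[20.0, 0.0, -30.0]])
        assert np.allclose(twist(pts, np.zeros((3, 1, 3))), 0.0)

    def test_point_on_axis_rejected(self):
        with pytest.raises(ValueError):
            twist(np.array([[0.0, 0.0, -30.0]]), np.zeros((2, 1, 3)))

    def test_angle_matches_atan2_recomputation(self):
        rng = np.random.default_rng(14)
        pts = np.array([[18.0, 4.0, -25.0]])
        disp = 0.5 * rng.standard_normal((6, 1, 3))
        ang = twist(pts, disp)
        for i in range(6):
            cur = pts[0] + disp[i, 0]
            a_cur = np.arctan2(cur[1], cur[0])
            a_ref = np.arctan2(pts[0, 1], pts[0, 0])
            # counterclockwise viewed from the base = positive standard
            # rotation about +z
            expect = np.degrees(
                (a_cur - a_ref + np.pi) % (2 * np.pi) - np.pi)
            assert ang[i, 0] == pytest.approx(expect, abs=1e-9)


def _traces(times, scale=1.0, shift=0.0):
    leads = {}
    for i, ld in enumerate(LEAD_NAMES):
        leads[ld] = scale * gaussian_twave(times, center=300.0 + shift,
                                           amp=1.0 + 0.3 * i)
    el = {n: np.zeros_like(times) for n in
          ["RA", "LA", "LL"] + [f"V{i}" for i in range(1, 7)]}
    return LeadTraces(times=times, electrodes=el, leads=leads)


class TestComparisonProtocol:
    def test_identical_case_reads_100_percent_and_zero_shift(self):
        t = np.arange(0.0, 600.0)
        dyn = _traces(t)
        case = FrozenCase(label="same", freeze_time=0.0,
                          nodes=np.zeros((1, 3)), traces=_traces(t))
        table = build_comparison_table(dyn, [case], (220.0, 450.0), 120.0)
        for ld in LEAD_NAMES:
            assert table.case_amplitude_percent["same"][ld] == \
                pytest.approx(100.0, abs=0.5)
            assert table.case_t_end_delta_ms["same"][ld] == \
                pytest.approx(0.0, abs=0.5)

    def test_scaled_case_reads_80_percent(self):
        t = np.arange(0.0, 600.0)
        dyn = _traces(t)
        case = FrozenCase(label="scaled", freeze_time=0.0,
                          nodes=np.zeros((1, 3)),
                          traces=_traces(t, scale=0.8))
        table = build_comparison_table(dyn, [case], (220.0, 450.0), 120.0)
        for ld in LEAD_NAMES:
            assert table.case_amplitude_percent["scaled"][ld] == \
                pytest.approx(80.0, abs=0.5)

    def test_low_amplitude_surface_points_masked(self):
        t = np.arange(0.0, 600.0)
        dyn = _traces(t)
        case = FrozenCase(label="c", freeze_time=0.0,
                          nodes=np.zeros((1, 3)), traces=_traces(t))
        bspm_dyn = np.array([2.0, 0.3, -1.4, 0.1])
        bspm_c = np.array([1.0, 0.3, -0.7, 0.1])
        table = build_comparison_table(dyn, [case], (220.0, 450.0), 120.0,
                                       bspm_dynamic=bspm_dyn,
                                       bspm_cases={"c": bspm_c})
        rel = table.masked_map["c"]
        assert np.isnan(rel[1]) and np.isnan(rel[3])
        assert rel[0] == pytest.approx(50.0)
        assert table.masked_map["mask_kept_fraction"] == pytest.approx(0.5)

    def test_freeze_cases_times_and_errors(self):
        times = np.arange(0.0, 851.0)
        hist = np.zeros((851, 4, 3))
        hist += times[:, None, None]
        cases = freeze_cases(times, hist)
        labels = {c.label: c.freeze_time for c in cases}
        assert labels == {"end_diastatic": 0.0, "end_diastolic": 150.0,
                          "end_systolic": 400.0}
        for c in cases:
            assert np.allclose(c.nodes, c.freeze_time)
        with pytest.raises(ValueError):
            freeze_cases(times, hist, {"late": 1000.0})
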