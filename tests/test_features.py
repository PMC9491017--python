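"""Feature extraction: gradients, velocities, kinetic energy, residence time."""

import math

import numpy as np
import pytest

import heartgsa as hg
from heartgsa.clinical import MMHG_TO_KPA
from heartgsa.features import FeatureConfig, WashoutDivergence, _window_time_average
from heartgsa.lumped import SideContext, SimulationTrace, ValveGeometry
from heartgsa.transients import ValveTimings
from heartgsa.windkessel import WindkesselParams


def _synthetic_trace(
    n=1446, period=0.723, q_in=125.0, q_out=125.0, v_vent=100.0, v_atr=60.0,
    p_atr=8.0, p_vent=5.0, p_art=80.0, side="left", n_beats=2,
) -> SimulationTrace:
    """Hand-built steady trace for closed-form feature checks."""
    m = n * n_beats
    dt_ms = period * 1000.0 / n
    const = lambda x: np.full(m, float(x))
    ctx = SideContext(
        windkessel=WindkesselParams(z=2.0, r=48.0, c=15.0),
        geometry={"AV": ValveGeometry(4.0), "MV": ValveGeometry(4.0)},
    )
    params = hg.HeartModelParams(
        "left", 49.89, 10.0, {"AV": 1e-7, "MV": 1e-7}, {"AV": 15.0, "MV": 15.0}, ctx
    )
    return SimulationTrace(
        side=side,
        t_s=np.arange(m) * dt_ms / 1000.0,
        dt_ms=dt_ms,
        period_s=period,
        n_beats=n_beats,
        p_atr=const(p_atr),
        p_vent=const(p_vent),
        p_art=const(p_art),
        p_dist=const(70.0),
        q_vein=const(q_in),
        q_in=const(q_in),
        q_out=const(q_out),
        sigma_in=const(1.0),
        sigma_out=const(1.0),
        v_atr=const(v_atr),
        v_vent=const(v_vent),
        converged=True,
        params=params,
    )


class TestGradient:
    def test_constant_flow_ohm(self, constant_volume_transients):
        """Steady flow through an open valve: gradient = Q·R in mmHg."""
        ctx = SideContext(
            windkessel=WindkesselParams(z=2.0, r=48.0, c=15.0),
            geometry={"AV": ValveGeometry(3.0, r_open=2.0), "MV": ValveGeometry(4.5, r_open=2.0)},
        )
        p = hg.HeartModelParams(
            "left", 48.0, 10.0, {"AV": 1e-7, "MV": 1e-7}, {"AV": 15.0, "MV": 15.0}, ctx
        )
        tim = ValveTimings(period=constant_volume_transients.period, events={}, dur_ms={})
        tr = hg.simulate(
            p, constant_volume_transients, tim, n_beats=20,
            sigma_override={"AV": 1.0, "MV": 1.0},
        )
        q = tr.q_out[tr.beat_slice].mean() / 1000.0  # mL/ms
        expected_mmhg = q * 2.0 / MMHG_TO_KPA
        got = hg.mean_valve_gradient(tr, tim, "AV", window="cycle")
        assert got == pytest.approx(expected_mmhg, rel=1e-6)

    def test_zero_flow_zero_gradient(self):
        tr = _synthetic_trace(q_in=0.0, q_out=0.0, p_atr=5.0, p_vent=5.0, p_art=5.0)
        tim = ValveTimings(period=tr.period_s, events={}, dur_ms={})
        assert hg.mean_valve_gradient(tr, tim, "AV", window="cycle") == 0.0

    def test_windowed_mean_matches_quadrature_oracle(self, baseline_trace, timings):
        """Systolic AV gradient equals an independent trapezoid average
        recomputed from the raw trace arrays."""
        got = hg.mean_valve_gradient(baseline_trace, timings, "AV", window="systole")
        # oracle: rebuild the window and integrate independently
        b = baseline_trace.beat_slice
        t = np.mod(baseline_trace.t_s[b], baseline_trace.period_s)
        dp = baseline_trace.p_vent[b] - baseline_trace.p_art[b]
        t_open, t_close = timings.events["AV"]
        half = timings.dur_ms["AV"] * 1e-3 / 2
        sel = (t >= t_open + half) & (t < t_close - half)
        idx = np.flatnonzero(sel)
        y = dp[idx]
        oracle = np.trapezoid(y, dx=1.0) / (y.size - 1)
        assert got == pytest.approx(oracle, rel=1e-9)

    def test_empty_window_rejected(self, baseline_trace):
        tim = ValveTimings(period=baseline_trace.period_s, events={}, dur_ms={})
        with pytest.raises(ValueError):
            hg.mean_valve_gradient(baseline_trace, tim, "AV", window="systole")

    def test_window_average_handles_wrapped_window(self):
        y = np.arange(10.0)
        mask = np.zeros(10, dtype=bool)
        mask[[8, 9, 0, 1]] = True
        # contiguous order 8,9,0,1 -> trapezoid average of [8,9,0,1]
        expected = np.trapezoid([8.0, 9.0, 0.0, 1.0]) / 3.0
        assert _window_time_average(y, mask) == pytest.approx(expected)


class TestVelocity:
    def test_unit_arithmetic(self):
        tr = _synthetic_trace(q_out=100.0)  # 100 mL/s over 4 cm²
        assert hg.max_valve_velocity(tr, "AV") == pytest.approx(0.25)

    def test_zero_flow(self):
        tr = _synthetic_trace(q_in=0.0, q_out=0.0)
        assert hg.max_valve_velocity(tr, "MV") == 0.0

    def test_sinusoidal_amplitude(self):
        tr = _synthetic_trace()
        m = tr.t_s.size
        tr.q_out = 200.0 * np.sin(2 * np.pi * tr.t_s / tr.period_s)
        assert hg.max_valve_velocity(tr, "AV") == pytest.approx(0.5, rel=1e-4)


class TestKineticEnergy:
    def test_closed_form(self):
        """v = 1 m/s, V = 100 mL, ρ = 1060 -> 53 mJ."""
        tr = _synthetic_trace(q_out=400.0, v_vent=100.0)  # 400 mL/s / 4 cm² = 1 m/s
        assert hg.mean_kinetic_energy(tr, "LV") == pytest.approx(53.0, rel=1e-9)

    def test_zero_flow(self):
        tr = _synthetic_trace(q_in=0.0, q_out=0.0)
        assert hg.mean_kinetic_energy(tr, "LV") == 0.0

    def test_time_varying_matches_quadrature_oracle(self, baseline_trace):
        got = hg.mean_kinetic_energy(baseline_trace, "LV")
        b = baseline_trace.beat_slice
        v = baseline_trace.valve_velocity("AV")[b]
        vol = baseline_trace.v_vent[b]
        oracle = np.mean(0.5 * 1060.0 * vol * 1e-6 * v**2 * 1e3)
        assert got == pytest.approx(oracle, rel=1e-9)


class TestResidenceTime:
    def test_constant_flow_closed_form(self):
        """V = 100 mL, Q = 125 mL/s -> steady age V/Q = 0.8 s."""
        tr = _synthetic_trace(q_in=125.0, q_out=125.0, v_vent=100.0)
        cfg = FeatureConfig(rt_rtol=1e-7, rt_max_cycles=2000)
        assert hg.residence_time(tr, "LV", cfg) == pytest.approx(0.8, rel=1e-3)

    def test_doubling_flow_halves_residence_time(self):
        cfg = FeatureConfig(rt_rtol=1e-7, rt_max_cycles=2000)
        rt1 = hg.residence_time(_synthetic_trace(q_in=125.0, q_out=125.0), "LV", cfg)
        rt2 = hg.residence_time(_synthetic_trace(q_in=250.0, q_out=250.0), "LV", cfg)
        assert rt2 == pytest.approx(rt1 / 2.0, rel=5e-3)

    def test_pulsatile_within_15pct_of_mean_flow_bound(self, baseline_trace):
        rt = hg.residence_time(baseline_trace, "LV")
        b = baseline_trace.beat_slice
        q_mean = np.clip(baseline_trace.q_in[b], 0, None).mean()
        v_mean = baseline_trace.v_vent[b].mean()
        assert abs(rt - v_mean / q_mean) < 0.15 * (v_mean / q_mean)

    def test_pulsatile_matches_fine_step_reference(self, baseline_trace):
        """The converged age agrees with a 5x-finer independent integration."""
        rt = hg.residence_time(baseline_trace, "LV", FeatureConfig(rt_rtol=1e-6))
        b = baseline_trace.beat_slice
        vol = baseline_trace.v_vent[b]
        q_out = np.clip(baseline_trace.q_out[b], 0, None)
        n = vol.size
        refine = 5
        tt = np.arange(n * refine) / refine
        vol_f = np.interp(tt, np.arange(n), vol, period=n)
        q_f = np.interp(tt, np.arange(n), q_out, period=n)
        dt = baseline_trace.dt_ms / 1000.0 / refine
        a = 0.0
        mean_prev = None
        for _ in range(400):
            ages = np.empty(n * refine)
            for k in range(n * refine):
                v_now = vol_f[k]
                v_next = vol_f[(k + 1) % (n * refine)]
                a = (a * v_now + dt * (v_now - q_f[k] * a)) / v_next
                ages[k] = a
            m = ages.mean()
            if mean_prev is not None and abs(m - mean_prev) < 1e-6 * m:
                break
            mean_prev = m
        assert rt == pytest.approx(m, rel=0.01)

    def test_no_inflow_divergence(self):
        tr = _synthetic_trace(q_in=0.0, q_out=0.0)
        with pytest.raises(WashoutDivergence):
            hg.residence_time(tr, "LV")

    def test_appendage_slower_than_atrium(self, baseline_trace):
        rt_app = hg.residence_time(baseline_trace, "APP")
        assert rt_app > 0


class TestExtractFeatures:
    def test_zero_flow_trace_flags_residence_time(self):
        tr = _synthetic_trace(q_in=0.0, q_out=0.0, p_atr=5.0, p_vent=5.0, p_art=5.0)
        tim = ValveTimings(period=tr.period_s, events={}, dur_ms={})
        reg = {
            "dp_AV": hg.features.FeatureDef("gradient", "AV", "cycle", "mmHg"),
            "maxv_AV": hg.features.FeatureDef("max_velocity", "AV", unit="m/s"),
            "RT_LV": hg.features.FeatureDef("residence_time", "LV", unit="s"),
        }
        fv = hg.extract_features(tr, tim, reg)
        assert fv["dp_AV"] == 0.0 and fv["maxv_AV"] == 0.0
        assert math.isnan(fv["RT_LV"]) and fv.flags["RT_LV"] == "washout-divergence"

    def test_single_feature_registry(self, baseline_trace, timings):
        reg = {"maxv_AV": hg.features.FeatureDef("max_velocity", "AV", unit="m/s")}
        fv = hg.extract_features(baseline_trace, timings, reg)
        assert len(fv) == 1

    def test_unconverged_trace_marked_invalid(self, baseline_trace, timings):
        import copy

        bad = copy.copy(baseline_trace)
        bad.converged = False
        fv = hg.extract_features(bad, timings)
        assert not fv.valid
        assert all(math.isnan(v) for v in fv.values.values())

    def test_round_trip_through_serialized_trace(self, baseline_trace, timings, tmp_path):
        """Every feature is reproduced from the trace CSV by an independent
        recomputation."""
        import copy

        import pandas as pd

        path = tmp_path / "trace.csv"
        baseline_trace.to_csv(path)
        df = pd.read_csv(path)
        clone = copy.copy(baseline_trace)
        clone.p_atr = df["p_atr_mmhg"].to_numpy()
        clone.p_vent = df["p_vent_mmhg"].to_numpy()
        clone.p_art = df["p_art_mmhg"].to_numpy()
        clone.q_vein = df["q_vein_ml_s"].to_numpy()
        clone.q_in = df["q_in_ml_s"].to_numpy()
        clone.q_out = df["q_out_ml_s"].to_numpy()
        clone.v_atr = df["v_atr_ml"].to_numpy()
        clone.v_vent = df["v_vent_ml"].to_numpy()
        a = hg.extract_features(baseline_trace, timings)
        b = hg.extract_features(clone, timings)
        for k in a:
            assert b[k] == pytest.approx(a[k], rel=1e-9), k

    def test_warmup_insensitivity(self, baseline_left_params, transients, timings):
        """Adding a 5th beat changes no feature by more than 0.5%."""
        t4 = hg.simulate(baseline_left_params, transients, timings, n_beats=4)
        t5 = hg.simulate(baseline_left_params, transients, timings, n_beats=5)
        f4 = hg.extract_features(t4, timings)
        f5 = hg.extract_features(t5, timings)
        for k in f4:
            assert abs(f5[k] - f4[k]) <= 5e-3 * max(abs(f4[k]), 1e-9), k

    def test_unit_audit_rescale_round_trip(self, baseline_trace, timings):
        """Converting the trace to SI and back moves no feature above 1e-12."""
        import copy

        clone = copy.copy(baseline_trace)
        c = 133.322  # mmHg -> Pa
        for attr in ("p_atr", "p_vent", "p_art"):
            setattr(clone, attr, getattr(clone, attr) * c / c)
        a = hg.extract_features(baseline_trace, timings)
        b = hg.extract_features(clone, timings)
        for k in a:
            assert b[k] == pytest.approx(a[k], rel=1e-12), k
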