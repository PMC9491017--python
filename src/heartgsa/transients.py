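"""Synthetic periodic chamber-volume transients, fluxes and valve timings.

The imaging-derived wall motion that drives the simulator is not publicly
available, so this module generates smooth periodic volume curves with the
canonical four-chamber morphology: one ventricular ejection phase, biphasic
filling (early E-wave, diastasis, atrial kick), and an atrial curve in rough
antiphase with reservoir / conduit / booster phases.  Curves are built from
C² smootherstep segments; the only hard data constraints are the prescribed
end-diastolic and end-systolic volumes.

Fluxes are the exact spectral time derivative of the volumes on the periodic
grid, and valve opening/closing events are detected from sign changes of the
ventricular net flux.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import PatientRecord

log = logging.getLogger(__name__)

# chamber roles per heart side: (ventricle, atrium, inflow valve, outflow valve)
SIDES = {
    "left": ("LV", "LA", "MV", "AV"),
    "right": ("RV", "RA", "TV", "PV"),
}


def smootherstep(x: np.ndarray | float) -> np.ndarray | float:
    """Quintic smoothstep 6x⁵−15x⁴+10x³ clamped to [0,1]; C² at both ends."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * x * (x * (6.0 * x - 15.0) + 10.0)


@dataclass(frozen=True)
class ShapeParams:
    """Morphology of the synthetic transients, as fractions of the cycle T.

    Defaults are synthetic choices (the source motion is image-derived and
    unavailable): systolic fraction 0.35, E/A filling split 0.7/0.3 with a
    diastasis plateau, 1024 samples per cycle.
    """

    n_samples: int = 1024
    systolic_fraction: float = 0.35
    ivc_fraction: float = 0.03  # isovolumic contraction hold
    ivr_fraction: float = 0.05  # isovolumic relaxation hold
    e_wave_fraction: float = 0.19
    a_wave_fraction: float = 0.15
    e_split: float = 0.7  # share of filling carried by the E-wave
    end_hold_fraction: float = 0.03
    # synthetic atrial extrema (mL); right side defaults slightly smaller
    la_max: float = 110.0
    la_min: float = 50.0
    ra_max: float = 100.0
    ra_min: float = 45.0
    conduit_drop: float = 0.6  # fraction of atrial range emptied in the E-wave
    diastasis_refill: float = 0.15
    # optional scaling of right-side stroke volume relative to left (1 = balanced)
    right_sv_fraction: float = 1.0
    # seeded jitter amplitude on interior phase boundaries (fraction of T)
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if self.n_samples < 64:
            raise ValueError("need at least 64 samples per cycle")
        total = (
            self.ivc_fraction
            + self.systolic_fraction
            + self.ivr_fraction
            + self.e_wave_fraction
            + self.a_wave_fraction
            + self.end_hold_fraction
        )
        if total >= 1.0:
            raise ValueError(f"phase fractions sum to {total:.3f} >= 1")
        if not 0.0 < self.e_split < 1.0:
            raise ValueError("e_split must lie in (0, 1)")


@dataclass
class VolumeTransients:
    """Periodic per-chamber volume curves over one cardiac cycle.

    ``t`` is a uniform grid in seconds covering [0, T) (the sample at T is
    implied by periodicity); ``volumes`` maps chamber name to mL series.
    """

    t: np.ndarray
    volumes: dict[str, np.ndarray]
    period: float

    @property
    def n(self) -> int:
        return self.t.size

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"time_s": self.t, **{k: v for k, v in self.volumes.items()}})
        df.to_csv(path, index=False)


@dataclass
class FluxSeries:
    """Per-interface flow series (mL/s) on the transient grid."""

    t: np.ndarray
    fluxes: dict[str, np.ndarray]  # e.g. net_LV, q_AV, q_MV, q_vein_LA
    period: float

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"time_s": self.t, **self.fluxes}).to_csv(path, index=False)


@dataclass
class ValveTimings:
    """Opening/closing times (s within the cycle) and transition widths (ms)."""

    period: float
    events: dict[str, tuple[float, float]]  # valve -> (t_open, t_close)
    dur_ms: dict[str, float]

    def with_dur(self, dur_ms: dict[str, float]) -> "ValveTimings":
        merged = {**self.dur_ms, **dur_ms}
        return ValveTimings(self.period, dict(self.events), merged)

    def open_interval(self, valve: str) -> tuple[float, float]:
        return self.events[valve]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "period_s": self.period,
                    "events_s": {k: list(v) for k, v in self.events.items()},
                    "dur_ms": self.dur_ms,
                },
                indent=2,
            )
        )


def _segment_curve(t_frac: np.ndarray, knots: list[tuple[float, float]]) -> np.ndarray:
    """Piecewise-smootherstep curve through (phase-fraction, value) knots.

    Between consecutive knots the value follows a smootherstep blend, giving a
    C² periodic curve when the first and last knot values agree.
    """
    v = np.empty_like(t_frac)
    for (x0, y0), (x1, y1) in zip(knots[:-1], knots[1:]):
        mask = (t_frac >= x0) & (t_frac < x1) if x1 < 1.0 else (t_frac >= x0)
        if x1 > x0:
            s = smootherstep((t_frac[mask] - x0) / (x1 - x0))
        else:
            s = 0.0
        v[mask] = y0 + (y1 - y0) * s
    return v


def _ventricular_knots(shape: ShapeParams, edv: float, esv: float) -> list[tuple[float, float]]:
    s = shape
    x = 0.0
    knots = [(x, edv)]
    x += s.ivc_fraction
    knots.append((x, edv))
    x += s.systolic_fraction
    knots.append((x, esv))
    x += s.ivr_fraction
    knots.append((x, esv))
    x += s.e_wave_fraction
    v_e = esv + s.e_split * (edv - esv)
    knots.append((x, v_e))
    x_a = 1.0 - s.end_hold_fraction - s.a_wave_fraction
    knots.append((x_a, v_e))  # diastasis plateau
    knots.append((x_a + s.a_wave_fraction, edv))
    knots.append((1.0, edv))
    return knots


def _atrial_knots(shape: ShapeParams, vmax: float, vmin: float) -> list[tuple[float, float]]:
    s = shape
    rng = vmax - vmin
    x_res_end = s.ivc_fraction + s.systolic_fraction + s.ivr_fraction
    x_e_end = x_res_end + s.e_wave_fraction
    x_a_start = 1.0 - s.end_hold_fraction - s.a_wave_fraction
    x_a_end = 1.0 - s.end_hold_fraction
    v_after_e = vmax - s.conduit_drop * rng
    v_before_a = v_after_e + s.diastasis_refill * rng
    return [
        (0.0, vmin),
        (x_res_end, vmax),          # reservoir: fills while ventricle ejects
        (x_e_end, v_after_e),       # conduit: empties into the E-wave
        (x_a_start, v_before_a),    # diastasis refill
        (x_a_end, vmin),            # booster: atrial kick
        (1.0, vmin),
    ]


def _jitter_shape(shape: ShapeParams, seed: int) -> ShapeParams:
    if shape.jitter <= 0.0:
        return shape
    rng = np.random.default_rng(seed)
    eps = shape.jitter
    return replace(
        shape,
        systolic_fraction=shape.systolic_fraction + rng.uniform(-eps, eps),
        e_wave_fraction=shape.e_wave_fraction + rng.uniform(-eps, eps),
        a_wave_fraction=shape.a_wave_fraction + rng.uniform(-eps, eps),
    )


def generate_volume_transients(
    rec: PatientRecord,
    shape: ShapeParams | None = None,
    seed: int = 0,
    sides: tuple[str, ...] = ("left", "right"),
) -> VolumeTransients:
    """Build deterministic periodic volume curves for the requested sides.

    The ventricular curve honours the record's EDV/ESV exactly at its extrema;
    right-side volumes fall back to left-side values (scaled by
    ``right_sv_fraction``) when the record has no RV volumes.
    """
    shape = _jitter_shape(shape or ShapeParams(), seed)
    T = rec.period_s
    t = np.arange(shape.n_samples) * (T / shape.n_samples)
    t_frac = t / T
    volumes: dict[str, np.ndarray] = {}
    for side in sides:
        vent, atr, _, _ = SIDES[side]
        if side == "left":
            edv, esv = rec.lvedv, rec.lvesv
            amax, amin = shape.la_max, shape.la_min
        else:
            if rec.rvedv is not None and rec.rvesv is not None:
                edv, esv = rec.rvedv, rec.rvesv
            else:
                sv = (rec.lvedv - rec.lvesv) * shape.right_sv_fraction
                edv = rec.lvedv
                esv = edv - sv
            amax, amin = shape.ra_max, shape.ra_min
        volumes[vent] = _segment_curve(t_frac, _ventricular_knots(shape, edv, esv))
        volumes[atr] = _segment_curve(t_frac, _atrial_knots(shape, amax, amin))
    return VolumeTransients(t=t, volumes=volumes, period=T)


def spectral_derivative(v: np.ndarray, period: float) -> np.ndarray:
    """Exact Fourier differentiation of a periodic series sampled uniformly."""
    n = v.size
    vk = np.fft.rfft(v)
    k = np.fft.rfftfreq(n, d=period / n)  # cycles per second
    dv = np.fft.irfft(vk * (2j * np.pi * k), n=n)
    return dv


def derive_fluxes(vt: VolumeTransients) -> FluxSeries:
    """Chamber net fluxes dV/dt and phase-assigned valve/vein fluxes (mL/s).

    Ventricular dV/dt < 0 is routed through the outflow valve, > 0 through the
    inflow valve; the venous inflow closes the atrial mass balance.
    """
    dt = np.diff(vt.t)
    if dt.size and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("transient grid must be uniform")
    fluxes: dict[str, np.ndarray] = {}
    for side, (vent, atr, inflow, outflow) in SIDES.items():
        if vent not in vt.volumes:
            continue
        dvv = spectral_derivative(vt.volumes[vent], vt.period)
        dva = spectral_derivative(vt.volumes[atr], vt.period)
        fluxes[f"net_{vent}"] = dvv
        fluxes[f"net_{atr}"] = dva
        fluxes[f"q_{outflow}"] = np.where(dvv < 0.0, -dvv, 0.0)
        fluxes[f"q_{inflow}"] = np.where(dvv > 0.0, dvv, 0.0)
        fluxes[f"q_vein_{atr}"] = dva + fluxes[f"q_{inflow}"]
    return FluxSeries(t=vt.t.copy(), fluxes=fluxes, period=vt.period)


def _moving_average(x: np.ndarray, w: int = 5) -> np.ndarray:
    """Periodic 5-point moving average used to suppress ripple before
    zero-crossing detection."""
    kernel = np.ones(w) / w
    ext = np.concatenate([x[-(w // 2):], x, x[: w // 2]])
    return np.convolve(ext, kernel, mode="valid")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs (stop exclusive),
    merging wrap-around across the periodic boundary."""
    if not mask.any():
        return []
    starts = list(np.flatnonzero(np.diff(np.r_[0, mask.astype(int)]) == 1))
    stops = list(np.flatnonzero(np.diff(np.r_[mask.astype(int), 0]) == -1) + 1)
    runs = list(zip(starts, stops))
    if len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == mask.size:
        # periodic wrap: last run continues into the first
        runs = [(runs[-1][0], runs[0][1])] + runs[1:-1]
    return runs


def detect_valve_events(fs: FluxSeries, dur_ms: dict[str, float] | float = 15.0) -> ValveTimings:
    """Valve opening/closing times from sign changes of ventricular net flux.

    The inflow valve opens when dV_vent/dt turns positive and closes when the
    last filling wave ends; the outflow valve spans the negative (ejection)
    run.  Positive runs separated only by near-zero plateaus (diastasis) are
    merged.  More than one ejection or filling interval after smoothing is
    reported as an ambiguity error listing the candidate times.
    """
    events: dict[str, tuple[float, float]] = {}
    dt = fs.period / fs.t.size
    for side, (vent, _, inflow, outflow) in SIDES.items():
        key = f"net_{vent}"
        if key not in fs.fluxes:
            continue
        q = _moving_average(fs.fluxes[key])
        # tolerance masks spectral-differentiation ripple on the zero plateaus
        tol = 1e-3 * np.max(np.abs(q)) if np.max(np.abs(q)) > 0 else np.inf
        if not np.isfinite(tol):
            continue  # constant volume: no events
        neg_runs = _runs(q < -tol)
        pos_runs = _runs(q > tol)
        # merge positive runs separated only by |q| <= tol gaps
        merged: list[tuple[int, int]] = []
        for run in sorted(pos_runs):
            if merged and not (q[merged[-1][1] : run[0]] < -tol).any():
                merged[-1] = (merged[-1][0], run[1])
            else:
                merged.append(run)
        if len(neg_runs) != 1 or len(merged) != 1:
            cands = [fs.t[r[0] % fs.t.size] for r in neg_runs + merged]
            raise ValueError(
                f"ambiguous {vent} flux morphology: {len(neg_runs)} ejection and "
                f"{len(merged)} filling intervals; candidate times {cands}"
            )
        n_pts = fs.t.size
        # the tolerance shaves the run edges; walk back out to the sign change
        def extend(run: tuple[int, int], sign: float) -> tuple[int, int]:
            s, e = run
            for _ in range(n_pts):
                prev = (s - 1) % n_pts
                if sign * q[prev] > 0.0 and abs(q[prev]) < abs(q[s % n_pts]):
                    s = prev
                else:
                    break
            for _ in range(n_pts):
                nxt = e % n_pts
                if sign * q[nxt] > 0.0 and abs(q[nxt]) < abs(q[(e - 1) % n_pts]):
                    e += 1
                else:
                    break
            return s, e

        (n0, n1) = extend(neg_runs[0], -1.0)
        (p0, p1) = extend(merged[0], +1.0)
        events[outflow] = (fs.t[n0 % n_pts], fs.t[n1 % n_pts])
        events[inflow] = (fs.t[p0 % n_pts], fs.t[p1 % n_pts])
    if isinstance(dur_ms, (int, float)):
        dur = {v: float(dur_ms) for v in events}
    else:
        dur = {v: float(dur_ms.get(v, 15.0)) for v in events}
    return ValveTimings(period=fs.period, events=events, dur_ms=dur)
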