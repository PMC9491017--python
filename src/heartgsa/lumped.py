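"""Desk-scale 0D circuit model of one heart side driven by prescribed volumes.

Each side (left or right) is a small resistive network: a constant atrial
preload pressure source feeds the atrium through a venous resistance, the
atrium empties into the ventricle through the inflow valve, the ventricle
ejects through the outflow valve into a three-element Windkessel afterload.
Chamber wall motion is prescribed (the volume transients), so at every step
the two chamber mass balances

    Q_vein − Q_inflow  = dV_atrium/dt
    Q_inflow − Q_outflow = dV_ventricle/dt

determine the atrial and ventricular node pressures from a 2×2 linear solve,
after which the Windkessel distal pressure is advanced implicitly.

Valves are resistors whose value blends log-linearly between an open
resistance (a linearized orifice law at baseline peak flow) and a closed leak
resistance R_leak = μ·c_geom/κ set by a Darcy-type permeability parameter κ.
The geometry factor is calibrated so that the closed valve is effectively
impermeable over the whole κ range — leak flow under physiological pressure
heads stays below 0.1% of peak systolic flow — which makes every output
feature insensitive to κ by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .clinical import MMHG_TO_KPA
from .transients import SIDES, VolumeTransients, ValveTimings, smootherstep, spectral_derivative
from .windkessel import WindkesselParams, windkessel_step

log = logging.getLogger(__name__)

RHO_BLOOD = 1060.0  # kg/m^3, standard Newtonian value
MU_BLOOD = 4.0  # mPa·s

# Parameter ranges spanned by the sensitivity study (native units).
PARAM_RANGES = {
    "r_wk_ao": (37.46, 62.32),  # kPa·ms/mL
    "r_wk_pa": (27.81, 46.21),  # kPa·ms/mL
    "p_la": (7.5, 12.5),        # mmHg
    "p_ra": (3.5, 8.5),         # mmHg
    "kappa": (1e-9, 1e-5),      # permeability-like scale (log-uniform)
    "dur": (11.25, 18.75),      # ms
}


@dataclass(frozen=True)
class ValveGeometry:
    """Effective orifice area and closed-valve leak geometry for one valve.

    ``a_eff_cm2`` is a synthetic configuration value (not a measured orifice);
    ``leak_factor`` is the Darcy geometry factor c_geom in R_leak = μ·c_geom/κ,
    calibrated for leak dominance (see module docstring).  ``r_open`` overrides
    the linearized-orifice open resistance when given.
    """

    a_eff_cm2: float
    leak_factor: float = 625.0
    r_open: float | None = None

    def leak_resistance(self, kappa: float, mu_mpa_s: float = MU_BLOOD) -> float:
        """Closed-valve resistance in kPa·ms/mL; ∝ 1/κ."""
        if not kappa > 0:
            raise ValueError("kappa must be positive")
        mu_kpa_ms = mu_mpa_s * 1e-3  # mPa·s = 1e-3 Pa·s = 1e-3 kPa·ms
        return mu_kpa_ms * self.leak_factor / kappa

    def open_resistance(self, q_peak_ml_ms: float, rho: float = RHO_BLOOD) -> float:
        """Linearized orifice resistance Δp/Q = ρ·Q_peak/(2A²) in kPa·ms/mL,
        evaluated at the baseline peak flow; falls back to ``r_open`` or a
        nominal 5 kPa·ms/mL when there is no flow to linearize at."""
        if self.r_open is not None:
            return self.r_open
        if q_peak_ml_ms <= 0:
            return 5.0
        a_m2 = self.a_eff_cm2 * 1e-4
        q_m3_s = q_peak_ml_ms * 1e-3  # mL/ms = 1e-6 m³ / 1e-3 s
        r_pa_s_m3 = rho * q_m3_s / (2.0 * a_m2**2)
        return r_pa_s_m3 * 1e-6  # Pa·s/m³ -> kPa·ms/mL


DEFAULT_GEOMETRY = {
    "AV": ValveGeometry(3.0),
    "MV": ValveGeometry(4.5),
    "PV": ValveGeometry(3.5),
    "TV": ValveGeometry(5.0),
}


def valve_resistance(
    kappa: float,
    sigma: float | np.ndarray,
    geom: ValveGeometry,
    r_open: float,
    mu_mpa_s: float = MU_BLOOD,
) -> float | np.ndarray:
    """Valve resistance at open fraction σ: log-linear blend
    R(σ, κ) = R_open · (R_leak(κ)/R_open)^(1−σ)."""
    sigma = np.clip(sigma, 0.0, 1.0)
    r_leak = geom.leak_resistance(kappa, mu_mpa_s)
    return r_open * (r_leak / r_open) ** (1.0 - sigma)


def valve_open_fraction(
    t: float | np.ndarray, timings: ValveTimings, valve: str, dur_ms: float | None = None
) -> float | np.ndarray:
    """Open fraction σ(t) ∈ [0,1] with smootherstep transitions of width
    ``dur`` centered on the opening and closing events.

    σ is exactly 0 when fully closed and exactly 1 when fully open; an open
    interval narrower than the transition width is rejected as overlapping.
    """
    T = timings.period
    t_open, t_close = timings.events[valve]
    dur_s = (dur_ms if dur_ms is not None else timings.dur_ms[valve]) * 1e-3
    open_len = (t_close - t_open) % T
    closed_len = T - open_len
    if dur_s >= open_len or dur_s >= closed_len:
        raise ValueError(
            f"valve {valve}: transition width {dur_s*1e3:.1f} ms overlaps the "
            f"open ({open_len*1e3:.0f} ms) or closed ({closed_len*1e3:.0f} ms) interval"
        )
    # phase relative to opening event, wrapped to [0, T)
    tau = (np.asarray(t, dtype=float) - t_open) % T
    rise = smootherstep((tau + dur_s / 2.0) / dur_s)  # opening centered at tau=0
    fall = smootherstep((tau - (open_len - dur_s / 2.0)) / dur_s)  # closing at tau=open_len
    # re-opening at tau = T wraps into the start of the next cycle
    rise_next = smootherstep((tau - (T - dur_s / 2.0)) / dur_s)
    sigma = np.clip(rise - fall + rise_next, 0.0, 1.0)
    # snap roundoff at the window edges so σ is exactly 0 / 1 outside them
    sigma = np.where(sigma > 1.0 - 1e-12, 1.0, sigma)
    sigma = np.where(sigma < 1e-12, 0.0, sigma)
    return float(sigma) if np.isscalar(t) else sigma


@dataclass(frozen=True)
class SideContext:
    """Fixed per-side circuit context not varied by the sensitivity study."""

    windkessel: WindkesselParams  # Z and C are used; R comes from HeartModelParams
    r_vein: float = 5.0  # venous inflow resistance, kPa·ms/mL (synthetic default)
    # small chamber wall compliance (mL/kPa) regularizing the node pressures
    # while valves switch; quasi-static at the default step size
    c_chamber: float = 0.05
    geometry: Mapping[str, ValveGeometry] = field(default_factory=lambda: DEFAULT_GEOMETRY)
    rho: float = RHO_BLOOD
    mu: float = MU_BLOOD


@dataclass(frozen=True)
class HeartModelParams:
    """The per-side parameter vector of the sensitivity study plus context.

    ``kappa`` and ``dur_ms`` are per-valve maps keyed by valve name (inflow
    and outflow valve of the side).  Ranges follow the study design; set
    ``validate=False`` to explore outside them.
    """

    side: str
    r_wk: float  # afterload peripheral resistance, kPa·ms/mL
    p_atrium: float  # preload source pressure, mmHg
    kappa: Mapping[str, float]
    dur_ms: Mapping[str, float]
    context: SideContext = None  # type: ignore[assignment]
    validate: bool = True

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {sorted(SIDES)}")
        if self.context is None:
            raise ValueError("HeartModelParams requires a SideContext")
        if not self.validate:
            return
        r_key = "r_wk_ao" if self.side == "left" else "r_wk_pa"
        p_key = "p_la" if self.side == "left" else "p_ra"
        for key, value in ((r_key, self.r_wk), (p_key, self.p_atrium)):
            lo, hi = PARAM_RANGES[key]
            if not lo <= value <= hi:
                raise ValueError(f"{key}={value} outside study range [{lo}, {hi}]")
        for name, k in self.kappa.items():
            lo, hi = PARAM_RANGES["kappa"]
            if not lo <= k <= hi:
                raise ValueError(f"kappa[{name}]={k} outside [{lo}, {hi}]")
        for name, d in self.dur_ms.items():
            lo, hi = PARAM_RANGES["dur"]
            if not lo <= d <= hi:
                raise ValueError(f"dur[{name}]={d} ms outside [{lo}, {hi}]")


@dataclass
class SimulationTrace:
    """Time series from one simulation (pressures mmHg, flows mL/s).

    The last full beat is the analysis beat; ``beat_slice`` indexes it.
    """

    side: str
    t_s: np.ndarray
    dt_ms: float
    period_s: float
    n_beats: int
    p_atr: np.ndarray
    p_vent: np.ndarray
    p_art: np.ndarray
    p_dist: np.ndarray
    q_vein: np.ndarray
    q_in: np.ndarray
    q_out: np.ndarray
    sigma_in: np.ndarray
    sigma_out: np.ndarray
    v_atr: np.ndarray
    v_vent: np.ndarray
    converged: bool
    params: HeartModelParams | None = None
    diagnostic: str = ""

    @property
    def beat_slice(self) -> slice:
        steps = round(self.period_s * 1000.0 / self.dt_ms)
        return slice((self.n_beats - 1) * steps, self.n_beats * steps)

    def valve_velocity(self, valve: str) -> np.ndarray:
        """Effective velocity Q/A_eff in m/s for the side's inflow/outflow valve."""
        vent, atr, inflow, outflow = SIDES[self.side]
        if valve == inflow:
            q = self.q_in
        elif valve == outflow:
            q = self.q_out
        else:
            raise KeyError(f"valve {valve} not on side {self.side}")
        a_cm2 = self.params.context.geometry[valve].a_eff_cm2
        return (q / a_cm2) / 100.0  # (cm³/s)/cm² = cm/s -> m/s

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.t_s,
                "p_atr_mmhg": self.p_atr,
                "p_vent_mmhg": self.p_vent,
                "p_art_mmhg": self.p_art,
                "p_dist_mmhg": self.p_dist,
                "q_vein_ml_s": self.q_vein,
                "q_in_ml_s": self.q_in,
                "q_out_ml_s": self.q_out,
                "sigma_in": self.sigma_in,
                "sigma_out": self.sigma_out,
                "v_atr_ml": self.v_atr,
                "v_vent_ml": self.v_vent,
            }
        ).to_csv(path, index=False)


def _periodic_interp(t_query: np.ndarray, t_src: np.ndarray, y: np.ndarray, period: float) -> np.ndarray:
    tq = np.mod(t_query, period)
    t_ext = np.concatenate([t_src, [period]])
    y_ext = np.concatenate([y, [y[0]]])
    return np.interp(tq, t_ext, y_ext)


def simulate(
    params: HeartModelParams,
    vt: VolumeTransients,
    timings: ValveTimings,
    n_beats: int = 4,
    dt_ms: float = 0.5,
    sigma_override: Mapping[str, float] | None = None,
    p_bound_mmhg: float = 1000.0,
) -> SimulationTrace:
    """Run one side of the heart for ``n_beats`` cycles.

    The step size is snapped so that a beat contains an integer number of
    steps (periodicity of the prescribed motion).  ``sigma_override`` pins a
    valve's open fraction to a constant (used for circuit-level verification).
    A failed linear solve or a pressure excursion beyond ``p_bound_mmhg``
    marks the trace unconverged instead of raising.
    """
    if dt_ms > 1.0:
        raise ValueError("dt must be <= 1 ms")
    if n_beats < 2:
        raise ValueError("need at least 2 beats (last beat is the analysis beat)")
    side = params.side
    vent, atr, inflow, outflow = SIDES[side]
    ctx = params.context
    T_ms = vt.period * 1000.0
    steps_per_beat = int(round(T_ms / dt_ms))
    dt = T_ms / steps_per_beat  # ms, snapped
    n_steps = steps_per_beat * n_beats
    t_ms = np.arange(n_steps) * dt
    t_s = t_ms / 1000.0

    # prescribed volumes and their rates on the simulation grid (mL, mL/ms)
    dv_v_src = spectral_derivative(vt.volumes[vent], vt.period) / 1000.0
    dv_a_src = spectral_derivative(vt.volumes[atr], vt.period) / 1000.0
    v_vent = _periodic_interp(t_s, vt.t, vt.volumes[vent], vt.period)
    v_atr = _periodic_interp(t_s, vt.t, vt.volumes[atr], vt.period)
    dv_v = _periodic_interp(t_s, vt.t, dv_v_src, vt.period)
    dv_a = _periodic_interp(t_s, vt.t, dv_a_src, vt.period)

    # valve open fractions and resistances over the grid
    def sigma_for(valve: str) -> np.ndarray:
        if sigma_override and valve in sigma_override:
            return np.full(n_steps, float(sigma_override[valve]))
        if valve not in timings.events:  # no events (e.g. constant volumes): closed
            return np.zeros(n_steps)
        return valve_open_fraction(t_s, timings, valve, params.dur_ms.get(valve))

    sig_in = sigma_for(inflow)
    sig_out = sigma_for(outflow)
    q_peak_in = float(np.max(dv_v)) if np.max(dv_v) > 0 else 0.0
    q_peak_out = float(-np.min(dv_v)) if np.min(dv_v) < 0 else 0.0
    r_open_in = ctx.geometry[inflow].open_resistance(q_peak_in, ctx.rho)
    r_open_out = ctx.geometry[outflow].open_resistance(q_peak_out, ctx.rho)
    r_in = valve_resistance(params.kappa.get(inflow, 1e-7), sig_in, ctx.geometry[inflow], r_open_in, ctx.mu)
    r_out = valve_resistance(params.kappa.get(outflow, 1e-7), sig_out, ctx.geometry[outflow], r_open_out, ctx.mu)

    wk = WindkesselParams(z=ctx.windkessel.z, r=params.r_wk, c=ctx.windkessel.c)
    p_src = params.p_atrium * MMHG_TO_KPA
    ra = ctx.r_vein
    ro_total = r_out + wk.z  # outflow valve in series with characteristic impedance

    # warm-start the distal pressure on its periodic orbit: integrate the
    # Windkessel alone against the prescribed ejection flux for several beats
    q_eject = np.clip(-dv_v[:steps_per_beat], 0.0, None)
    p_c = float(np.mean(q_eject)) * wk.r
    for _ in range(10):
        for qe in q_eject:
            p_c, _ = windkessel_step(p_c, qe, wk, dt)

    p_a_arr = np.empty(n_steps)
    p_v_arr = np.empty(n_steps)
    p_art_arr = np.empty(n_steps)
    p_c_arr = np.empty(n_steps)
    qv_arr = np.empty(n_steps)
    qi_arr = np.empty(n_steps)
    qo_arr = np.empty(n_steps)
    converged = True
    diagnostic = ""
    bound_kpa = p_bound_mmhg * MMHG_TO_KPA
    c_dt = ctx.c_chamber / dt  # chamber compliance term (0 = algebraic nodes)
    p_a_prev = p_src
    p_v_prev = p_src

    for i in range(n_steps):
        ri, ro = r_in[i], ro_total[i]
        a11 = -(c_dt + 1.0 / ra + 1.0 / ri)
        a12 = 1.0 / ri
        a22 = -(c_dt + 1.0 / ri + 1.0 / ro)
        b1 = dv_a[i] - p_src / ra - c_dt * p_a_prev
        b2 = dv_v[i] - p_c / ro - c_dt * p_v_prev
        det = a11 * a22 - a12 * a12
        if det == 0.0 or not np.isfinite(det):
            converged = False
            diagnostic = f"singular node system at step {i} (t={t_s[i]:.4f} s)"
            break
        p_a = (b1 * a22 - a12 * b2) / det
        p_v = (a11 * b2 - a12 * b1) / det
        q_out = (p_v - p_c) / ro
        p_a_prev, p_v_prev = p_a, p_v
        p_c, p_art = windkessel_step(p_c, q_out, wk, dt)
        p_a_arr[i], p_v_arr[i] = p_a, p_v
        p_art_arr[i], p_c_arr[i] = p_art, p_c
        qv_arr[i] = (p_src - p_a) / ra
        qi_arr[i] = (p_a - p_v) / ri
        qo_arr[i] = q_out
        if abs(p_v) > bound_kpa or abs(p_a) > bound_kpa:
            converged = False
            diagnostic = f"pressure bound {p_bound_mmhg} mmHg exceeded at t={t_s[i]:.4f} s"
            break

    if not converged:
        log.warning("simulation discarded: %s", diagnostic)
        for arr in (p_a_arr, p_v_arr, p_art_arr, p_c_arr, qv_arr, qi_arr, qo_arr):
            arr[i:] = np.nan

    to_mmhg = 1.0 / MMHG_TO_KPA
    to_ml_s = 1000.0  # mL/ms -> mL/s
    return SimulationTrace(
        side=side,
        t_s=t_s,
        dt_ms=dt,
        period_s=vt.period,
        n_beats=n_beats,
        p_atr=p_a_arr * to_mmhg,
        p_vent=p_v_arr * to_mmhg,
        p_art=p_art_arr * to_mmhg,
        p_dist=p_c_arr * to_mmhg,
        q_vein=qv_arr * to_ml_s,
        q_in=qi_arr * to_ml_s,
        q_out=qo_arr * to_ml_s,
        sigma_in=sig_in,
        sigma_out=sig_out,
        v_atr=v_atr,
        v_vent=v_vent,
        converged=converged,
        params=params,
        diagnostic=diagnostic,
    )


def run_metadata_json(trace: SimulationTrace, path: str | Path, seed: int | None = None) -> None:
    """Write run metadata (parameters, convergence, seed) next to a trace CSV."""
    p = trace.params
    payload = {
        "side": trace.side,
        "converged": trace.converged,
        "diagnostic": trace.diagnostic,
        "dt_ms": trace.dt_ms,
        "n_beats": trace.n_beats,
        "seed": seed,
        "params": None
        if p is None
        else {
            "r_wk": p.r_wk,
            "p_atrium_mmhg": p.p_atrium,
            "kappa": dict(p.kappa),
            "dur_ms": dict(p.dur_ms),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
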