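"""Scalar output features extracted from a simulation trace.

The sensitivity study characterizes each simulation by a handful of named
scalars: windowed mean pressure gradients across the valves (mmHg), maximal
effective valve velocities (m/s), mean kinetic-energy proxies per compartment
(mJ), and compartmental residence times (s).  All are computed on the
analysis beat (the last simulated cycle).

The kinetic energy is a 0D proxy ½·ρ·V(t)·v(t)² built from a compartment's
volume and the effective velocity of its dominant outflow branch — not a
volume-integrated field energy.  Residence times come from a well-mixed
compartmental age model: the mean age a(t) of blood in a compartment obeys

    d(a·V)/dt = V + Q_in·a_in − Q_out·a

with fresh inflow (a_in = 0), integrated over repeated cycles until its cycle
mean settles; the converged cycle-mean age is reported.  The left atrial
appendage is modeled as a small side pocket exchanging volume with the atrium
at a configured fraction of atrial inflow (a synthetic analog).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .lumped import RHO_BLOOD, SimulationTrace
from .transients import SIDES, ValveTimings

log = logging.getLogger(__name__)

WINDOWS = ("cycle", "systole", "diastole")


@dataclass(frozen=True)
class ArteryConfig:
    """Synthetic arterial compartment used for the kinetic-energy proxy."""

    volume_ml: float
    area_cm2: float


@dataclass(frozen=True)
class FeatureConfig:
    rho: float = RHO_BLOOD
    aorta: ArteryConfig = ArteryConfig(volume_ml=150.0, area_cm2=5.0)
    pulmonary_artery: ArteryConfig = ArteryConfig(volume_ml=120.0, area_cm2=4.5)
    appendage_volume_ml: float = 10.0
    appendage_exchange_fraction: float = 0.3
    rt_rtol: float = 1e-3  # cycle-to-cycle relative change for age convergence
    rt_max_cycles: int = 400


@dataclass(frozen=True)
class FeatureDef:
    """Registered definition: kind, site, and averaging window."""

    kind: str  # gradient | max_velocity | kinetic_energy | residence_time
    site: str  # valve name or compartment name
    window: str = "cycle"
    unit: str = ""


def default_registry(side: str, window: str = "cycle") -> dict[str, FeatureDef]:
    """The per-side feature registry of the study.

    ``window`` applies to the valve gradients; the physiologically named
    alternative ('systole' for the outflow valve, 'diastole' for the inflow
    valve) is selected by passing window='named'.
    """
    def gwin(default: str) -> str:
        return default if window == "named" else window

    if side == "left":
        return {
            "dp_AV": FeatureDef("gradient", "AV", gwin("systole"), "mmHg"),
            "dp_MV": FeatureDef("gradient", "MV", gwin("diastole"), "mmHg"),
            "Ek_LV": FeatureDef("kinetic_energy", "LV", unit="mJ"),
            "Ek_AO": FeatureDef("kinetic_energy", "AO", unit="mJ"),
            "Ek_LA": FeatureDef("kinetic_energy", "LA", unit="mJ"),
            "RT_LV": FeatureDef("residence_time", "LV", unit="s"),
            "RT_APP": FeatureDef("residence_time", "APP", unit="s"),
            "maxv_AV": FeatureDef("max_velocity", "AV", unit="m/s"),
            "maxv_MV": FeatureDef("max_velocity", "MV", unit="m/s"),
        }
    if side == "right":
        return {
            "dp_PV": FeatureDef("gradient", "PV", gwin("systole"), "mmHg"),
            "dp_TV": FeatureDef("gradient", "TV", gwin("diastole"), "mmHg"),
            "Ek_RV": FeatureDef("kinetic_energy", "RV", unit="mJ"),
            "Ek_PV": FeatureDef("kinetic_energy", "PA", unit="mJ"),
            "Ek_RA": FeatureDef("kinetic_energy", "RA", unit="mJ"),
            "RT_RV": FeatureDef("residence_time", "RV", unit="s"),
            "maxv_PV": FeatureDef("max_velocity", "PV", unit="m/s"),
            "maxv_TV": FeatureDef("max_velocity", "TV", unit="m/s"),
        }
    raise ValueError(f"unknown side '{side}'")


@dataclass
class FeatureVector(Mapping):
    """Named scalar outputs of one simulation, with per-feature flags."""

    values: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)
    valid: bool = True
    run_id: str = ""

    def __getitem__(self, k: str) -> float:
        return self.values[k]

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def to_row(self) -> dict[str, float | str | bool]:
        return {"run_id": self.run_id, "valid": self.valid, **self.values}


def _beat_arrays(trace: SimulationTrace) -> dict[str, np.ndarray]:
    s = trace.beat_slice
    return {
        "t": trace.t_s[s],
        "p_atr": trace.p_atr[s],
        "p_vent": trace.p_vent[s],
        "p_art": trace.p_art[s],
        "q_vein": trace.q_vein[s],
        "q_in": trace.q_in[s],
        "q_out": trace.q_out[s],
        "v_atr": trace.v_atr[s],
        "v_vent": trace.v_vent[s],
    }


def _window_mask(
    trace: SimulationTrace, timings: ValveTimings, window: str, valve: str
) -> np.ndarray:
    """Boolean mask over the analysis beat selecting the averaging window.

    'systole' is the outflow-valve open interval and 'diastole' the
    inflow-valve open interval, both trimmed by half a transition width at
    each end so that means never straddle valve switching.
    """
    b = trace.beat_slice
    t = np.mod(trace.t_s[b], trace.period_s)
    if window == "cycle":
        return np.ones(t.size, dtype=bool)
    vent, atr, inflow, outflow = SIDES[trace.side]
    ref = outflow if window == "systole" else inflow
    if ref not in timings.events:
        raise ValueError(f"no {window} window: valve {ref} has no events")
    t_open, t_close = timings.events[ref]
    half = timings.dur_ms.get(ref, 15.0) * 1e-3 / 2.0
    T = trace.period_s
    lo = (t_open + half) % T
    hi = (t_close - half) % T
    mask = (t >= lo) & (t < hi) if lo <= hi else (t >= lo) | (t < hi)
    if not mask.any():
        raise ValueError(f"empty {window} window for valve {valve}")
    return mask


def mean_valve_gradient(
    trace: SimulationTrace, timings: ValveTimings, valve: str, window: str = "cycle"
) -> float:
    """Time-mean upstream-minus-downstream pressure difference (mmHg) over the
    chosen window of the analysis beat."""
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}")
    arr = _beat_arrays(trace)
    vent, atr, inflow, outflow = SIDES[trace.side]
    if valve == outflow:
        dp = arr["p_vent"] - arr["p_art"]
    elif valve == inflow:
        dp = arr["p_atr"] - arr["p_vent"]
    else:
        raise KeyError(f"valve {valve} not on side {trace.side}")
    if window == "cycle":
        # full periodic beat: the plain sample mean is the exact time average
        return float(np.mean(dp))
    mask = _window_mask(trace, timings, window, valve)
    return _window_time_average(dp, mask)


def _window_time_average(y: np.ndarray, mask: np.ndarray) -> float:
    """Trapezoid-rule time average of y over a contiguous (possibly wrapped)
    window on the uniform beat grid."""
    idx = np.flatnonzero(mask)
    gaps = np.flatnonzero(np.diff(idx) > 1)
    if gaps.size:  # wrapped window: rotate so it becomes contiguous
        split = gaps[0] + 1
        idx = np.concatenate([idx[split:], idx[:split]])
    yw = y[idx]
    return float(np.trapezoid(yw) / (yw.size - 1))


def max_valve_velocity(trace: SimulationTrace, valve: str) -> float:
    """Maximum |Q|/A_eff over the analysis beat, in m/s."""
    v = trace.valve_velocity(valve)[trace.beat_slice]
    return float(np.max(np.abs(v)))


def _compartment_series(
    trace: SimulationTrace, compartment: str, cfg: FeatureConfig
) -> tuple[np.ndarray, np.ndarray]:
    """(volume mL, branch velocity m/s) series over the analysis beat for the
    kinetic-energy proxy; branch = the compartment's dominant outflow."""
    arr = _beat_arrays(trace)
    vent, atr, inflow, outflow = SIDES[trace.side]
    geom = trace.params.context.geometry
    if compartment == vent:
        return arr["v_vent"], (arr["q_out"] / geom[outflow].a_eff_cm2) / 100.0
    if compartment == atr:
        return arr["v_atr"], (arr["q_in"] / geom[inflow].a_eff_cm2) / 100.0
    if compartment in ("AO", "PA"):
        art = cfg.aorta if compartment == "AO" else cfg.pulmonary_artery
        vol = np.full(arr["q_out"].size, art.volume_ml)
        return vol, (arr["q_out"] / art.area_cm2) / 100.0
    raise KeyError(f"unknown compartment '{compartment}' on side {trace.side}")


def mean_kinetic_energy(
    trace: SimulationTrace, compartment: str, cfg: FeatureConfig | None = None
) -> float:
    """Time-mean of ½·ρ·V(t)·v(t)² over the analysis beat, in mJ."""
    cfg = cfg or FeatureConfig()
    vol_ml, v_ms = _compartment_series(trace, compartment, cfg)
    # ½ ρ[kg/m³] V[m³] v² [m²/s²] = J; V mL = 1e-6 m³; J -> mJ is 1e3
    ek = 0.5 * cfg.rho * (vol_ml * 1e-6) * v_ms**2 * 1e3
    return float(np.mean(ek))


class WashoutDivergence(RuntimeError):
    """Raised when a compartment has no inflow to wash it out."""


def _age_cycle(
    a0: float, vol: np.ndarray, q_out: np.ndarray, dt_s: float
) -> tuple[np.ndarray, float]:
    """One cycle of the well-mixed age equation with fresh inflow.

    Explicit update of d(aV)/dt = V − Q_out·a on the beat grid; returns the
    age series and the end-of-cycle age.
    """
    n = vol.size
    a = np.empty(n)
    a_prev = a0
    for k in range(n):
        v_now = vol[k]
        v_next = vol[(k + 1) % n]
        num = a_prev * v_now + dt_s * (v_now - q_out[k] * a_prev)
        a_new = num / v_next
        a[k] = a_new
        a_prev = a_new
    return a, a_prev


def residence_time(
    trace: SimulationTrace,
    compartment: str,
    cfg: FeatureConfig | None = None,
) -> float:
    """Converged cycle-mean age of blood in a compartment, in seconds.

    The analysis-beat flows are cycled until the cycle-mean age changes by
    less than ``cfg.rt_rtol`` between beats.  A compartment without inflow
    cannot wash out; that raises :class:`WashoutDivergence`.
    """
    cfg = cfg or FeatureConfig()
    arr = _beat_arrays(trace)
    dt_s = trace.dt_ms / 1000.0
    vent, atr, inflow, outflow = SIDES[trace.side]

    if compartment == vent:
        vol = arr["v_vent"]
        q_in = np.clip(arr["q_in"], 0.0, None)
        q_out = np.clip(arr["q_out"], 0.0, None)
    elif compartment == atr:
        vol = arr["v_atr"]
        q_in = np.clip(arr["q_vein"], 0.0, None)
        q_out = np.clip(arr["q_in"], 0.0, None)
    elif compartment == "APP":
        return _appendage_residence_time(trace, cfg)
    else:
        raise KeyError(f"unknown compartment '{compartment}'")

    if float(np.mean(q_in)) * trace.period_s < 1e-9 * float(np.mean(vol)):
        raise WashoutDivergence(f"compartment {compartment} has no inflow")

    a_end = 0.0
    prev_mean = None
    for _ in range(cfg.rt_max_cycles):
        a, a_end = _age_cycle(a_end, vol, q_out, dt_s)
        mean_a = float(np.mean(a))
        if prev_mean is not None and abs(mean_a - prev_mean) <= cfg.rt_rtol * abs(mean_a):
            return mean_a
        prev_mean = mean_a
    raise WashoutDivergence(
        f"compartment {compartment}: age did not converge in {cfg.rt_max_cycles} cycles"
    )


def _appendage_residence_time(trace: SimulationTrace, cfg: FeatureConfig) -> float:
    """Age of the appendage side pocket exchanging with the atrium.

    The pocket (constant volume) exchanges a fixed fraction of the positive
    atrial inflow bidirectionally with the atrium, whose own age series is
    computed first; the pocket's inflow age is the atrial age.
    """
    arr = _beat_arrays(trace)
    dt_s = trace.dt_ms / 1000.0
    vent, atr, inflow, outflow = SIDES[trace.side]
    vol_atr = arr["v_atr"]
    q_in_atr = np.clip(arr["q_vein"], 0.0, None)
    q_out_atr = np.clip(arr["q_in"], 0.0, None)
    if float(np.mean(q_in_atr)) * trace.period_s < 1e-9 * float(np.mean(vol_atr)):
        raise WashoutDivergence("atrium has no inflow; appendage cannot wash out")

    q_ex = cfg.appendage_exchange_fraction * q_in_atr
    if float(np.mean(q_ex)) <= 0.0:
        raise WashoutDivergence("appendage exchange flow is zero")
    v_app = cfg.appendage_volume_ml

    a_atr_end = 0.0
    a_app = 0.0
    prev_mean = None
    n = vol_atr.size
    for _ in range(cfg.rt_max_cycles):
        a_atr, a_atr_end = _age_cycle(a_atr_end, vol_atr, q_out_atr, dt_s)
        app = np.empty(n)
        for k in range(n):
            # d(a_app V_app)/dt = V_app + Q_ex (a_atr − a_app), V_app constant
            a_app = a_app + dt_s * (1.0 + q_ex[k] * (a_atr[k] - a_app) / v_app)
            app[k] = a_app
        mean_a = float(np.mean(app))
        if prev_mean is not None and abs(mean_a - prev_mean) <= cfg.rt_rtol * abs(mean_a):
            return mean_a
        prev_mean = mean_a
    raise WashoutDivergence("appendage age did not converge")


def extract_features(
    trace: SimulationTrace,
    timings: ValveTimings,
    registry: Mapping[str, FeatureDef] | None = None,
    cfg: FeatureConfig | None = None,
    run_id: str = "",
) -> FeatureVector:
    """Apply every registered feature definition to the analysis beat.

    An unconverged trace yields a vector marked invalid (it is excluded from
    emulator training); a residence-time washout failure flags that feature
    and records NaN rather than failing the whole vector.
    """
    registry = registry or default_registry(trace.side)
    cfg = cfg or FeatureConfig()
    values: dict[str, float] = {}
    units: dict[str, str] = {}
    flags: dict[str, str] = {}
    if not trace.converged:
        return FeatureVector(
            values={k: math.nan for k in registry},
            units={k: d.unit for k, d in registry.items()},
            flags={k: "unconverged" for k in registry},
            valid=False,
            run_id=run_id,
        )
    for name, d in registry.items():
        units[name] = d.unit
        try:
            if d.kind == "gradient":
                values[name] = mean_valve_gradient(trace, timings, d.site, d.window)
            elif d.kind == "max_velocity":
                values[name] = max_valve_velocity(trace, d.site)
            elif d.kind == "kinetic_energy":
                values[name] = mean_kinetic_energy(trace, d.site, cfg)
            elif d.kind == "residence_time":
                values[name] = residence_time(trace, d.site, cfg)
            else:
                raise ValueError(f"unknown feature kind '{d.kind}'")
        except WashoutDivergence as exc:
            log.warning("feature %s flagged: %s", name, exc)
            values[name] = math.nan
            flags[name] = "washout-divergence"
    return FeatureVector(values=values, units=units, flags=flags, valid=True, run_id=run_id)


def features_to_csv(vectors: list[FeatureVector], path: str | Path) -> pd.DataFrame:
    """Serialize a batch of feature vectors to one CSV row per run."""
    df = pd.DataFrame([v.to_row() for v in vectors])
    df.to_csv(path, index=False)
    return df
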