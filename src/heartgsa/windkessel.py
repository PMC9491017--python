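"""Three-element Windkessel afterload: estimation from clinical scalars and
time stepping.

The arterial outlets are closed by a three-element Windkessel: characteristic
impedance Z in series with a parallel peripheral resistance R and compliance
C.  Parameters are estimated from cuff pressures and cardiac output for the
systemic side, and from an assumed mean pulmonary artery pressure for the
pulmonary side:

    R = MAP / CO        (kPa·ms/mL, with 1 mmHg = 0.133322 kPa)
    Z = 0.05 · R
    C = T_cycle / R     (mL/kPa, T_cycle in ms)

The compliance formula is the period-over-resistance reading, which makes the
Windkessel relaxation time R·C equal one cardiac cycle.  The distal state is
advanced with an implicit Euler step of C·dp_c/dt = q_in − p_c/R, which is
unconditionally stable at any simulator step size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .clinical import MMHG_TO_KPA

MAP_CONVENTIONS = ("third_pulse", "third_pulse_split_z", "two_fifths_pulse")


@dataclass(frozen=True)
class WindkesselParams:
    """Z (kPa·ms/mL), R (kPa·ms/mL), C (mL/kPa)."""

    z: float
    r: float
    c: float

    def __post_init__(self) -> None:
        if not (self.z > 0 and self.r > 0 and self.c > 0):
            raise ValueError(f"Windkessel parameters must be positive: {self}")
        if not self.z < self.r:
            raise ValueError(f"characteristic impedance must satisfy Z < R: {self}")

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["units"] = {"z": "kPa·ms/mL", "r": "kPa·ms/mL", "c": "mL/kPa"}
        Path(path).write_text(json.dumps(payload, indent=2))


def mean_arterial_pressure(p_sys: float, p_dia: float, convention: str = "third_pulse") -> float:
    """MAP in mmHg from cuff pressures under a named convention.

    ``third_pulse``: dia + (sys − dia)/3 (the standard resting estimate);
    ``two_fifths_pulse``: dia + 0.4·(sys − dia) (common at elevated rates).
    """
    pp = p_sys - p_dia
    if convention in ("third_pulse", "third_pulse_split_z"):
        return p_dia + pp / 3.0
    if convention == "two_fifths_pulse":
        return p_dia + 0.4 * pp
    raise ValueError(f"unknown MAP convention '{convention}'; choose from {MAP_CONVENTIONS}")


def _from_map_and_co(map_mmhg: float, co_l_min: float, hr: float, split_z: bool) -> WindkesselParams:
    co_ml_ms = co_l_min * 1000.0 / 60000.0  # L/min -> mL/ms
    r_total = map_mmhg * MMHG_TO_KPA / co_ml_ms
    r = 0.95 * r_total if split_z else r_total
    z = 0.05 * r
    t_cycle_ms = 60000.0 / hr
    c = t_cycle_ms / r
    return WindkesselParams(z=z, r=r, c=c)


def estimate_systemic_windkessel(
    p_sys: float,
    p_dia: float,
    hr: float,
    co: float,
    map_convention: str = "third_pulse",
) -> WindkesselParams:
    """Systemic (aortic) Windkessel from cuff pressures (mmHg), HR (bpm) and
    CO (L/min).

    The ``*_split_z`` convention assigns R = 0.95·R_total with Z absorbing the
    remaining 5%; otherwise R = R_total and Z = 0.05·R sits on top.
    """
    if not p_sys > p_dia:
        raise ValueError("require p_sys > p_dia")
    if not co > 0:
        raise ValueError("require co > 0")
    map_mmhg = mean_arterial_pressure(p_sys, p_dia, map_convention)
    return _from_map_and_co(map_mmhg, co, hr, split_z=map_convention.endswith("split_z"))


def estimate_pulmonary_windkessel(
    rv_co: float, mpap: float = 14.0, hr: float = 83.0
) -> WindkesselParams:
    """Pulmonary Windkessel from an assumed mean PA pressure (default 14 mmHg)
    and the right-ventricular cardiac output (L/min)."""
    if not rv_co > 0:
        raise ValueError("require rv_co > 0")
    if not mpap > 0:
        raise ValueError("require mpap > 0")
    return _from_map_and_co(mpap, rv_co, hr, split_z=False)


def windkessel_step(
    p_c: float, q_in: float, params: WindkesselParams, dt: float
) -> tuple[float, float]:
    """Advance the distal pressure one implicit-Euler step.

    ``p_c`` in kPa, ``q_in`` in mL/ms, ``dt`` in ms.  Returns the new distal
    pressure and the proximal pressure p = p_c + Z·q_in (evaluated at the new
    state).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    a = dt / params.c
    p_c_new = (p_c + a * q_in) / (1.0 + a / params.r)
    return p_c_new, p_c_new + params.z * q_in
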