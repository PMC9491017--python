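"""Patient-record handling and clinical validation arithmetic.

Loads the small table of clinical scalars that anchors every baseline in the
pipeline (ventricular volumes, heart rate, cuff pressures), derives stroke
volume / cardiac output / ejection fraction from it, and compares simulated
output features against clinically measured values as a relative-error table.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

log = logging.getLogger(__name__)

MMHG_TO_KPA = 0.133322

# Published reference values for the validation worked example: feature values
# from the cluster-scale CFD study alongside the clinical measurements (means
# of three).  They exercise the report format; the desk-scale circuit model is
# different physics and does not reproduce the in-silico column.
REFERENCE_IN_SILICO = {
    "dp_AV": 4.61, "dp_MV": 2.71, "dp_PV": 2.35, "dp_TV": 5.73,  # mmHg
    "Ek_LV": 16.71, "Ek_AO": 22.59, "Ek_LA": 23.33,  # mJ
    "Ek_RV": 3.65, "Ek_PV": 5.51, "Ek_RA": 9.59,
    "RT_LV": 0.811, "RT_APP": 0.854, "RT_RV": 0.91,  # s
    "maxv_AV": 1.13, "maxv_MV": 0.73, "maxv_PV": 0.71, "maxv_TV": 0.57,  # m/s
}
REFERENCE_CLINICAL = {
    "dp_AV": 5.0, "dp_MV": 2.38, "dp_PV": 3.0, "dp_TV": 47.0,  # mmHg
    "maxv_AV": 1.15, "maxv_MV": 0.81, "maxv_PV": 0.814, "maxv_TV": 3.43,  # m/s
}

_REQUIRED_KEYS = ("lvedv", "lvesv", "hr", "p_sys_cuff", "p_dia_cuff")
_OPTIONAL_KEYS = ("co", "rvedv", "rvesv")


class ValidationError(ValueError):
    """A record violated a physiological invariant or is missing a key."""


@dataclass(frozen=True)
class PatientRecord:
    """Clinical scalars for one patient.

    Volumes in mL, heart rate in beats/min, cuff pressures in mmHg, cardiac
    output (optional, derivable) in L/min.
    """

    lvedv: float
    lvesv: float
    hr: float
    p_sys_cuff: float
    p_dia_cuff: float
    co: float | None = None
    rvedv: float | None = None
    rvesv: float | None = None

    def __post_init__(self) -> None:
        if not (self.lvedv > self.lvesv > 0):
            raise ValidationError(
                f"require lvedv > lvesv > 0, got lvedv={self.lvedv}, lvesv={self.lvesv}"
            )
        if not self.hr > 0:
            raise ValidationError(f"require hr > 0, got {self.hr}")
        if not (self.p_sys_cuff > self.p_dia_cuff > 0):
            raise ValidationError(
                "require p_sys_cuff > p_dia_cuff > 0, got "
                f"{self.p_sys_cuff}/{self.p_dia_cuff}"
            )
        if self.rvedv is not None and self.rvesv is not None:
            if not (self.rvedv > self.rvesv > 0):
                raise ValidationError(
                    f"require rvedv > rvesv > 0, got rvedv={self.rvedv}, rvesv={self.rvesv}"
                )

    @property
    def period_s(self) -> float:
        """Cardiac cycle length T = 60/HR in seconds."""
        return 60.0 / self.hr


def load_patient_record(path: str | Path) -> PatientRecord:
    """Read a patient record from a two-column CSV (key,value) or YAML/JSON file.

    Raises :class:`ValidationError` naming the key when a required scalar is
    missing; optional fields absent from the file are left as ``None``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".yaml", ".yml", ".json"):
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: expected a mapping of keys to values")
    else:
        raw = {}
        with path.open(newline="") as fh:
            reader = csv.reader(fh)
            rows = [r for r in reader if r and r[0].strip()]
        # tolerate an optional "key,value" header row
        if rows and rows[0][0].strip().lower() in ("key", "parameter", "name"):
            rows = rows[1:]
        for row in rows:
            if len(row) < 2:
                raise ValidationError(f"{path}: malformed row {row!r}")
            raw[row[0].strip()] = row[1].strip()

    for key in _REQUIRED_KEYS:
        if key not in raw or raw[key] in (None, ""):
            raise ValidationError(f"patient record missing required key '{key}'")
    kwargs = {k: float(raw[k]) for k in _REQUIRED_KEYS}
    for key in _OPTIONAL_KEYS:
        if key in raw and raw[key] not in (None, ""):
            kwargs[key] = float(raw[key])
    return PatientRecord(**kwargs)


def stroke_volume(rec: PatientRecord) -> float:
    """Left-ventricular stroke volume EDV − ESV in mL."""
    return rec.lvedv - rec.lvesv


def cardiac_output(rec: PatientRecord) -> float:
    """Cardiac output SV × HR in L/min, derived from the volumes."""
    return stroke_volume(rec) * rec.hr / 1000.0


def ejection_fraction(rec: PatientRecord) -> float:
    """Left-ventricular ejection fraction 100 × SV / EDV in percent (unrounded)."""
    return 100.0 * stroke_volume(rec) / rec.lvedv


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass
class ClinicalMeasurements:
    """Named clinical measurements: feature name -> (value, unit)."""

    values: dict[str, float]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"clinical value for '{name}' must be finite and >= 0")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def __iter__(self):
        return iter(self.values)


def load_clinical_table(path: str | Path) -> ClinicalMeasurements:
    """Read a clinical measurement table CSV with columns (feature, value, unit)."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    for need in ("feature", "value"):
        if need not in cols:
            raise ValidationError(f"clinical table needs a '{need}' column")
    values = dict(zip(df[cols["feature"]].astype(str), df[cols["value"]].astype(float)))
    units = (
        dict(zip(df[cols["feature"]].astype(str), df[cols["unit"]].astype(str)))
        if "unit" in cols
        else {}
    )
    return ClinicalMeasurements(values=values, units=units)


def relative_error_report(
    sim: Mapping[str, float], clin: ClinicalMeasurements
) -> pd.DataFrame:
    """Per-feature relative error of simulated vs clinically measured values.

    For every feature present on both sides, computes 100·|sim − clin| / clin
    (clinical value as denominator) plus an integer-rounded display column.
    A zero clinical value flags the row "undefined" rather than raising;
    features present on only one side are omitted and logged.
    """
    shared = [n for n in clin if n in sim]
    if not shared:
        raise ValidationError("no shared feature names between simulation and clinic")
    for n in clin:
        if n not in sim:
            log.info("clinical feature '%s' has no simulated counterpart; omitted", n)
    for n in sim:
        if n not in clin:
            log.info("simulated feature '%s' has no clinical counterpart; omitted", n)

    rows = []
    for name in shared:
        s, c = float(sim[name]), float(clin[name])
        if c == 0.0:
            rows.append((name, s, c, math.nan, None, "undefined"))
        else:
            err = 100.0 * abs(s - c) / c
            rows.append((name, s, c, err, round_half_away(err), "ok"))
    return pd.DataFrame(
        rows,
        columns=["feature", "sim", "clin", "rel_err_pct", "rel_err_pct_rounded", "flag"],
    )


def write_report(df: pd.DataFrame, out_csv: str | Path, out_json: str | Path | None = None) -> None:
    """Serialize a relative-error report to CSV and (optionally) JSON."""
    df.to_csv(out_csv, index=False)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(df.to_dict(orient="records"), indent=2))
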