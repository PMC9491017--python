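"""End-to-end orchestration: transients → design → simulations → features →
emulators → screening → sensitivity indices → report.

The left-heart study varies the 6-parameter vector
{r_wk_ao, p_la, kappa_av, kappa_mv, dur_av, dur_mv}; the right-heart study
varies {r_wk_pa, p_ra, dur_pv, dur_tv} (the valve permeability parameters are
dropped there, their influence being negligible by construction).  All stages
are seeded and write deterministic artifact names, so a repeated run with the
same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import ClinicalMeasurements, PatientRecord, load_patient_record, relative_error_report
from .design import Parameter, ParameterSpace, latin_hypercube
from .emulator import GPEConfig, TrainedGPE, fit_gpe, save_gpe, screen_emulators
from .features import FeatureConfig, FeatureVector, default_registry, extract_features, features_to_csv
from .lumped import HeartModelParams, PARAM_RANGES, SideContext, simulate
from .sobol import SobolResult, gsa_with_emulator, heatmap_table, screen_indices
from .transients import ShapeParams, ValveTimings, derive_fluxes, detect_valve_events, generate_volume_transients
from .windkessel import estimate_pulmonary_windkessel, estimate_systemic_windkessel

log = logging.getLogger(__name__)

# study baselines (native units); ranges in lumped.PARAM_RANGES are authoritative
BASELINES = {
    "r_wk_ao": 49.89,
    "r_wk_pa": 37.01,
    "p_la": 10.0,
    "p_ra": 5.0,
    "kappa": 1e-7,  # geometric midpoint of the log range
    "dur": 15.0,
}

LEFT_PARAMS = ("r_wk_ao", "p_la", "kappa_av", "kappa_mv", "dur_av", "dur_mv")
RIGHT_PARAMS = ("r_wk_pa", "p_ra", "dur_pv", "dur_tv")


def side_parameter_space(side: str) -> ParameterSpace:
    """The study's per-side parameter space with the published ranges."""
    def rng(key: str) -> tuple[float, float]:
        return PARAM_RANGES[key]

    if side == "left":
        return ParameterSpace(
            (
                Parameter("r_wk_ao", *rng("r_wk_ao"), baseline=BASELINES["r_wk_ao"]),
                Parameter("p_la", *rng("p_la"), baseline=BASELINES["p_la"]),
                Parameter("kappa_av", *rng("kappa"), scale="log10", baseline=BASELINES["kappa"]),
                Parameter("kappa_mv", *rng("kappa"), scale="log10", baseline=BASELINES["kappa"]),
                Parameter("dur_av", *rng("dur"), baseline=BASELINES["dur"]),
                Parameter("dur_mv", *rng("dur"), baseline=BASELINES["dur"]),
            )
        )
    if side == "right":
        return ParameterSpace(
            (
                Parameter("r_wk_pa", *rng("r_wk_pa"), baseline=BASELINES["r_wk_pa"]),
                Parameter("p_ra", *rng("p_ra"), baseline=BASELINES["p_ra"]),
                Parameter("dur_pv", *rng("dur"), baseline=BASELINES["dur"]),
                Parameter("dur_tv", *rng("dur"), baseline=BASELINES["dur"]),
            )
        )
    raise ValueError(f"unknown side '{side}'")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    record_path: str | None = None
    record: PatientRecord | None = None
    sides: tuple[str, ...] = ("left",)
    n_train: int = 60
    n_saltelli: int = 10000
    n_draws: int = 20
    k_folds: int = 5
    seed_design: int = 101
    seed_fit: int = 202
    seed_gsa: int = 303
    n_beats: int = 4
    dt_ms: float = 0.5
    shape: ShapeParams = field(default_factory=ShapeParams)
    gpe: GPEConfig = field(default_factory=GPEConfig)
    feature_cfg: FeatureConfig = field(default_factory=FeatureConfig)
    gradient_window: str = "cycle"  # registry window for valve gradients
    r2_threshold: float = 0.5
    negligible_threshold: float = 0.01
    rv_co: float | None = None  # L/min; defaults to the left-side CO (balanced)
    outdir: str = "heartgsa_out"
    resume: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "sides" in raw:
            raw["sides"] = tuple(raw["sides"])
        if "shape" in raw and isinstance(raw["shape"], dict):
            raw["shape"] = ShapeParams(**raw["shape"])
        if "gpe" in raw and isinstance(raw["gpe"], dict):
            raw["gpe"] = GPEConfig(**raw["gpe"])
        return cls(**raw)

    def digest(self) -> str:
        payload = {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(self).items()
            if k not in ("outdir", "resume")
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Record of what a pipeline run produced."""

    config_digest: str
    version: str
    sides: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"config_digest": self.config_digest, "version": self.version, "sides": self.sides},
                indent=2,
            )
        )


def _resolve_record(cfg: RunConfig) -> PatientRecord:
    if cfg.record is not None:
        return cfg.record
    if cfg.record_path is not None:
        return load_patient_record(cfg.record_path)
    raise ValueError("RunConfig needs a patient record or a record_path")


def _sample_to_params(
    side: str, row: dict[str, float], ctx: SideContext
) -> tuple[HeartModelParams, dict[str, float]]:
    if side == "left":
        kappa = {"AV": row["kappa_av"], "MV": row["kappa_mv"]}
        dur = {"AV": row["dur_av"], "MV": row["dur_mv"]}
        p = HeartModelParams("left", row["r_wk_ao"], row["p_la"], kappa, dur, ctx)
    else:
        kappa = {"PV": BASELINES["kappa"], "TV": BASELINES["kappa"]}
        dur = {"PV": row["dur_pv"], "TV": row["dur_tv"]}
        p = HeartModelParams("right", row["r_wk_pa"], row["p_ra"], kappa, dur, ctx)
    return p, dur


def baseline_params(side: str, ctx: SideContext) -> HeartModelParams:
    if side == "left":
        return HeartModelParams(
            "left",
            BASELINES["r_wk_ao"],
            BASELINES["p_la"],
            {"AV": BASELINES["kappa"], "MV": BASELINES["kappa"]},
            {"AV": BASELINES["dur"], "MV": BASELINES["dur"]},
            ctx,
        )
    return HeartModelParams(
        "right",
        BASELINES["r_wk_pa"],
        BASELINES["p_ra"],
        {"PV": BASELINES["kappa"], "TV": BASELINES["kappa"]},
        {"PV": BASELINES["dur"], "TV": BASELINES["dur"]},
        ctx,
    )


def side_context(cfg: RunConfig, rec: PatientRecord, side: str) -> SideContext:
    """Fixed circuit context for one side, from the clinical estimates."""
    from .clinical import cardiac_output

    co = rec.co if rec.co is not None else cardiac_output(rec)
    if side == "left":
        wk = estimate_systemic_windkessel(rec.p_sys_cuff, rec.p_dia_cuff, rec.hr, co)
    else:
        rv_co = cfg.rv_co if cfg.rv_co is not None else co
        wk = estimate_pulmonary_windkessel(rv_co, hr=rec.hr)
    return SideContext(windkessel=wk)


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute every stage for each requested side and write all artifacts."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec = _resolve_record(cfg)
    manifest = RunManifest(config_digest=cfg.digest(), version=__version__)

    vt = generate_volume_transients(rec, cfg.shape, seed=cfg.seed_design)
    vt.to_csv(outdir / "transients.csv")
    fs = derive_fluxes(vt)
    fs.to_csv(outdir / "fluxes.csv")
    timings = detect_valve_events(fs, dur_ms=BASELINES["dur"])
    timings.to_json(outdir / "timings.json")

    for side in cfg.sides:
        manifest.sides[side] = _run_side(cfg, rec, vt, timings, side, outdir)
    manifest.to_json(outdir / "manifest.json")
    return manifest


def _run_side(
    cfg: RunConfig,
    rec: PatientRecord,
    vt,
    timings: ValveTimings,
    side: str,
    outdir: Path,
) -> dict:
    ctx = side_context(cfg, rec, side)
    space = side_parameter_space(side)
    registry = default_registry(side, window=cfg.gradient_window)
    info: dict = {"n_train": cfg.n_train, "parameters": space.names}

    design = latin_hypercube(space, cfg.n_train, seed=cfg.seed_design)
    design.to_csv(outdir / f"design_{side}.csv", sidecar=outdir / f"design_{side}.json")

    features_path = outdir / f"features_{side}.csv"
    if cfg.resume and features_path.exists():
        log.info("resume: reusing %s", features_path)
        fdf = pd.read_csv(features_path)
    else:
        vectors: list[FeatureVector] = []
        for i, row in design.values.iterrows():
            params, _ = _sample_to_params(side, row.to_dict(), ctx)
            trace = simulate(params, vt, timings, n_beats=cfg.n_beats, dt_ms=cfg.dt_ms)
            vectors.append(
                extract_features(trace, timings, registry, cfg.feature_cfg, run_id=f"{side}-{i:03d}")
            )
        fdf = features_to_csv(vectors, features_path)
    n_converged = int(fdf["valid"].sum())
    info["converged"] = n_converged
    info["discarded"] = cfg.n_train - n_converged

    x_all = design.values.to_numpy()
    models: dict[str, TrainedGPE] = {}
    cv_rows = []
    for name in registry:
        y = fdf[name].to_numpy()
        mask = fdf["valid"].to_numpy() & np.isfinite(y)
        try:
            model = fit_gpe(
                x_all[mask],
                y[mask],
                cfg.gpe,
                space=space,
                k_folds=cfg.k_folds,
                feature_name=name,
            )
            models[name] = model
            save_gpe(model, outdir / f"gpe_{side}_{name}.json")
            cv_rows.append({"feature": name, "cv_mean_r2": model.cv_mean, "error": ""})
        except ValueError as exc:
            log.warning("feature %s not emulated: %s", name, exc)
            cv_rows.append({"feature": name, "cv_mean_r2": float("nan"), "error": str(exc)})
    cv_df = pd.DataFrame(cv_rows)
    cv_df.to_csv(outdir / f"cv_scores_{side}.csv", index=False)

    kept, excluded = screen_emulators(models, threshold=cfg.r2_threshold)
    not_fitted = [r["feature"] for r in cv_rows if r["error"]]
    info["kept"] = kept
    info["excluded"] = excluded + not_fitted

    results: dict[str, SobolResult] = {}
    for name in kept:
        res = gsa_with_emulator(
            models[name], space, n=cfg.n_saltelli, n_draws=cfg.n_draws, seed=cfg.seed_gsa, feature=name
        )
        screen_indices(res, threshold=cfg.negligible_threshold)
        res.to_csv(outdir / f"sobol_{side}_{name}.csv")
        results[name] = res

    excluded_scores = {n: (models[n].cv_mean if n in models else float("nan")) for n in info["excluded"]}
    if results or excluded_scores:
        s1_df, st_df = heatmap_table(results, excluded_scores)
        s1_df.to_csv(outdir / f"heatmap_s1_{side}.csv")
        st_df.to_csv(outdir / f"heatmap_st_{side}.csv")
    info["sobol_files"] = sorted(f"sobol_{side}_{n}.csv" for n in results)
    return info


def validate_against_clinical(
    sim_features: FeatureVector | dict[str, float], clin: ClinicalMeasurements
) -> pd.DataFrame:
    """Relative-error comparison of simulated features against the clinical
    measurement table (delegates to the clinical module)."""
    return relative_error_report(sim_features, clin)
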