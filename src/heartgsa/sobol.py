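"""Variance-based sensitivity indices on pick-freeze designs.

Given model evaluations on the Saltelli matrices A, B and AB_i, the
first-order and total-effect indices of parameter i are estimated as

    S1_i = mean( f(B) · (f(AB_i) − f(A)) ) / V̂          (Saltelli 2010)
    ST_i = mean( (f(A) − f(AB_i))² ) / (2·V̂)            (Jansen 1999)

with V̂ the empirical variance of the concatenated (f(A), f(B)) sample.
S1_i is the fraction of output variance explained by parameter i alone; ST_i
adds all of its interactions.  When the emulator rather than the simulator is
evaluated, index uncertainty is propagated by recomputing the indices for
each joint posterior draw.

Small negative estimates are sampling noise; they are reported raw and only
clipped to zero in heatmap display.  Near-constant outputs make the
normalization degenerate: those results carry a flag and zero indices rather
than raising.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ParameterSpace, saltelli_matrices, split_saltelli, stack_saltelli
from .emulator import TrainedGPE, predict, sample_posterior

log = logging.getLogger(__name__)

# An output whose spread across the whole parameter space is below this
# fraction of its magnitude is treated as constant: its variance sits at the
# level of solver/emulator noise and apportioning it is meaningless.
DEGENERATE_COV = 1e-3


@dataclass
class SobolResult:
    """Index estimates for one output feature across all parameters."""

    feature: str
    parameters: list[str]
    s1: np.ndarray  # point estimates (predictive-mean path)
    st: np.ndarray
    s1_draws: np.ndarray | None = None  # (n_draws, D)
    st_draws: np.ndarray | None = None
    n: int = 0
    seed: int = 0
    n_draws: int = 0
    degenerate: bool = False
    negligible: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.degenerate:
            if not np.all(np.isfinite(self.s1)) or not np.all(np.isfinite(self.st)):
                raise ValueError("index estimates must be finite")

    @property
    def s1_point(self) -> np.ndarray:
        """Headline S1: across-draw mean when draws exist, else the
        predictive-mean-path estimate."""
        return self.s1_draws.mean(axis=0) if self.s1_draws is not None else self.s1

    @property
    def st_point(self) -> np.ndarray:
        return self.st_draws.mean(axis=0) if self.st_draws is not None else self.st

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"parameter": self.parameters, "s1": self.s1, "st": self.st}
        )
        if self.s1_draws is not None:
            df["s1_draw_mean"] = self.s1_draws.mean(axis=0)
            df["s1_lo"] = np.percentile(self.s1_draws, 2.5, axis=0)
            df["s1_hi"] = np.percentile(self.s1_draws, 97.5, axis=0)
            df["st_draw_mean"] = self.st_draws.mean(axis=0)
            df["st_lo"] = np.percentile(self.st_draws, 2.5, axis=0)
            df["st_hi"] = np.percentile(self.st_draws, 97.5, axis=0)
        if self.negligible is not None:
            df["negligible"] = self.negligible
        df["degenerate"] = self.degenerate
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature": self.feature,
            "n": self.n,
            "seed": self.seed,
            "n_draws": self.n_draws,
            "degenerate": self.degenerate,
            "rows": self.to_frame().to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def sobol_from_evaluations(
    fa: np.ndarray, fb: np.ndarray, fab: np.ndarray
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Estimate (S1, ST) per parameter from pick-freeze evaluations.

    ``fab`` has shape (D, n).  Returns (s1, st, degenerate); a near-constant
    output yields zero indices with the degenerate flag set.
    """
    fa = np.asarray(fa, dtype=float).ravel()
    fb = np.asarray(fb, dtype=float).ravel()
    fab = np.atleast_2d(np.asarray(fab, dtype=float))
    n = fa.size
    if fb.size != n or fab.shape[1] != n:
        raise ValueError("evaluation vectors must have equal length")
    if n < 2:
        raise ValueError("need at least 2 evaluations")
    if not (np.all(np.isfinite(fa)) and np.all(np.isfinite(fb)) and np.all(np.isfinite(fab))):
        raise ValueError("evaluations must be finite")
    both = np.concatenate([fa, fb])
    v = float(np.var(both))
    scale = abs(float(np.mean(both))) + 1e-12
    if np.sqrt(v) <= DEGENERATE_COV * scale:
        d = fab.shape[0]
        return np.zeros(d), np.zeros(d), True
    s1 = np.mean(fb[None, :] * (fab - fa[None, :]), axis=1) / v
    st = np.mean((fa[None, :] - fab) ** 2, axis=1) / (2.0 * v)
    return s1, st, False


def gsa_with_emulator(
    model: TrainedGPE,
    space: ParameterSpace,
    n: int = 10000,
    n_draws: int = 20,
    seed: int = 0,
    feature: str | None = None,
) -> SobolResult:
    """Sensitivity indices of one emulated feature over the parameter space.

    The pick-freeze matrices are built once; the predictive-mean path gives
    the point estimates, and joint posterior draws over all n·(D+2) points
    give across-draw means and 2.5/97.5 percentiles.
    """
    a, b, ab = saltelli_matrices(space, n, seed)
    x_all = stack_saltelli(a, b, ab)
    d = space.dim

    mu, _ = predict(model, x_all)
    fa, fb, fab = split_saltelli(mu, n, d)
    s1, st, degenerate = sobol_from_evaluations(fa, fb, fab)

    s1_draws = st_draws = None
    if n_draws >= 1:
        draws = sample_posterior(model, x_all, n_draws, seed=seed + 1)
        s1_list, st_list = [], []
        for j in range(n_draws):
            fa_j, fb_j, fab_j = split_saltelli(draws[j], n, d)
            s1_j, st_j, deg_j = sobol_from_evaluations(fa_j, fb_j, fab_j)
            degenerate = degenerate or deg_j
            s1_list.append(s1_j)
            st_list.append(st_j)
        s1_draws = np.vstack(s1_list)
        st_draws = np.vstack(st_list)

    return SobolResult(
        feature=feature or model.feature_name or "feature",
        parameters=space.names,
        s1=s1,
        st=st,
        s1_draws=s1_draws,
        st_draws=st_draws,
        n=n,
        seed=seed,
        n_draws=n_draws,
        degenerate=degenerate,
    )


def screen_indices(result: SobolResult, threshold: float = 0.01) -> SobolResult:
    """Annotate parameters whose S1 and ST point estimates both fall below the
    negligibility threshold."""
    result.negligible = (result.s1_point < threshold) & (result.st_point < threshold)
    return result


def heatmap_table(
    results: dict[str, SobolResult],
    excluded: dict[str, float] | None = None,
    clip_negative: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Feature × parameter matrices of S1 and ST point estimates.

    Excluded features appear as rows of missing values carrying their CV R²
    in a trailing column.  Display values are clipped at zero (raw estimates
    stay in the per-feature result files).
    """
    if not results and not excluded:
        raise ValueError("need at least one result")
    params: list[str] = []
    for r in results.values():
        params = r.parameters
        break
    rows_s1, rows_st, index = [], [], []
    cv_col = []
    for name, r in results.items():
        s1, st = r.s1_point.copy(), r.st_point.copy()
        if clip_negative:
            s1, st = np.clip(s1, 0.0, None), np.clip(st, 0.0, None)
        rows_s1.append(s1)
        rows_st.append(st)
        index.append(name)
        cv_col.append(np.nan)
    for name, r2 in (excluded or {}).items():
        rows_s1.append(np.full(len(params), np.nan))
        rows_st.append(np.full(len(params), np.nan))
        index.append(name)
        cv_col.append(r2)
    s1_df = pd.DataFrame(rows_s1, index=index, columns=params)
    st_df = pd.DataFrame(rows_st, index=index, columns=params)
    s1_df["cv_r2_if_excluded"] = cv_col
    st_df["cv_r2_if_excluded"] = cv_col
    return s1_df, st_df
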