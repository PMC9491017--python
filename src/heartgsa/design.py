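"""Parameter spaces and sampling designs for emulator training and GSA.

The study perturbs each scalar parameter ±25% around its baseline; the
permeability-like valve parameters span four decades and are sampled
log-uniformly over an explicit range.  Training designs are Latin hypercube
samples of size ≈10·D; sensitivity indices use the pick-freeze construction:
two independent base matrices A and B plus the hybrid matrices AB_i (A with
column i taken from B), n·(D+2) model evaluations in total.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc


@dataclass(frozen=True)
class Parameter:
    name: str
    lower: float
    upper: float
    scale: str = "linear"  # linear | log10
    baseline: float | None = None

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: require lower < upper")
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"{self.name}: unknown scale '{self.scale}'")
        if self.scale == "log10" and self.lower <= 0:
            raise ValueError(f"{self.name}: log-scale parameters must be positive")


@dataclass(frozen=True)
class ParameterSpace:
    parameters: tuple[Parameter, ...]

    def __post_init__(self) -> None:
        if len(self.parameters) < 1:
            raise ValueError("need at least one parameter")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    @property
    def dim(self) -> int:
        return len(self.parameters)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        """Native units -> [0,1]^D (log10-transformed first for log params)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        u = np.empty_like(x)
        for j, p in enumerate(self.parameters):
            if p.scale == "log10":
                lo, hi = np.log10(p.lower), np.log10(p.upper)
                u[:, j] = (np.log10(x[:, j]) - lo) / (hi - lo)
            else:
                u[:, j] = (x[:, j] - p.lower) / (p.upper - p.lower)
        return u

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_2d(np.asarray(u, dtype=float))
        x = np.empty_like(u)
        for j, p in enumerate(self.parameters):
            if p.scale == "log10":
                lo, hi = np.log10(p.lower), np.log10(p.upper)
                x[:, j] = 10.0 ** (lo + u[:, j] * (hi - lo))
            else:
                x[:, j] = p.lower + u[:, j] * (p.upper - p.lower)
        return x

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        ok = np.ones(x.shape[0], dtype=bool)
        for j, p in enumerate(self.parameters):
            ok &= (x[:, j] >= p.lower) & (x[:, j] <= p.upper)
        return ok

    def to_dict(self) -> dict:
        return {
            "parameters": [
                {
                    "name": p.name,
                    "lower": p.lower,
                    "upper": p.upper,
                    "scale": p.scale,
                    "baseline": p.baseline,
                }
                for p in self.parameters
            ]
        }


def space_from_baselines(
    baselines: dict[str, float],
    pct: float = 0.25,
    log_params: dict[str, tuple[float, float]] | None = None,
) -> ParameterSpace:
    """Build a space from baseline values: linear parameters get the interval
    [b·(1−pct), b·(1+pct)]; log-scale parameters get their explicit range
    (a multiplicative perturbation cannot span their decades)."""
    if not 0.0 < pct < 1.0:
        raise ValueError("pct must lie in (0, 1)")
    log_params = log_params or {}
    params = []
    for name, b in baselines.items():
        if name in log_params:
            lo, hi = log_params[name]
            params.append(Parameter(name, lo, hi, scale="log10", baseline=b))
        else:
            params.append(Parameter(name, b * (1.0 - pct), b * (1.0 + pct), baseline=b))
    return ParameterSpace(tuple(params))


@dataclass
class DesignMatrix:
    """Sampled parameter values in native units plus provenance."""

    values: pd.DataFrame  # columns = parameter names
    kind: str  # lhs | saltelli-A | saltelli-B | saltelli-AB<i>
    seed: int
    space: ParameterSpace

    @property
    def n(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.values.to_csv(path, index=False)
        if sidecar is not None:
            Path(sidecar).write_text(
                json.dumps(
                    {"kind": self.kind, "seed": self.seed, "space": self.space.to_dict()},
                    indent=2,
                )
            )


def latin_hypercube(space: ParameterSpace, n: int, seed: int) -> DesignMatrix:
    """Seeded Latin hypercube design: one sample per equal-probability bin and
    dimension, in transformed scale for log parameters."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=space.dim, seed=seed)
    u = sampler.random(n)
    x = space.from_unit(u)
    return DesignMatrix(
        values=pd.DataFrame(x, columns=space.names), kind="lhs", seed=seed, space=space
    )


def saltelli_matrices(
    space: ParameterSpace, n: int, seed: int, base: str = "sobol"
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Pick-freeze design (A, B, AB_1..AB_D) in native units.

    Base points come from a seeded scrambled Sobol' sequence in 2D dimensions
    split into A and B (``base='random'`` falls back to plain uniform draws
    for reproducibility comparisons).  AB_i equals A with column i replaced
    from B.  Total model evaluations: n·(D+2).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    d = space.dim
    if base == "sobol":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # n need not be a power of 2
            u = qmc.Sobol(d=2 * d, scramble=True, seed=seed).random(n)
    elif base == "random":
        u = np.random.default_rng(seed).random((n, 2 * d))
    else:
        raise ValueError("base must be 'sobol' or 'random'")
    a = space.from_unit(u[:, :d])
    b = space.from_unit(u[:, d:])
    ab = []
    for i in range(d):
        m = a.copy()
        m[:, i] = b[:, i]
        ab.append(m)
    return a, b, ab


def stack_saltelli(a: np.ndarray, b: np.ndarray, ab: list[np.ndarray]) -> np.ndarray:
    """All n·(D+2) evaluation rows as one matrix, ordered A, B, AB_1..AB_D."""
    return np.vstack([a, b, *ab])


def split_saltelli(
    f: np.ndarray, n: int, d: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of :func:`stack_saltelli` for a vector of model evaluations:
    returns (fA, fB, fAB) with fAB of shape (D, n)."""
    if f.shape[-1] != n * (d + 2):
        raise ValueError(f"expected {n*(d+2)} evaluations, got {f.shape[-1]}")
    fa = f[..., :n]
    fb = f[..., n : 2 * n]
    fab = np.stack([f[..., (2 + i) * n : (3 + i) * n] for i in range(d)], axis=-2)
    return fa, fb, fab
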