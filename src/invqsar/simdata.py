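"""Simulation benchmark for inverse-QSAR coordinate optimization.

The benchmark replaces compound data with a known two-dimensional ground
truth: Mishra's bird function, a multimodal test surface.  Training and
test points are sampled uniformly over a rectangle, observed responses add
Gaussian noise, and a dense lattice scan (`grid_search_oracle`) provides an
independent, brute-force optimum for validating the evolutionary optimizer.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd


class NoFeasiblePointError(RuntimeError):
    """Raised when every lattice point is excluded by the feasibility filter."""


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Sampling settings for one simulation trial.

    ``noise_variance`` is a variance (not a standard deviation).
    """

    n_train: int = 50
    n_test: int = 20
    x1_range: tuple[float, float] = (-2.0, 3.0)
    x2_range: tuple[float, float] = (-1.0, 4.0)
    noise_mean: float = 0.0
    noise_variance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train <= 0:
            raise ValueError("n_train must be positive")
        if self.n_test < 0:
            raise ValueError("n_test must be non-negative")
        for lo, hi in (self.x1_range, self.x2_range):
            if not lo < hi:
                raise ValueError(f"degenerate range [{lo}, {hi}]")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")


@dataclasses.dataclass
class LabeledPoints:
    """A set of 2-D inputs with noisy and noise-free responses."""

    X: np.ndarray
    y_observed: np.ndarray
    y_true: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y_observed = np.asarray(self.y_observed, dtype=float)
        self.y_true = np.asarray(self.y_true, dtype=float)
        n = self.X.shape[0]
        if not (self.y_observed.shape == (n,) and self.y_true.shape == (n,)):
            raise ValueError("X, y_observed and y_true must have equal row counts")

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x1": self.X[:, 0],
                "x2": self.X[:, 1],
                "y_observed": self.y_observed,
                "y_true": self.y_true,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LabeledPoints":
        return cls(
            X=frame[["x1", "x2"]].to_numpy(),
            y_observed=frame["y_observed"].to_numpy(),
            y_true=frame["y_true"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path) -> "LabeledPoints":
        return cls.from_frame(pd.read_csv(path))


def bird_function(x1, x2):
    """Mishra's bird function.

    f(x1, x2) = sin(x1) e^{(1-cos x2)^2} + cos(x2) e^{(1-sin x1)^2} + (x1-x2)^2

    Accepts scalars or broadcastable arrays; raises on non-finite input.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("bird_function requires finite inputs")
    out = (
        np.sin(x1) * np.exp((1.0 - np.cos(x2)) ** 2)
        + np.cos(x2) * np.exp((1.0 - np.sin(x1)) ** 2)
        + (x1 - x2) ** 2
    )
    if out.ndim == 0:
        return float(out)
    return out


def generate_simulation_data(
    config: SimulationConfig,
) -> tuple[LabeledPoints, LabeledPoints]:
    """Sample one training/test trial of the bird-function benchmark.

    Inputs are uniform over the configured rectangle; observed responses add
    N(noise_mean, noise_variance) errors.  Fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([config.x1_range[0], config.x2_range[0]])
    hi = np.array([config.x1_range[1], config.x2_range[1]])
    sd = float(np.sqrt(config.noise_variance))

    def sample(n: int) -> LabeledPoints:
        X = rng.uniform(lo, hi, size=(n, 2))
        y_true = bird_function(X[:, 0], X[:, 1])
        noise = rng.normal(config.noise_mean, sd, size=n)
        return LabeledPoints(X=X, y_observed=np.asarray(y_true) + noise, y_true=y_true)

    return sample(config.n_train), sample(config.n_test)


def _lattice_axis(lo: float, hi: float, resolution: float) -> np.ndarray:
    # Largest k with lo + k*resolution <= hi; tolerate FP representation of
    # spans that are exact multiples of the resolution.
    k = int(np.floor((hi - lo) / resolution + 1e-9))
    return lo + resolution * np.arange(k + 1)


def _evaluate_batch(fn: Callable, X: np.ndarray) -> np.ndarray:
    """Call fn on an (n, d) batch, falling back to a row loop for scalar fns."""
    try:
        out = np.asarray(fn(X), dtype=float)
        if out.shape == (X.shape[0],):
            return out
    except Exception:
        pass
    return np.array([float(fn(row)) for row in X])


def grid_search_oracle(
    fn: Callable,
    bounds: Sequence[tuple[float, float]],
    resolution: float,
    ad_filter: Optional[Callable] = None,
    chunk_size: int = 1 << 18,
) -> tuple[np.ndarray, float]:
    """Brute-force lattice maximization of ``fn`` over a box.

    The lattice starts at each lower bound with the given spacing; the last
    point per axis is the largest ``lo + k*resolution <= hi``.  ``fn`` (and
    ``ad_filter``, if given) may accept either an (n, d) batch or a single
    d-vector.  Ties are broken by the first point in row-major scan order.

    Returns ``(argmax, max_value)``; raises :class:`NoFeasiblePointError` if
    the filter rejects every lattice point.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    axes = []
    for lo, hi in bounds:
        if not lo < hi:
            raise ValueError(f"degenerate bounds [{lo}, {hi}]")
        axes.append(_lattice_axis(lo, hi, resolution))
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)

    best_val = -np.inf
    best_idx = -1
    for start in range(0, points.shape[0], chunk_size):
        chunk = points[start : start + chunk_size]
        vals = _evaluate_batch(fn, chunk)
        if ad_filter is not None:
            ok = np.asarray(_evaluate_batch(ad_filter, chunk), dtype=bool)
            if not ok.any():
                continue
            vals = np.where(ok, vals, -np.inf)
        i = int(np.argmax(vals))
        if vals[i] > best_val:
            best_val = float(vals[i])
            best_idx = start + i
    if best_idx < 0 or not np.isfinite(best_val):
        raise NoFeasiblePointError("no feasible point on the lattice")
    return points[best_idx].copy(), best_val
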