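"""Run configuration: schema-validated YAML settings and seed fan-out.

A single top-level seed is split into independent per-subsystem seeds
(data generation, cross-validation, optimizer) through
``numpy.random.SeedSequence`` so each stage is reproducible in isolation.
Unknown configuration keys are rejected.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field


def child_seed(seed: int, stream: int) -> int:
    """Deterministic per-subsystem seed derived from the run seed.

    Streams: 0 data, 1 cross-validation, 2 optimizer, 3 analysis.  The
    result is a non-negative 31-bit integer.
    """
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


class _Settings(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulationSettings(_Settings):
    n_train: int = 50
    n_test: int = 20
    x1_range: tuple[float, float] = (-2.0, 3.0)
    x2_range: tuple[float, float] = (-1.0, 4.0)
    noise_mean: float = 0.0
    noise_variance: float = 1.0
    trials: int = 3


class FixtureSettings(_Settings):
    n: int = 600
    d: int = 15
    noise_sigma: float = 0.3


class CVSettings(_Settings):
    n_folds: Optional[int] = None  # default depends on the task (10 or 5)
    c_grid: Optional[Sequence[float]] = None
    nu_grid: Optional[Sequence[float]] = None
    gamma_grid: Optional[Sequence[float]] = None

    def to_cv_config(self, seed: int, default_folds: int = 10):
        from .models import DEFAULT_SVR_GRID, CVConfig

        grid = {k: list(v) for k, v in DEFAULT_SVR_GRID.items()}
        if self.c_grid is not None:
            grid["C"] = list(self.c_grid)
        if self.nu_grid is not None:
            grid["nu"] = list(self.nu_grid)
        if self.gamma_grid is not None:
            grid["gamma"] = list(self.gamma_grid)
        return CVConfig(
            n_folds=self.n_folds if self.n_folds is not None else default_folds,
            grid=grid,
            seed=seed,
        )


class DESettings(_Settings):
    F: float = 0.5
    CR: float = 0.9
    p: float = 1.0
    Tc: int = 1
    cp: float = 5.0
    theta: float = 0.2
    n_generations: Optional[int] = None  # default depends on the task

    def to_de_params(self, seed: int, default_generations: int):
        from .optimize import DEParams

        return DEParams(
            F=self.F,
            CR=self.CR,
            p=self.p,
            Tc=self.Tc,
            cp=self.cp,
            theta=self.theta,
            n_generations=(
                self.n_generations if self.n_generations is not None else default_generations
            ),
            seed=seed,
        )


class AnalysisSettings(_Settings):
    top_n: int = 30
    top_k: int = 30
    min_delta: float = 1.0
    active_pki_threshold: float = 8.0


class RunConfig(_Settings):
    """Top-level run configuration (YAML-serializable)."""

    task: Literal["simulation", "fixture", "compounds"] = "simulation"
    seed: int = 0
    output_dir: str = "out"
    activity_csv: Optional[str] = None
    ad_nu: float = 0.01
    simulation: SimulationSettings = Field(default_factory=SimulationSettings)
    fixture: FixtureSettings = Field(default_factory=FixtureSettings)
    cv: CVSettings = Field(default_factory=CVSettings)
    de: DESettings = Field(default_factory=DESettings)
    analysis: AnalysisSettings = Field(default_factory=AnalysisSettings)

    @property
    def default_generations(self) -> int:
        # 1,000 generations for the 2-D simulation benchmark, 10,000 for
        # descriptor-space compound runs.
        return 1000 if self.task == "simulation" else 10000

    @property
    def default_cv_folds(self) -> int:
        return 10 if self.task == "simulation" else 5


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
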