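"""Scenario and experiment configuration.

A :class:`ScenarioConfig` holds every parameter of the data-generating
process for one simulation cell: the sample size, the number of levels of
the grouping factor, the fixed-effect coefficients, and the three variance
components (between-group, residual, and predictor variance).

An :class:`ExperimentPlan` holds the full Monte Carlo design: the grid of
scenario cells, the number of replicates per cell, the master seed, the
confidence-interval policy for each model class, and the singularity
tolerance.  Plans can be read from a flat YAML config file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml

__all__ = ["ScenarioConfig", "ExperimentPlan", "DEFAULT_GRID_N_OBS", "DEFAULT_GRID_N_LEVELS"]

#: Sample sizes of the default scenario grid.
DEFAULT_GRID_N_OBS = (30, 60, 120)
#: Grouping-factor level counts of the default scenario grid.
DEFAULT_GRID_N_LEVELS = (3, 5, 10)


@dataclass(frozen=True)
class ScenarioConfig:
    """Data-generating parameters for one simulation cell.

    The generative model is

        y_i = beta0 + u_{g(i)} + beta1 * x1_i + beta2 * x2_i + eps_i

    with group effects u_j ~ N(0, sigma2_site), noise eps_i ~ N(0,
    sigma2_resid), and predictors x1, x2 ~ N(0, var_x), allocated to groups
    in an unbalanced design (every level observed at least once, perfectly
    balanced allocations rejected).

    Parameters
    ----------
    n_obs : int
        Total number of observations. Must exceed ``n_levels``.
    n_levels : int
        Number of levels of the grouping factor (e.g. field sites).
    beta0 : float
        Overall intercept (grand mean across groups).
    beta1, beta2 : float
        Slopes of the two predictors; defaults give one strong (2) and one
        weak (0.2) relationship.
    sigma2_site : float
        Variance of the group-level intercept deviations.
    sigma2_resid : float
        Residual (observation-level) variance.
    var_x : float
        Variance of each predictor.
    """

    n_obs: int
    n_levels: int
    beta0: float = 73.0
    beta1: float = 2.0
    beta2: float = 0.2
    sigma2_site: float = 1.0
    sigma2_resid: float = 1.0
    var_x: float = 0.5

    def __post_init__(self) -> None:
        if self.n_obs <= 0 or self.n_levels <= 0:
            raise ValueError("n_obs and n_levels must be positive integers")
        if self.n_obs <= self.n_levels:
            # with n_obs == n_levels the only allocation is the balanced one
            # and rejection sampling could never terminate
            raise ValueError(
                f"n_obs ({self.n_obs}) must exceed n_levels ({self.n_levels}); "
                "otherwise no unbalanced allocation exists"
            )
        for name in ("sigma2_site", "sigma2_resid", "var_x"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def truths(self) -> dict[str, float]:
        """True generating values keyed by parameter name."""
        return {
            "intercept": self.beta0,
            "beta1": self.beta1,
            "beta2": self.beta2,
            "sigma2_site": self.sigma2_site,
        }


@dataclass
class ExperimentPlan:
    """Full Monte Carlo design: scenario grid, replication, seed, policies."""

    n_obs_grid: Sequence[int] = DEFAULT_GRID_N_OBS
    n_levels_grid: Sequence[int] = DEFAULT_GRID_N_LEVELS
    n_reps: int = 10_000
    seed: int = 0
    alpha: float = 0.05
    lm_interval: str = "t"
    lmm_interval: str = "z"
    singular_tol: float = 1e-4
    scenario_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lm_interval not in ("t", "z") or self.lmm_interval not in ("t", "z"):
            raise ValueError("interval policies must be 't' or 'z'")
        if self.singular_tol <= 0:
            raise ValueError("singular_tol must be positive")
        # fail fast on invalid grid cells
        for cfg in self.scenarios():
            del cfg

    def scenarios(self) -> list[ScenarioConfig]:
        """The grid of scenario cells, n_obs varying fastest."""
        return [
            ScenarioConfig(n_obs=n, n_levels=g, **self.scenario_kwargs)
            for g in self.n_levels_grid
            for n in self.n_obs_grid
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_obs_grid"] = list(self.n_obs_grid)
        d["n_levels_grid"] = list(self.n_levels_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentPlan":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentPlan":
        """Load a plan from a flat key-value YAML file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a key-value mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
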