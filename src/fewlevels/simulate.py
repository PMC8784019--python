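"""Synthetic data generation for the unbalanced grouped Gaussian design.

Datasets mimic a blocked ecological study: observations are nested in a
small number of groups (sites, individuals, populations), each group shifts
the intercept by a Gaussian deviation, and two Gaussian predictors act with
a strong and a weak slope.  Allocations are deliberately unbalanced: after
guaranteeing one observation per level, the remaining observations are
assigned uniformly at random, and any allocation that lands perfectly
balanced is discarded and redrawn (balanced designs decouple the
fixed-effect estimators from the random effects and are excluded by
design).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ScenarioConfig

__all__ = ["SimDataset", "allocate_groups", "gen_dataset", "child_rng"]


@dataclass(frozen=True)
class SimDataset:
    """One simulated dataset plus the true generating values used to score fits.

    Attributes
    ----------
    y : ndarray, shape (n_obs,)
        Response.
    x1, x2 : ndarray, shape (n_obs,)
        Predictors (strong and weak slope, respectively).
    group : ndarray of int, shape (n_obs,)
        Group labels in ``1..n_levels``. Label order carries no meaning.
    true_site_effects : ndarray, shape (n_levels,)
        The drawn group-intercept deviations, indexed by label - 1.
    config : ScenarioConfig
        The generating parameters, kept for downstream scoring.
    """

    y: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    group: np.ndarray
    true_site_effects: np.ndarray
    config: ScenarioConfig

    def __post_init__(self) -> None:
        n, g = self.config.n_obs, self.config.n_levels
        for name in ("y", "x1", "x2", "group"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have length n_obs={n}")
        if len(self.true_site_effects) != g:
            raise ValueError(f"true_site_effects must have length n_levels={g}")
        counts = np.bincount(self.group, minlength=g + 1)[1:]
        if counts.min() < 1:
            raise ValueError("every level in 1..n_levels must appear at least once")
        if counts.min() == counts.max():
            raise ValueError("group allocation must be unbalanced")

    @property
    def n_obs(self) -> int:
        return self.config.n_obs

    @property
    def n_levels(self) -> int:
        return self.config.n_levels

    @property
    def group_counts(self) -> np.ndarray:
        """Observation count per level, indexed by label - 1."""
        return np.bincount(self.group, minlength=self.n_levels + 1)[1:]

    def to_frame(self) -> pd.DataFrame:
        """Tidy view: columns y, x1, x2, group."""
        return pd.DataFrame(
            {"y": self.y, "x1": self.x1, "x2": self.x2, "group": self.group}
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the dataset as UTF-8 CSV with a header row."""
        self.to_frame().to_csv(path, index=False)

    def checksum(self) -> str:
        """Short content hash identifying the dataset (pairing diagnostics)."""
        import hashlib

        h = hashlib.blake2b(digest_size=8)
        for arr in (self.y, self.x1, self.x2, self.group.astype(np.int64)):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


def allocate_groups(n_obs: int, n_levels: int, rng: np.random.Generator) -> np.ndarray:
    """Draw an unbalanced group allocation.

    One observation is placed in each level; the remaining
    ``n_obs - n_levels`` observations pick a level uniformly at random with
    replacement.  If the resulting counts happen to be perfectly balanced,
    the whole allocation is discarded and redrawn.

    Returns integer labels in ``1..n_levels`` of length ``n_obs``.
    """
    if n_obs <= n_levels:
        raise ValueError(
            f"n_obs ({n_obs}) must exceed n_levels ({n_levels}): rejection of "
            "balanced allocations cannot terminate otherwise"
        )
    base = np.arange(1, n_levels + 1)
    can_balance = n_obs % n_levels == 0
    while True:
        extra = rng.integers(1, n_levels + 1, size=n_obs - n_levels)
        labels = np.concatenate([base, extra])
        if not can_balance:
            return labels  # balance impossible by pigeonhole: single attempt
        counts = np.bincount(labels, minlength=n_levels + 1)[1:]
        if counts.min() != counts.max():
            return labels


def gen_dataset(config: ScenarioConfig, rng: np.random.Generator) -> SimDataset:
    """Generate one dataset from the scenario's data-generating process.

    Draw order is fixed (allocation, site effects, x1, x2, noise) so a given
    seed reproduces the dataset bitwise.
    """
    c = config
    group = allocate_groups(c.n_obs, c.n_levels, rng)
    site = rng.normal(0.0, np.sqrt(c.sigma2_site), size=c.n_levels)
    sd_x = np.sqrt(c.var_x)
    x1 = rng.normal(0.0, sd_x, size=c.n_obs)
    x2 = rng.normal(0.0, sd_x, size=c.n_obs)
    eps = rng.normal(0.0, np.sqrt(c.sigma2_resid), size=c.n_obs)
    y = c.beta0 + site[group - 1] + c.beta1 * x1 + c.beta2 * x2 + eps
    return SimDataset(y=y, x1=x1, x2=x2, group=group, true_site_effects=site, config=c)


def child_rng(master_seed: int, n_obs: int, n_levels: int, rep: int) -> np.random.Generator:
    """Independent random stream for one (scenario, replicate) pair.

    Streams are keyed by the scenario coordinates and replicate index via a
    ``SeedSequence`` spawn key, so any single replicate is reproducible in
    isolation and results do not depend on the execution order of cells.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(n_obs, n_levels, rep))
    return np.random.default_rng(ss)
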