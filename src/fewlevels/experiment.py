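"""Monte Carlo orchestration: the scenario grid, replicate loop, persistence.

Each replicate generates one dataset and fits *both* models to it (a paired
design: LM and LMM always see identical data, which the shared
``data_checksum`` column makes auditable).  Per-(scenario, replicate) random
streams are pre-assigned from the master seed, so results are identical
whatever order cells run in.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from time import perf_counter

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentPlan, ScenarioConfig
from .metrics import summarize
from .models import fit_lm, fit_lmm
from .simulate import child_rng, gen_dataset

__all__ = ["run_cell", "run_experiment", "ExperimentResult"]

logger = logging.getLogger("fewlevels")

RECORD_COLUMNS = [
    "n_obs",
    "n_levels",
    "rep",
    "model",
    "parameter",
    "estimate",
    "ci_low",
    "ci_high",
    "truth",
    "singular",
    "converged",
    "data_checksum",
]


def run_cell(
    config: ScenarioConfig,
    n_reps: int,
    seed: int,
    alpha: float = 0.05,
    lm_interval: str = "t",
    lmm_interval: str = "z",
    singular_tol: float = 1e-4,
) -> pd.DataFrame:
    """Run one scenario cell and return tidy replicate records.

    Emits, per replicate, six records: the two slopes from each model plus
    the LMM's overall intercept and random-intercept variance estimate.
    A replicate whose fit raises (rank deficiency is the only realistic
    cause under this generator, and it is vanishingly rare) is recorded
    with NaN estimates and ``converged=False`` rather than redrawn --
    redrawing would bias the Monte Carlo distribution.
    """
    c = config
    rows: list[tuple] = []
    n_failures = 0
    for rep in range(n_reps):
        rng = child_rng(seed, c.n_obs, c.n_levels, rep)
        ds = gen_dataset(c, rng)
        checksum = ds.checksum()

        def rec(model, parameter, est, lo, hi, truth, singular, converged):
            rows.append(
                (c.n_obs, c.n_levels, rep, model, parameter, est, lo, hi, truth, singular, converged, checksum)
            )

        try:
            lm = fit_lm(ds, alpha=alpha, interval=lm_interval)
            for e, truth in zip(lm.slopes, (c.beta1, c.beta2)):
                rec("LM", e.name, e.estimate, e.ci_low, e.ci_high, truth, False, True)
        except Exception as err:  # noqa: BLE001 - per-replicate isolation
            n_failures += 1
            logger.warning("LM fit failed (rep %d): %s", rep, err)
            for name, truth in (("beta1", c.beta1), ("beta2", c.beta2)):
                rec("LM", name, np.nan, np.nan, np.nan, truth, False, False)
        try:
            lmm = fit_lmm(ds, alpha=alpha, singular_tol=singular_tol, interval=lmm_interval)
            e = lmm.intercept
            rec("LMM", "intercept", e.estimate, e.ci_low, e.ci_high, c.beta0, lmm.singular, lmm.converged)
            for e, truth in zip(lmm.slopes, (c.beta1, c.beta2)):
                rec("LMM", e.name, e.estimate, e.ci_low, e.ci_high, truth, lmm.singular, lmm.converged)
            rec("LMM", "sigma2_site", lmm.sigma2_site_hat, np.nan, np.nan, c.sigma2_site, lmm.singular, lmm.converged)
        except Exception as err:  # noqa: BLE001
            n_failures += 1
            logger.warning("LMM fit failed (rep %d): %s", rep, err)
            for name, truth in (
                ("intercept", c.beta0),
                ("beta1", c.beta1),
                ("beta2", c.beta2),
                ("sigma2_site", c.sigma2_site),
            ):
                rec("LMM", name, np.nan, np.nan, np.nan, truth, False, False)
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if n_failures:
        logger.warning(
            "cell (n_obs=%d, n_levels=%d): %d fit failure(s)", c.n_obs, c.n_levels, n_failures
        )
    return df


@dataclass
class ExperimentResult:
    """Everything a full run produces, plus provenance metadata."""

    records: pd.DataFrame
    summary: pd.DataFrame
    summary_by_singularity: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write replicates.csv, summary.csv, summary_by_singularity.csv
        and metadata.json; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "replicates": out / "replicates.csv",
            "summary": out / "summary.csv",
            "summary_by_singularity": out / "summary_by_singularity.csv",
            "metadata": out / "metadata.json",
        }
        self.records.to_csv(paths["replicates"], index=False)
        self.summary.to_csv(paths["summary"], index=False)
        self.summary_by_singularity.to_csv(paths["summary_by_singularity"], index=False)
        with open(paths["metadata"], "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2)
        return paths


def run_experiment(plan: ExperimentPlan, out_dir: str | Path | None = None) -> ExperimentResult:
    """Run every cell of the plan and summarise.

    If ``out_dir`` is given its writability is checked before any
    computation starts, and the records, both summary tables, and a
    metadata sidecar are written there at the end.
    """
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        try:
            probe.write_text("")
        finally:
            probe.unlink(missing_ok=True)

    frames = []
    timings = {}
    for cfg in plan.scenarios():
        t0 = perf_counter()
        frames.append(
            run_cell(
                cfg,
                plan.n_reps,
                plan.seed,
                alpha=plan.alpha,
                lm_interval=plan.lm_interval,
                lmm_interval=plan.lmm_interval,
                singular_tol=plan.singular_tol,
            )
        )
        dt = perf_counter() - t0
        timings[f"n_obs={cfg.n_obs},n_levels={cfg.n_levels}"] = round(dt, 3)
        logger.info("cell n_obs=%d n_levels=%d: %.1fs", cfg.n_obs, cfg.n_levels, dt)
    records = pd.concat(frames, ignore_index=True)
    meta = {
        "tool": "fewlevels",
        "version": __version__,
        "plan": plan.to_dict(),
        "n_datasets": plan.n_reps * len(plan.scenarios()),
        "n_nonconverged_fits": int(
            records.loc[~records["converged"], ["n_obs", "n_levels", "rep", "model"]]
            .drop_duplicates()
            .shape[0]
        ),
        "cell_seconds": timings,
    }
    result = ExperimentResult(
        records=records,
        summary=summarize(records),
        summary_by_singularity=summarize(records, stratify_by_singular=True),
        metadata=meta,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
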