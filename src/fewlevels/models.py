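"""The two competing estimators: dummy-coded LM and random-intercept LMM.

Both are exposed statsmodels-style: a model object built from data whose
``fit()`` returns a results object carrying estimates, standard errors,
confidence intervals, variance components and diagnostics.  Thin
``fit_lm`` / ``fit_lmm`` wrappers accept a :class:`~fewlevels.simulate.SimDataset`
directly.

The LMM is a Gaussian random-intercept model

    y = X beta + Z u + eps,   u ~ N(0, sigma2_site I_g),  eps ~ N(0, sigma2_resid I_n)

estimated by REML.  The two variance components are profiled down to the
single ratio theta = sd(u) / sd(eps), giving marginal covariance
sigma2_resid * V(theta) with V = I + theta^2 Z Z'.  Up to an additive
constant the concentrated REML deviance (-2 restricted log-likelihood) is

    log|V| + log|X' V^-1 X| + (n - p) log(r' V^-1 r),

with r the GLS residual at theta.  Because Z indicates group membership,
V^-1 = I - Z D Z' with D = diag(theta^2 / (1 + theta^2 n_j)) (Woodbury),
so every criterion evaluation costs O(g p^2) after one pass over the data.
The deviance is minimised over theta >= 0 with the boundary permitted; a
boundary (or near-boundary) optimum is flagged as a singular fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "FixedEffectEstimate",
    "LMFit",
    "LMMFit",
    "DummyCodedLM",
    "RandomInterceptLMM",
    "fit_lm",
    "fit_lmm",
    "reml_criterion",
    "slopes_at_infinite_variance",
]

_RANK_RTOL = 1e-10  # relative cutoff on design singular values
_DEFAULT_SINGULAR_TOL = 1e-4  # boundary tolerance on theta (ratio scale)


@dataclass(frozen=True)
class FixedEffectEstimate:
    """Point estimate of one fixed-effect coefficient with its Wald interval."""

    name: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be nonnegative")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("interval must bracket the estimate")


def _interval(name: str, est: float, se: float, alpha: float, policy: str, df: int) -> FixedEffectEstimate:
    """Wald interval with a z or t critical value."""
    if policy == "z":
        crit = stats.norm.ppf(1 - alpha / 2)
    elif policy == "t":
        crit = stats.t.ppf(1 - alpha / 2, df)
    else:
        raise ValueError(f"unknown interval policy {policy!r}; use 'z' or 't'")
    half = crit * se
    return FixedEffectEstimate(name, est, se, est - half, est + half)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise naming the most implicated column if the design is rank deficient."""
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] <= _RANK_RTOL * s[0]:
        _, _, vt = np.linalg.svd(X)
        offender = names[int(np.argmax(np.abs(vt[-1])))]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (column {offender!r} is collinear)"
        )


# ---------------------------------------------------------------------------
# Dummy-coded linear model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LMFit:
    """OLS results for the model with the grouping factor as fixed effects.

    ``group_effects`` are the per-level intercepts (reference level's
    intercept plus its dummy offset for the others), i.e. the no-pooling
    group means after adjusting for the covariates.
    """

    slopes: tuple[FixedEffectEstimate, FixedEffectEstimate]
    group_effects: np.ndarray
    sigma2_resid_hat: float
    df_resid: int
    alpha: float
    interval_policy: str

    @property
    def params(self) -> dict[str, float]:
        return {e.name: e.estimate for e in self.slopes}

    def summary(self) -> str:
        lines = [
            "Dummy-coded linear model (OLS)",
            f"  residual variance: {self.sigma2_resid_hat:.6g} on {self.df_resid} df",
            f"  {100 * (1 - self.alpha):g}% CIs: {self.interval_policy}-based",
            f"  {'param':<10}{'estimate':>12}{'se':>12}{'ci_low':>12}{'ci_high':>12}",
        ]
        for e in self.slopes:
            lines.append(
                f"  {e.name:<10}{e.estimate:>12.5f}{e.se:>12.5f}{e.ci_low:>12.5f}{e.ci_high:>12.5f}"
            )
        lines.append(
            "  group intercepts: "
            + ", ".join(f"{a:.4f}" for a in self.group_effects)
        )
        return "\n".join(lines)


class DummyCodedLM:
    """Linear model with intercept, covariates, and treatment-coded group dummies.

    Parameters
    ----------
    endog : array, shape (n,)
        Response.
    exog : array, shape (n, k)
        Covariate columns (no intercept, no group dummies).
    groups : int array, shape (n,)
        Group labels in ``1..g``.
    """

    def __init__(self, endog, exog, groups, exog_names=None):
        self.y = np.asarray(endog, dtype=float)
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != self.y.shape[0]:
            exog = exog.T
        self.exog = exog
        self.groups = np.asarray(groups, dtype=int)
        self.g = int(self.groups.max())
        n, k = exog.shape
        self.exog_names = list(exog_names) if exog_names else [f"x{i+1}" for i in range(k)]
        dummies = (self.groups[:, None] == np.arange(2, self.g + 1)[None, :]).astype(float)
        self.X = np.column_stack([np.ones(n), exog, dummies])
        self.names = ["intercept", *self.exog_names, *[f"group_{j}" for j in range(2, self.g + 1)]]

    def fit(self, alpha: float = 0.05, interval: str = "t") -> LMFit:
        X, y = self.X, self.y
        n, p = X.shape
        _check_full_rank(X, self.names)
        XtX = X.T @ X
        c, low = linalg.cho_factor(XtX)
        beta = linalg.cho_solve((c, low), X.T @ y)
        resid = y - X @ beta
        df = n - p
        sigma2 = float(resid @ resid) / df
        cov = sigma2 * linalg.cho_solve((c, low), np.eye(p))
        se = np.sqrt(np.diag(cov))
        k = len(self.exog_names)
        slopes = tuple(
            _interval(self.names[1 + i], float(beta[1 + i]), float(se[1 + i]), alpha, interval, df)
            for i in range(k)
        )
        group_effects = beta[0] + np.concatenate([[0.0], beta[1 + k :]])
        return LMFit(
            slopes=slopes,
            group_effects=group_effects,
            sigma2_resid_hat=sigma2,
            df_resid=df,
            alpha=alpha,
            interval_policy=interval,
        )


# ---------------------------------------------------------------------------
# Random-intercept LMM via profiled REML
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LMMFit:
    """REML results for the random-intercept model."""

    intercept: FixedEffectEstimate
    slopes: tuple[FixedEffectEstimate, ...]
    sigma2_site_hat: float
    sigma2_resid_hat: float
    theta_hat: float
    singular: bool
    converged: bool
    alpha: float
    interval_policy: str
    cov_params: np.ndarray

    @property
    def params(self) -> dict[str, float]:
        out = {self.intercept.name: self.intercept.estimate}
        out.update({e.name: e.estimate for e in self.slopes})
        return out

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model (REML)",
            f"  theta (sd ratio): {self.theta_hat:.6g}"
            + ("  [singular fit]" if self.singular else ""),
            f"  group variance:    {self.sigma2_site_hat:.6g}",
            f"  residual variance: {self.sigma2_resid_hat:.6g}",
            f"  {100 * (1 - self.alpha):g}% CIs: {self.interval_policy}-based Wald",
            f"  {'param':<10}{'estimate':>12}{'se':>12}{'ci_low':>12}{'ci_high':>12}",
        ]
        for e in (self.intercept, *self.slopes):
            lines.append(
                f"  {e.name:<10}{e.estimate:>12.5f}{e.se:>12.5f}{e.ci_low:>12.5f}{e.ci_high:>12.5f}"
            )
        return "\n".join(lines)


class RandomInterceptLMM:
    """Gaussian LMM with a single random intercept, fitted by profiled REML.

    Parameters
    ----------
    endog : array, shape (n,)
        Response.
    exog : array, shape (n, p)
        Full fixed-effects design, including the intercept column.
    groups : int array, shape (n,)
        Group labels in ``1..g``.
    exog_names : sequence of str, optional
        Names for the columns of ``exog``.
    """

    #: coarse search grid for bracketing the deviance minimum (theta scale)
    _GRID = np.concatenate([[0.0], np.geomspace(1e-3, 32.0, 24)])

    def __init__(self, endog, exog, groups, exog_names=None):
        self.y = np.asarray(endog, dtype=float)
        X = np.atleast_2d(np.asarray(exog, dtype=float))
        if X.shape[0] != self.y.shape[0]:
            X = X.T
        self.X = X
        self.groups = np.asarray(groups, dtype=int)
        self.n, self.p = X.shape
        self.g = int(self.groups.max())
        self.names = (
            list(exog_names) if exog_names else ["intercept"] + [f"x{i}" for i in range(1, self.p)]
        )
        _check_full_rank(X, self.names)
        idx = self.groups - 1
        self._counts = np.bincount(idx, minlength=self.g).astype(float)
        # sufficient statistics: criterion evaluations never touch X, y again
        self._XtX = X.T @ X
        self._Xty = X.T @ self.y
        self._yty = float(self.y @ self.y)
        self._ZtX = np.zeros((self.g, self.p))
        np.add.at(self._ZtX, idx, X)
        self._Zty = np.bincount(idx, weights=self.y, minlength=self.g)

    # -- profiled REML criterion ------------------------------------------

    def _solve(self, theta: float):
        """GLS pieces at theta: (beta, chol of X'V^-1 X, r'V^-1 r, log|V|)."""
        t2 = theta * theta
        d = t2 / (1.0 + t2 * self._counts)
        ZtX_d = self._ZtX * d[:, None]
        A = self._XtX - self._ZtX.T @ ZtX_d
        b = self._Xty - ZtX_d.T @ self._Zty
        q = self._yty - float(d @ (self._Zty**2))
        c, low = linalg.cho_factor(A)
        beta = linalg.cho_solve((c, low), b)
        rVr = max(q - float(beta @ b), np.finfo(float).tiny)
        logdetV = float(np.sum(np.log1p(t2 * self._counts)))
        return beta, (c, low), rVr, logdetV

    def reml_criterion(self, theta: float) -> float:
        """Concentrated REML deviance at theta, up to an additive constant.

        ``log|V| + log|X' V^-1 X| + (n - p) log(r' V^-1 r)`` with
        ``V = I + theta^2 Z Z'`` and r the GLS residual at theta.
        """
        if theta < 0:
            raise ValueError("theta must be nonnegative")
        _, (c, _), rVr, logdetV = self._solve(theta)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(c))))
        return logdetV + logdetA + (self.n - self.p) * np.log(rVr)

    def _minimize_theta(self) -> tuple[float, bool]:
        """Bracket on a coarse grid (grown geometrically if the optimum sits
        at the grid edge), then polish with bounded Brent; exact boundary
        check at theta = 0. Ties resolve to the smaller theta."""
        grid = self._GRID
        vals = np.array([self.reml_criterion(t) for t in grid])
        i = int(np.argmin(vals))
        while i == len(grid) - 1 and grid[-1] < 1e6:
            grid = np.append(grid, grid[-1] * 4.0)
            vals = np.append(vals, self.reml_criterion(grid[-1]))
            i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        converged = True
        if hi > lo:
            res = optimize.minimize_scalar(
                self.reml_criterion,
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-9},
            )
            converged = bool(res.success)
            theta = float(res.x)
            if vals[i] < res.fun:  # grid point beat the polish (flat region)
                theta = float(grid[i])
        else:
            theta = float(grid[i])
        # the profiled deviance may decrease monotonically into the boundary
        if self.reml_criterion(0.0) <= self.reml_criterion(theta):
            theta = 0.0
        return theta, converged

    def fit(
        self,
        alpha: float = 0.05,
        singular_tol: float = _DEFAULT_SINGULAR_TOL,
        interval: str = "z",
    ) -> LMMFit:
        """Minimise the profiled REML deviance and assemble Wald inference.

        A fit with ``theta_hat`` below ``singular_tol`` is flagged singular:
        the random-intercept variance is estimated at (or numerically
        indistinguishable from) zero.
        """
        if singular_tol <= 0:
            raise ValueError("singular_tol must be positive")
        theta, converged = self._minimize_theta()
        beta, (c, low), rVr, _ = self._solve(theta)
        sigma2_resid = rVr / (self.n - self.p)
        sigma2_site = theta * theta * sigma2_resid
        cov = sigma2_resid * linalg.cho_solve((c, low), np.eye(self.p))
        se = np.sqrt(np.diag(cov))
        df = self.n - self.p
        ests = [
            _interval(self.names[i], float(beta[i]), float(se[i]), alpha, interval, df)
            for i in range(self.p)
        ]
        return LMMFit(
            intercept=ests[0],
            slopes=tuple(ests[1:]),
            sigma2_site_hat=float(sigma2_site),
            sigma2_resid_hat=float(sigma2_resid),
            theta_hat=float(theta),
            singular=bool(theta < singular_tol),
            converged=converged,
            alpha=alpha,
            interval_policy=interval,
            cov_params=cov,
        )


# ---------------------------------------------------------------------------
# SimDataset conveniences
# ---------------------------------------------------------------------------


def _lmm_from_dataset(dataset) -> RandomInterceptLMM:
    X = np.column_stack([np.ones(dataset.n_obs), dataset.x1, dataset.x2])
    return RandomInterceptLMM(
        dataset.y, X, dataset.group, exog_names=["intercept", "beta1", "beta2"]
    )


def fit_lm(dataset, alpha: float = 0.05, interval: str = "t") -> LMFit:
    """OLS fit with the grouping factor dummy-coded (no pooling)."""
    model = DummyCodedLM(
        dataset.y,
        np.column_stack([dataset.x1, dataset.x2]),
        dataset.group,
        exog_names=["beta1", "beta2"],
    )
    return model.fit(alpha=alpha, interval=interval)


def fit_lmm(
    dataset,
    alpha: float = 0.05,
    singular_tol: float = _DEFAULT_SINGULAR_TOL,
    interval: str = "z",
) -> LMMFit:
    """Random-intercept REML fit (partial pooling)."""
    return _lmm_from_dataset(dataset).fit(
        alpha=alpha, singular_tol=singular_tol, interval=interval
    )


def reml_criterion(dataset, theta: float) -> float:
    """Concentrated REML deviance of the random-intercept model at theta."""
    return _lmm_from_dataset(dataset).reml_criterion(theta)


def slopes_at_infinite_variance(dataset) -> tuple[float, float]:
    """GLS slope limit as theta -> infinity, via within-group centering.

    With an infinite random-intercept variance the GLS estimator discards
    all between-group contrasts, which is exactly the within-group (fixed
    effects) estimator: center y, x1, x2 by their group means and regress.
    Equals the dummy-coded LM slopes.
    """
    idx = dataset.group - 1
    counts = np.bincount(idx, minlength=dataset.n_levels).astype(float)

    def center(v):
        means = np.bincount(idx, weights=v, minlength=dataset.n_levels) / counts
        return v - means[idx]

    Xc = np.column_stack([center(dataset.x1), center(dataset.x2)])
    yc = center(dataset.y)
    beta, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    return float(beta[0]), float(beta[1])
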