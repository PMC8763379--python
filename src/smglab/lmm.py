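"""Random-intercept linear mixed models with permutation-based inference.

The statistics stage relates longitudinal outcome metrics (cross-validation
accuracy and the five feature-space metrics) to study covariates through

    Y_ij = beta0 + b_i + beta' X_ij + eps_ij,
    b_i ~ N(0, sigma_b^2),  eps_ij ~ N(0, sigma_eps^2), independent,

where i indexes subjects and j repeated measurements.  Because studies of
this kind have few subjects and the normality assumptions are doubtful,
significance comes from a permutation test: the tested covariate's values
are shuffled *within each subject* (which preserves the random-intercept
dependence structure and the other covariates), the model is refitted, and
the observed coefficient t-ratio is ranked among the permuted ones with the
add-one rule p = (1 + b) / (1 + m).

Fitting uses maximum likelihood (not REML) so that refits under permuted
fixed effects are on a comparable likelihood scale.  The single variance
ratio rho = sigma_b^2 / sigma_eps^2 is profiled out analytically per subject
block via the Sherman-Morrison identity, leaving a one-dimensional
optimization; this makes a fit cheap enough for hundreds of thousands of
permutation refits.  ``fit_lmm(..., method="statsmodels")`` routes the same
model through :class:`statsmodels.regression.mixed_linear_model.MixedLM`
instead, which serves as an independent cross-check of the profiled fitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

_TWO_PI = 2.0 * np.pi


@dataclass
class LMMSpec:
    """Model description: outcome, fixed covariates, grouping, and test setup."""

    outcome: str
    covariates: tuple[str, ...]
    group: str = "subject"
    test_covariate: str | None = None
    sidedness: str = "two-sided"        # "two-sided", "greater", "less"
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.sidedness not in ("two-sided", "greater", "less"):
            raise ValueError("sidedness must be 'two-sided', 'greater' or 'less'")


@dataclass
class LMMFit:
    """Maximum-likelihood fit of the random-intercept model."""

    params: pd.Series            # fixed effects, index ["const", covariates...]
    bse: pd.Series               # asymptotic standard errors
    tvalues: pd.Series           # params / bse
    sigma_b: float
    sigma_eps: float
    loglike: float
    n_obs: int
    n_groups: int
    pvalues: dict = field(default_factory=dict)   # permutation p per covariate


def normalized_time(data: pd.DataFrame, time_col: str = "time_min",
                    group_col: str = "subject") -> pd.Series:
    """Per-subject elapsed time rescaled to [0, 1].

    Each subject's measurement times map to (t - t_first) / (t_last -
    t_first); subjects whose measurements all share one time are rejected.
    """
    out = pd.Series(np.nan, index=data.index, dtype=float, name="time_norm")
    for g, sub in data.groupby(group_col):
        t = sub[time_col].astype(float)
        span = t.max() - t.min()
        if span == 0:
            raise ValueError(f"subject {g!r} has no time variation to normalize")
        out.loc[sub.index] = (t - t.min()) / span
    return out


# ---------------------------------------------------------------------------
# profiled maximum-likelihood fitter
# ---------------------------------------------------------------------------

def _design(data: pd.DataFrame, spec: LMMSpec):
    missing = [c for c in (spec.outcome, *spec.covariates, spec.group)
               if c not in data.columns]
    if missing:
        raise ValueError(f"column(s) missing from data: {missing}")
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in spec.covariates]
    )
    y = data[spec.outcome].to_numpy(dtype=float)
    codes, groups = pd.factorize(data[spec.group], sort=True)
    names = ["const", *spec.covariates]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        rank_full = np.linalg.matrix_rank(X)
        involved = [
            names[j] for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank_full
        ]
        raise ValueError(f"singular design matrix; collinear column(s): {involved}")
    return X, y, codes, len(groups), names


class _Profiler:
    """Profile -2 log-likelihood of the variance ratio rho = sigma_b^2/sigma_eps^2.

    For block-diagonal V with blocks sigma_eps^2 (I + rho J), Sherman-Morrison
    gives V^{-1} in terms of per-group sums, so each evaluation costs only a
    p x p solve plus O(n_groups * p) arithmetic.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int):
        self.X, self.y, self.codes, self.G = X, y, codes, n_groups
        self.N, self.p = X.shape
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.n_i = np.bincount(codes, minlength=n_groups).astype(float)
        self.Sx = np.zeros((n_groups, self.p))
        for j in range(self.p):
            self.Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_groups)
        self.Sy = np.bincount(codes, weights=y, minlength=n_groups)

    def gls(self, rho: float):
        w = rho / (1.0 + self.n_i * rho)
        A = self.XtX - (self.Sx * w[:, None]).T @ self.Sx
        c = self.Xty - self.Sx.T @ (w * self.Sy)
        beta = np.linalg.solve(A, c)
        yVy = self.yty - float(w @ (self.Sy ** 2))
        q = max(yVy - float(beta @ c), 1e-300)
        return beta, A, q, w

    def neg2ll(self, rho: float) -> float:
        _, _, q, _ = self.gls(rho)
        sigma2 = q / self.N
        logdet = float(np.sum(np.log1p(self.n_i * rho)))
        return self.N * np.log(_TWO_PI * sigma2) + logdet + self.N

    def fit(self):
        res = minimize_scalar(
            lambda u: self.neg2ll(np.exp(u)),
            bounds=(-13.0, 13.0), method="bounded",
            options={"xatol": 1e-6},
        )
        rho = float(np.exp(res.x))
        best = float(res.fun)
        at_zero = self.neg2ll(0.0)
        if at_zero <= best:      # boundary solution sigma_b = 0
            rho, best = 0.0, at_zero
        beta, A, q, _ = self.gls(rho)
        sigma2 = q / self.N
        cov_beta = sigma2 * np.linalg.inv(A)
        return beta, cov_beta, rho, sigma2, -0.5 * best


def fit_lmm(data: pd.DataFrame, spec: LMMSpec, method: str = "profile") -> LMMFit:
    """Maximum-likelihood fit of the random-intercept model of ``spec``.

    ``method="profile"`` uses the fast built-in profiled-likelihood fitter;
    ``method="statsmodels"`` fits the identical model through MixedLM (ML).
    """
    X, y, codes, n_groups, names = _design(data, spec)
    if n_groups < 2:
        raise ValueError("need at least 2 subjects")
    if np.min(np.bincount(codes)) < 2:
        raise ValueError("every subject needs at least 2 measurements")
    if method == "statsmodels":
        import statsmodels.api as sm

        md = sm.MixedLM(y, X, groups=codes)
        fit = md.fit(reml=False)
        params = pd.Series(fit.fe_params, index=names)
        bse = pd.Series(fit.bse_fe, index=names)
        sigma_b = float(np.sqrt(max(float(np.squeeze(fit.cov_re)), 0.0)))
        sigma_eps = float(np.sqrt(fit.scale))
        return LMMFit(params=params, bse=bse, tvalues=params / bse,
                      sigma_b=sigma_b, sigma_eps=sigma_eps,
                      loglike=float(fit.llf), n_obs=len(y), n_groups=n_groups)
    if method != "profile":
        raise ValueError("method must be 'profile' or 'statsmodels'")
    prof = _Profiler(X, y, codes, n_groups)
    beta, cov_beta, rho, sigma2, llf = prof.fit()
    params = pd.Series(beta, index=names)
    bse = pd.Series(np.sqrt(np.diag(cov_beta)), index=names)
    return LMMFit(params=params, bse=bse, tvalues=params / bse,
                  sigma_b=float(np.sqrt(rho * sigma2)),
                  sigma_eps=float(np.sqrt(sigma2)),
                  loglike=llf, n_obs=len(y), n_groups=n_groups)


def _tstat(X, y, codes, n_groups, col: int) -> float:
    if float(np.var(y)) < 1e-30:
        return 0.0  # constant outcome carries no evidence; all refits tie
    prof = _Profiler(X, y, codes, n_groups)
    beta, cov_beta, _, _, _ = prof.fit()
    se = float(np.sqrt(max(cov_beta[col, col], 0.0)))
    if se == 0 or not np.isfinite(se):
        return 0.0  # degenerate (e.g. constant outcome): no evidence either way
    return float(beta[col] / se)


def permutation_pvalue(
    data: pd.DataFrame,
    spec: LMMSpec,
    coefficient: str | None = None,
    rng: np.random.Generator | None = None,
    return_null: bool = False,
):
    """Permutation p-value for one fixed effect of the random-intercept model.

    The tested covariate is shuffled within each subject; all other columns
    stay fixed.  The statistic is the coefficient's t-ratio from a full ML
    refit.  ``sidedness="greater"``/``"less"`` rank signed statistics,
    ``"two-sided"`` absolute values; the add-one rule bounds p below by
    1/(n_permutations + 1).
    """
    coefficient = coefficient or spec.test_covariate or spec.covariates[-1]
    if coefficient not in spec.covariates:
        raise ValueError(f"{coefficient!r} is not among the fixed covariates")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    X, y, codes, n_groups, names = _design(data, spec)
    col = names.index(coefficient)
    xcol = X[:, col]
    group_idx = [np.flatnonzero(codes == g) for g in range(n_groups)]
    if all(np.ptp(xcol[idx]) == 0 for idx in group_idx):
        raise ValueError(
            f"covariate {coefficient!r} is constant within every subject; "
            "within-subject permutation cannot test it"
        )
    observed = _tstat(X, y, codes, n_groups, col)
    null_stats = np.empty(spec.n_permutations)
    Xp = X.copy()
    for b in range(spec.n_permutations):
        xp = xcol.copy()
        for idx in group_idx:
            xp[idx] = xcol[idx][rng.permutation(len(idx))]
        Xp[:, col] = xp
        null_stats[b] = _tstat(Xp, y, codes, n_groups, col)
    if spec.sidedness == "two-sided":
        b_ge = int(np.sum(np.abs(null_stats) >= abs(observed) - 1e-12))
    elif spec.sidedness == "greater":
        b_ge = int(np.sum(null_stats >= observed - 1e-12))
    else:
        b_ge = int(np.sum(null_stats <= observed + 1e-12))
    p = (1.0 + b_ge) / (1.0 + spec.n_permutations)
    if return_null:
        return p, observed, null_stats
    return p, observed


def fit_with_permutations(data: pd.DataFrame, spec: LMMSpec,
                          test_covariates=None) -> LMMFit:
    """Fit the model and attach permutation p-values for the tested covariates."""
    fit = fit_lmm(data, spec)
    tested = tuple(test_covariates or
                   ((spec.test_covariate,) if spec.test_covariate else spec.covariates))
    rng = np.random.default_rng(spec.seed)
    for cov in tested:
        p, _ = permutation_pvalue(data, spec, coefficient=cov, rng=rng)
        fit.pvalues[cov] = p
    return fit
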