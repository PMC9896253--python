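"""Logistic prediction models: maximum-likelihood fitting, odds-ratio tables,
collinearity diagnostics, and Rubin pooling across imputations.

The basic model carries seven predictors (age per 10 years younger, NIHSS per
point higher, ASPECTS per point lower, ICA occlusion, collateral score per
point lower, onset-to-groin per 60 min, unsuccessful reperfusion); the
extended model adds the CSF/ICV ratio per percentage point lower.  Fitting is
iteratively reweighted least squares with step-halving, so the log-likelihood
is non-decreasing across iterations; convergence is declared when the largest
coefficient change drops below 1e-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .cohort import BASIC_PREDICTORS, EXTENDED_PREDICTORS  # noqa: F401  (re-export)
from .errors import (
    NotConvergedError,
    PoolingError,
    RankDeficiencyError,
    SeparationError,
)

_COEF_LIMIT = 50.0  # |beta| beyond this on standardized-ish codings => separation


def _loglike(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
    check_separation: bool = True,
    names: list[str] | None = None,
):
    """Core IRLS loop.  Returns (beta, cov, loglike, converged, n_iter, history)."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError("design matrix is rank deficient")
    names = names or [f"x{j}" for j in range(p)]
    pen = np.full(p, ridge)
    pen[0] = 0.0  # never penalize the intercept

    beta = np.zeros(p)
    ll = _loglike(X, y, beta) - 0.5 * np.sum(pen * beta**2)
    history = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        H = X.T @ (X * w[:, None]) + np.diag(pen)
        g = X.T @ (y - mu) - pen * beta
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise RankDeficiencyError("singular information matrix") from exc
        # step-halving keeps the (penalized) log-likelihood monotone
        for _ in range(40):
            cand = beta + step
            ll_cand = _loglike(X, y, cand) - 0.5 * np.sum(pen * cand**2)
            if ll_cand >= ll - 1e-12:
                break
            step = step / 2.0
        delta = float(np.max(np.abs(cand - beta)))
        beta, ll = cand, ll_cand
        history.append(ll)
        if check_separation and np.max(np.abs(beta)) > _COEF_LIMIT:
            raise SeparationError(names[int(np.argmax(np.abs(beta)))])
        if delta < tol:
            converged = True
            break

    mu = expit(X @ beta)
    if check_separation and not converged:
        events, nonevents = mu[y == 1], mu[y == 0]
        if (
            events.size and nonevents.size
            and np.all(events > 1 - 1e-8) and np.all(nonevents < 1e-8)
        ):
            # perfect prediction: blame the predictor with the largest
            # scale-adjusted coefficient (intercept excluded)
            scales = np.std(X, axis=0)
            scales[0] = 0.0
            j = int(np.argmax(np.abs(beta) * scales))
            raise SeparationError(names[j])
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = X.T @ (X * w[:, None]) + np.diag(pen)
    cov = np.linalg.inv(H)
    return beta, cov, _loglike(X, y, beta), converged, n_iter, history


@dataclass
class LogisticFit:
    """A fitted logistic model: coefficients, covariance and diagnostics."""

    params: pd.Series
    cov: pd.DataFrame
    loglike: float
    n: int
    converged: bool
    predictors: list[str]
    n_iter: int = 0
    loglike_history: list[float] = field(default_factory=list, repr=False)
    df: pd.Series | None = None  # Rubin degrees of freedom (pooled fits only)
    m: int = 1  # number of pooled imputations

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Event probabilities for the rows of a coded frame."""
        X = np.column_stack(
            [np.ones(len(frame))] + [frame[p].to_numpy(float) for p in self.predictors]
        )
        return expit(X @ self.params.to_numpy())


def fit_logistic(
    frame: pd.DataFrame,
    predictors: list[str],
    outcome: str = "outcome_event",
    ridge: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression on a coded model frame.

    ``frame`` must contain one column per predictor plus a 0/1 outcome column
    with no missing values among the used columns.  Complete separation
    raises :class:`SeparationError` naming the offending predictor; a rank
    deficient design raises :class:`RankDeficiencyError`.  ``ridge`` > 0
    applies an optional L2 penalty (off by default).
    """
    cols = list(predictors) + [outcome]
    sub = frame[cols]
    if sub.isna().any().any():
        raise ValueError("missing values among predictors/outcome; impute first")
    y = sub[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("need at least one event and one non-event")
    X = np.column_stack([np.ones(len(sub))] + [sub[p].to_numpy(float) for p in predictors])
    names = ["intercept"] + list(predictors)
    beta, cov, ll, converged, n_iter, history = _irls(
        X, y, ridge=ridge, tol=tol, max_iter=max_iter, names=names
    )
    return LogisticFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        loglike=ll,
        n=len(y),
        converged=converged,
        predictors=list(predictors),
        n_iter=n_iter,
        loglike_history=history,
    )


def odds_ratios(
    fit: LogisticFit,
    level: float = 0.95,
    include_intercept: bool = False,
) -> pd.DataFrame:
    """Wald odds-ratio table: OR, CI bounds and p value per predictor.

    Pooled fits (carrying Rubin degrees of freedom) use t reference
    distributions; single fits use the normal.
    """
    if not fit.converged:
        raise NotConvergedError(
            f"fit did not converge after {fit.n_iter} iterations; refusing OR table"
        )
    rows = []
    se = fit.bse
    for name in fit.params.index:
        if name == "intercept" and not include_intercept:
            continue
        b, s = float(fit.params[name]), float(se[name])
        if fit.df is not None and np.isfinite(fit.df.get(name, np.inf)):
            dist = stats.t(df=float(fit.df[name]))
        else:
            dist = stats.norm()
        q = dist.ppf(0.5 + level / 2.0)
        p = 2.0 * dist.sf(abs(b) / s) if s > 0 else (1.0 if b == 0 else 0.0)
        rows.append(
            {
                "predictor": name,
                "or": float(np.exp(b)),
                "ci_low": float(np.exp(b - q * s)),
                "ci_high": float(np.exp(b + q * s)),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")


def vif(frame: pd.DataFrame, predictors: list[str]) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1-R^2_j), regressing each
    predictor on all others (with intercept).  Perfect collinearity maps to
    ``inf``.
    """
    if len(frame) < len(predictors) + 2:
        raise ValueError("need at least len(predictors)+2 rows for VIF")
    out = {}
    X = frame[predictors].to_numpy(dtype=float)
    for j, name in enumerate(predictors):
        y = X[:, j]
        others = np.column_stack([np.ones(len(y)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot <= 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def pool_fits(fits: list[LogisticFit]) -> LogisticFit:
    """Combine per-imputation fits with Rubin's rules.

    Pooled coefficient = mean; total covariance = mean within-imputation
    covariance + (1 + 1/m) x between-imputation covariance; per-coefficient
    degrees of freedom df = (m-1) (1 + W / ((1+1/m) B))^2.
    """
    if not fits:
        raise PoolingError("no fits to pool")
    ref = fits[0]
    for f in fits[1:]:
        if f.predictors != ref.predictors:
            raise PoolingError("fits have mismatched predictor lists")
    m = len(fits)
    params = np.stack([f.params.to_numpy() for f in fits])
    covs = np.stack([f.cov.to_numpy() for f in fits])
    qbar = params.mean(axis=0)
    wbar = covs.mean(axis=0)
    if m > 1:
        dev = params - qbar
        B = dev.T @ dev / (m - 1)
    else:
        B = np.zeros_like(wbar)
    T = wbar + (1.0 + 1.0 / m) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        bd = np.diag(B)
        wd = np.diag(wbar)
        lam = (1.0 + 1.0 / m) * bd
        df = np.where(lam > 0, (m - 1) * (1.0 + wd / lam) ** 2, np.inf)
    names = ref.params.index
    return LogisticFit(
        params=pd.Series(qbar, index=names),
        cov=pd.DataFrame(T, index=names, columns=names),
        loglike=float(np.mean([f.loglike for f in fits])),
        n=ref.n,
        converged=all(f.converged for f in fits),
        predictors=list(ref.predictors),
        n_iter=max(f.n_iter for f in fits),
        df=pd.Series(df, index=names),
        m=m,
    )
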