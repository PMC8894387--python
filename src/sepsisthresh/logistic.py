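"""Maximum-likelihood logistic regression engine.

Every inferential stage of the package (tertile odds ratios, one-line and
two-piecewise exposure models, confounder screening) runs through
:func:`fit_logistic`.  The fit is plain iteratively reweighted least squares
(IRLS) on the Bernoulli log-likelihood with Wald inference from the inverse
observed information; there is no penalisation, so perfect separation is an
error rather than a silently shrunken estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "LogisticFit",
    "SeparationError",
    "RankDeficiencyError",
    "fit_logistic",
    "odds_ratios",
    "screen_confounders",
]

MAX_ITER = 100
SCORE_TOL = 1e-8


class SeparationError(ValueError):
    """Raised when the likelihood has no finite maximiser (perfect separation)."""


class RankDeficiencyError(ValueError):
    """Raised when the design matrix columns are linearly dependent."""


@dataclass
class LogisticFit:
    """Result of a converged (or failed) maximum-likelihood logistic fit.

    Attributes
    ----------
    params
        Coefficient estimates on the log-odds scale, indexed by column name.
    cov
        Inverse observed information evaluated at the estimate.
    loglik
        Maximised Bernoulli log-likelihood (always <= 0).
    n_obs, converged, n_iter
        Fitting metadata.
    """

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n_obs: int
    converged: bool
    n_iter: int

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.params.index)

    def linear_combination(self, weights: dict[str, float]) -> tuple[float, float]:
        """Estimate and standard error of sum_j w_j * beta_j (delta method)."""
        w = pd.Series(0.0, index=self.params.index)
        for name, val in weights.items():
            w[name] = val
        est = float(w @ self.params)
        var = float(w @ self.cov.to_numpy() @ w)
        return est, float(np.sqrt(var))

    def to_dict(self) -> dict:
        return {
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "log_likelihood": self.loglik,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "iterations": self.n_iter,
        }


def _as_frame(X, names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(names))


def _check_single_column_separation(X: np.ndarray, y: np.ndarray, names) -> None:
    # cheap detector for the common failure mode: one column completely
    # separates cases from non-cases
    for j, name in enumerate(names):
        col = X[:, j]
        if np.ptp(col) == 0:
            continue
        lo1, hi1 = col[y == 1].min(), col[y == 1].max()
        lo0, hi0 = col[y == 0].min(), col[y == 0].max()
        if hi1 <= lo0 or hi0 <= lo1:
            raise SeparationError(
                f"column {name!r} perfectly separates the outcome; "
                "the maximum-likelihood estimate does not exist"
            )


def fit_logistic(X, y, names=None) -> LogisticFit:
    """Fit logit P(y=1) = X beta by IRLS.

    Parameters
    ----------
    X
        Design matrix (``pandas.DataFrame`` or array plus ``names``); must
        already contain an intercept column if one is wanted.
    y
        Binary response with both classes present.

    Raises
    ------
    RankDeficiencyError
        If the columns of ``X`` are linearly dependent (names the dependent
        columns).
    SeparationError
        If the outcome is perfectly separated so no finite MLE exists.
    """
    Xf = _as_frame(X, names)
    y = np.asarray(y, dtype=float).ravel()
    Xm = Xf.to_numpy(dtype=float)
    n, p = Xm.shape
    if y.shape[0] != n:
        raise ValueError(f"response length {y.shape[0]} != design rows {n}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("response has a single class; logistic fit undefined")
    if np.isnan(Xm).any():
        raise ValueError("design matrix contains missing values")

    # rank check via pivoted QR on standardised columns
    scale = np.where(Xm.std(axis=0) > 0, Xm.std(axis=0), 1.0)
    r = np.linalg.matrix_rank(Xm / scale)
    if r < p:
        _, R, piv = _qr_pivot(Xm / scale)
        dep = [Xf.columns[j] for j in piv[r:]]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {r} < {p}); "
            f"dependent columns: {dep}"
        )

    _check_single_column_separation(Xm, y, Xf.columns)

    beta = np.zeros(p)
    ll_old = _bernoulli_loglik(Xm, y, beta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = Xm @ beta
        mu = expit(eta)
        score = Xm.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        w = mu * (1.0 - mu)
        if w.max() < 1e-12:
            raise SeparationError("all fitted probabilities degenerate; separation suspected")
        XtWX = (Xm * w[:, None]).T @ Xm
        try:
            step = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rank guarded above
            raise RankDeficiencyError(str(exc)) from exc
        # step halving keeps the log-likelihood monotone
        t = 1.0
        for _ in range(30):
            ll_new = _bernoulli_loglik(Xm, y, beta + t * step)
            if ll_new >= ll_old - 1e-12:
                break
            t /= 2.0
        beta = beta + t * step
        ll_old = ll_new
        if np.max(np.abs(beta)) > 1e3:
            raise SeparationError(
                "coefficients diverging (|beta| > 1e3); data are separated or nearly so"
            )
    else:
        it = MAX_ITER

    eta = Xm @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    XtWX = (Xm * w[:, None]).T @ Xm
    cov = np.linalg.inv(XtWX)
    return LogisticFit(
        params=pd.Series(beta, index=Xf.columns),
        cov=pd.DataFrame(cov, index=Xf.columns, columns=Xf.columns),
        loglik=float(_bernoulli_loglik(Xm, y, beta)),
        n_obs=n,
        converged=converged,
        n_iter=it,
    )


def _bernoulli_loglik(X, y, beta) -> float:
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _qr_pivot(A):
    from scipy.linalg import qr

    Q, R, piv = qr(A, pivoting=True, mode="economic")
    return Q, R, piv


def odds_ratios(fit: LogisticFit, conf: float = 0.95) -> pd.DataFrame:
    """Wald odds ratios, confidence limits and two-sided p-values per coefficient."""
    z = stats.norm.ppf(0.5 + conf / 2.0)
    se = fit.bse
    zstat = fit.params / se
    p = 2.0 * stats.norm.sf(np.abs(zstat))
    return pd.DataFrame(
        {
            "or": np.exp(fit.params),
            "lower": np.exp(fit.params - z * se),
            "upper": np.exp(fit.params + z * se),
            "p": p,
        },
        index=fit.params.index,
    )


@dataclass
class ScreenResult:
    """Change-in-estimate confounder screen output."""

    selected: list[str]
    log: pd.DataFrame = field(repr=False)


def screen_confounders(
    y,
    exposure,
    candidates: pd.DataFrame,
    base: pd.DataFrame | None = None,
    threshold: float = 0.10,
) -> ScreenResult:
    """Select covariates whose inclusion moves the exposure OR by > ``threshold``.

    A candidate is selected when ``|OR_with / OR_without - 1| > threshold``,
    where both models contain the intercept, the exposure and the ``base``
    covariates.  Candidates whose model fails to converge are flagged in the
    log (``status`` column) rather than silently dropped.
    """
    exposure = np.asarray(exposure, dtype=float)
    n = exposure.shape[0]
    X0 = pd.DataFrame({"intercept": np.ones(n), "exposure": exposure})
    if base is not None:
        X0 = pd.concat([X0, base.reset_index(drop=True)], axis=1)
    fit0 = fit_logistic(X0, y)
    or0 = float(np.exp(fit0.params["exposure"]))

    rows = []
    selected = []
    for name in candidates.columns:
        X1 = X0.copy()
        X1[name] = candidates[name].to_numpy(dtype=float)
        try:
            fit1 = fit_logistic(X1, y)
        except (SeparationError, RankDeficiencyError) as exc:
            rows.append({"candidate": name, "or_without": or0, "or_with": np.nan,
                         "rel_change": np.nan, "selected": False,
                         "status": f"failed: {exc}"})
            continue
        or1 = float(np.exp(fit1.params["exposure"]))
        change = abs(or1 / or0 - 1.0)
        keep = change > threshold
        if keep:
            selected.append(name)
        rows.append({"candidate": name, "or_without": or0, "or_with": or1,
                     "rel_change": change, "selected": keep, "status": "ok"})
    return ScreenResult(selected=selected, log=pd.DataFrame(rows))
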