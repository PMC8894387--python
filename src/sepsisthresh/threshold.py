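"""Threshold-effect (two-piecewise logistic) analysis of a continuous exposure.

The exposure enters the logit either as a single linear term (the "one-line"
model) or as ``beta1 * x + beta2 * max(x - K, 0)`` — a hinge that keeps the
logit continuous at the turning point K while letting the slope change.  K is
not known a priori: it is estimated by profiling the log-likelihood over a
grid of candidate values and keeping the maximiser, the standard exploratory
turning-point search for threshold (U- or J-shaped) risk relationships.
Non-linearity is judged by a likelihood-ratio test of the one-line model
against the two-piecewise model at the selected K (df = 1, the hinge
coefficient; the search itself is not counted, which makes the test
anti-conservative — measured, not hidden, see docs/methods.md), and the
sampling uncertainty of K itself by a nonparametric patient bootstrap with
percentile limits.  Effects are reported per unit and per sample-SD of the
exposure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .logistic import LogisticFit, fit_logistic

__all__ = [
    "EffectEstimate",
    "ThresholdResult",
    "GridSpec",
    "make_grid",
    "fit_one_line",
    "fit_two_piecewise",
    "search_turning_point",
    "lrt_one_vs_two",
    "bootstrap_turning_point_ci",
    "per_sd_or",
    "standardize_value",
    "threshold_effect_analysis",
]

logger = logging.getLogger(__name__)

MIN_SEGMENT = 20  # smallest number of observations allowed on either side of K


@dataclass
class EffectEstimate:
    """An odds ratio with its Wald CI and two-sided p-value."""

    or_: float
    lower: float
    upper: float
    p: float

    def per_sd(self, sd: float) -> "EffectEstimate":
        return EffectEstimate(self.or_**sd, self.lower**sd, self.upper**sd, self.p)

    def rounded(self, nd: int = 2) -> tuple[float, float, float]:
        return round(self.or_, nd), round(self.lower, nd), round(self.upper, nd)

    def to_dict(self) -> dict:
        return {"or": self.or_, "lower": self.lower, "upper": self.upper, "p": self.p}


def _wald_effect(est: float, se: float, conf: float = 0.95) -> EffectEstimate:
    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = 2.0 * stats.norm.sf(abs(est) / se) if se > 0 else np.nan
    return EffectEstimate(float(np.exp(est)), float(np.exp(est - z * se)),
                          float(np.exp(est + z * se)), float(p))


@dataclass
class GridSpec:
    """Candidate turning points: ``step``-spaced values between the
    ``q_lo`` and ``q_hi`` exposure quantiles, keeping >= ``min_segment``
    observations on each side of every candidate."""

    q_lo: float = 0.05
    q_hi: float = 0.95
    step: float = 0.1
    min_segment: int = MIN_SEGMENT


def make_grid(x: np.ndarray, spec: GridSpec) -> np.ndarray:
    """Realize the candidate-K grid for an observed exposure vector."""
    x = np.asarray(x, dtype=float)
    lo, hi = np.quantile(x, [spec.q_lo, spec.q_hi])
    # snap to the step lattice so printed K values land on one decimal
    start = np.ceil(lo / spec.step) * spec.step
    grid = np.arange(start, hi + 1e-9, spec.step)
    xs = np.sort(x)
    n_below = np.searchsorted(xs, grid, side="left")
    ok = (n_below >= spec.min_segment) & (x.size - n_below >= spec.min_segment)
    keep = grid[ok]
    if len(keep) < 3:
        raise ValueError("fewer than 3 admissible turning-point candidates; "
                         "widen the quantile window or lower min_segment")
    return np.round(np.asarray(keep), 10)


def _design(x: np.ndarray, covariates: pd.DataFrame | None, K: float | None) -> pd.DataFrame:
    cols = {"intercept": np.ones(len(x)), "ratio": x}
    if K is not None:
        cols["ratio_hinge"] = np.maximum(x - K, 0.0)
    X = pd.DataFrame(cols)
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    return X


def fit_one_line(y, x, covariates: pd.DataFrame | None = None,
                 sd: float | None = None, conf: float = 0.95):
    """Linear ("one-line") exposure model; returns the fit and the per-unit
    and per-SD exposure odds ratios."""
    x = np.asarray(x, dtype=float)
    fit = fit_logistic(_design(x, covariates, None), y)
    est, se = fit.params["ratio"], fit.bse["ratio"]
    eff = _wald_effect(est, se, conf)
    sd = float(np.std(x, ddof=1)) if sd is None else sd
    return fit, eff, eff.per_sd(sd)


def fit_two_piecewise(y, x, K: float, covariates: pd.DataFrame | None = None,
                      conf: float = 0.95, min_segment: int = MIN_SEGMENT):
    """Hinge model at a fixed turning point K.

    The logit is ``b1 * x + b2 * (x - K)+`` (continuous at K); the
    below-threshold slope is b1, the above-threshold slope b1 + b2 with its
    variance from the delta method (V11 + V22 + 2 V12).
    Returns ``(fit, effect_below, effect_above)``.
    """
    x = np.asarray(x, dtype=float)
    n_below, n_above = int((x < K).sum()), int((x >= K).sum())
    if n_below < min_segment or n_above < min_segment:
        raise ValueError(
            f"turning point {K} leaves a segment below the minimum size "
            f"({n_below} below / {n_above} above < {min_segment})"
        )
    fit = fit_logistic(_design(x, covariates, K), y)
    b1, se1 = fit.params["ratio"], fit.bse["ratio"]
    est_above, se_above = fit.linear_combination({"ratio": 1.0, "ratio_hinge": 1.0})
    return fit, _wald_effect(b1, se1, conf), _wald_effect(est_above, se_above, conf)


def _irls(X: np.ndarray, y: np.ndarray, beta: np.ndarray | None = None,
          tol: float = 1e-8, max_iter: int = 100) -> tuple[np.ndarray, float, bool]:
    """Bare-metal IRLS on a numeric design; same likelihood and stopping rule
    as :func:`sepsisthresh.logistic.fit_logistic`, stripped of validation so
    the profile search and bootstrap can afford ~10^5 fits."""
    n, p = X.shape
    if beta is None:
        beta = np.zeros(p)
    eta = X @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    for _ in range(max_iter):
        mu = expit(eta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            return beta, ll, True
        w = mu * (1.0 - mu)
        step = np.linalg.solve((X * w[:, None]).T @ X, score)
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            eta_c = X @ cand
            ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
            if ll_c >= ll - 1e-12:
                break
            t /= 2.0
        beta, eta, ll = cand, eta_c, ll_c
        if np.max(np.abs(beta)) > 1e3:
            raise ValueError("diverging coefficients; separation suspected")
    return beta, ll, False


def _profile_loglik(y: np.ndarray, x: np.ndarray, Z: np.ndarray | None,
                    grid: np.ndarray) -> np.ndarray:
    """Two-piecewise log-likelihood at every candidate K.

    The hinge column is updated in place and each fit warm-starts from its
    grid neighbour, so scanning the grid costs only a few IRLS steps per K.
    """
    n = y.shape[0]
    ncov = 0 if Z is None else Z.shape[1]
    X = np.empty((n, 3 + ncov))
    X[:, 0] = 1.0
    X[:, 1] = x
    if Z is not None:
        X[:, 3:] = Z
    profile = np.full(grid.size, -np.inf)
    beta = None
    for i, K in enumerate(grid):
        X[:, 2] = np.maximum(x - K, 0.0)
        try:
            beta, ll, converged = _irls(X, y, None if beta is None else beta.copy())
            if converged:
                profile[i] = ll
        except (ValueError, np.linalg.LinAlgError):
            beta = None
    return profile


def search_turning_point(y, x, covariates: pd.DataFrame | None = None,
                         grid: np.ndarray | GridSpec | None = None):
    """Profile-likelihood turning-point search.

    Fits the two-piecewise model at every candidate K and returns
    ``(K_hat, grid, profile_loglik)`` with K_hat the log-likelihood
    maximiser (ties broken toward the smallest K, with a warning).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if grid is None or isinstance(grid, GridSpec):
        grid = make_grid(x, grid or GridSpec())
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3:
        raise ValueError("turning-point grid needs at least 3 candidates")
    Z = None if covariates is None else covariates.to_numpy(dtype=float)
    profile = _profile_loglik(y, x, Z, grid)
    if not np.isfinite(profile).any():
        raise RuntimeError("two-piecewise fit failed at every candidate turning point")
    best = np.flatnonzero(profile >= profile[np.isfinite(profile)].max() - 1e-12)
    if best.size > 1:
        logger.warning("profile log-likelihood tied at %d candidates; taking smallest K", best.size)
    return float(grid[best[0]]), grid, profile


def lrt_one_vs_two(fit_one: LogisticFit, fit_two: LogisticFit, df: int = 1):
    """Likelihood-ratio test of the one-line model against the hinge model.

    ``statistic = 2 * (loglik_two - loglik_one)`` referred to chi-squared(df).
    A materially negative statistic means the models are not nested as fitted
    (or a fit failed) and is an error.
    """
    delta = fit_two.loglik - fit_one.loglik
    if delta < -1e-6:
        raise ValueError(
            f"two-piecewise log-likelihood {fit_two.loglik:.6f} below one-line "
            f"{fit_one.loglik:.6f}: fits are inconsistent"
        )
    statistic = max(2.0 * delta, 0.0)
    return statistic, float(stats.chi2.sf(statistic, df))


def bootstrap_turning_point_ci(
    y,
    x,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 500,
    seed: int = 0,
    grid_spec: GridSpec | None = None,
    conf: float = 0.95,
    min_boot: int = 100,
    max_fail_fraction: float = 0.10,
):
    """Nonparametric bootstrap percentile CI for the turning point.

    Patients are resampled with replacement; each resample reruns the full
    grid search (grid recomputed from the resample's own exposure quantiles).
    Resamples whose search fails are dropped and counted; more than
    ``max_fail_fraction`` failures is an error.  Returns
    ``(lower, upper, K_hat_distribution)``.
    """
    if n_boot < min_boot:
        raise ValueError(f"n_boot={n_boot} below the enforced minimum {min_boot}")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    Z = None if covariates is None else covariates.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n = len(y)
    spec = grid_spec or GridSpec()
    ks, n_fail = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            k_hat, _, _ = search_turning_point(
                y[idx], x[idx],
                None if Z is None else Z.iloc[idx].reset_index(drop=True),
                grid=spec,
            )
            ks.append(k_hat)
        except Exception:
            n_fail += 1
    if n_fail > max_fail_fraction * n_boot:
        raise RuntimeError(f"{n_fail}/{n_boot} bootstrap resamples failed the turning-point search")
    if n_fail:
        logger.info("bootstrap: %d/%d resamples failed and were dropped", n_fail, n_boot)
    ks = np.asarray(ks)
    alpha = 1.0 - conf
    lower, upper = np.quantile(ks, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lower), float(upper), ks


def per_sd_or(or_unit: float, sd: float) -> float:
    """Rescale a per-unit odds ratio to per-SD: OR_sd = OR_unit ** sd.
    CI limits transform identically (monotone power of a positive number)."""
    if or_unit <= 0:
        raise ValueError("odds ratio must be positive")
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(or_unit**sd)


def standardize_value(v: float, mean: float, sd: float) -> float:
    """Exposure value as a z-score relative to the cohort mean/SD."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return (v - mean) / sd


@dataclass
class ThresholdResult:
    """Full threshold-effect analysis output (the published table's analogue)."""

    K_hat: float
    K_ci: tuple[float, float]
    or_below: EffectEstimate
    or_above: EffectEstimate
    or_below_sd: EffectEstimate
    or_above_sd: EffectEstimate
    one_line_or: EffectEstimate
    one_line_or_sd: EffectEstimate
    lrt_statistic: float
    lrt_p: float
    grid: np.ndarray = field(repr=False)
    profile_loglik: np.ndarray = field(repr=False)
    sd_used: float = np.nan
    mean_used: float = np.nan
    n_boot: int = 0
    seed: int = 0

    @property
    def K_hat_sd(self) -> float:
        return standardize_value(self.K_hat, self.mean_used, self.sd_used)

    @property
    def K_ci_sd(self) -> tuple[float, float]:
        return (standardize_value(self.K_ci[0], self.mean_used, self.sd_used),
                standardize_value(self.K_ci[1], self.mean_used, self.sd_used))

    def to_dict(self) -> dict:
        return {
            "turning_point": self.K_hat,
            "turning_point_ci": list(self.K_ci),
            "turning_point_standardized": self.K_hat_sd,
            "turning_point_ci_standardized": list(self.K_ci_sd),
            "or_below": self.or_below.to_dict(),
            "or_above": self.or_above.to_dict(),
            "or_below_per_sd": self.or_below_sd.to_dict(),
            "or_above_per_sd": self.or_above_sd.to_dict(),
            "one_line_or": self.one_line_or.to_dict(),
            "one_line_or_per_sd": self.one_line_or_sd.to_dict(),
            "lrt_statistic": self.lrt_statistic,
            "lrt_p": self.lrt_p,
            "exposure_mean": self.mean_used,
            "exposure_sd": self.sd_used,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }

    def to_table(self) -> pd.DataFrame:
        """Model I / Model II summary with per-unit and per-SD columns."""
        def fmt(e: EffectEstimate) -> str:
            return f"{e.or_:.2f} ({e.lower:.2f}, {e.upper:.2f})"

        rows = [
            ("Model I: one line effect", fmt(self.one_line_or), f"{self.one_line_or.p:.3f}",
             fmt(self.one_line_or_sd), f"{self.one_line_or_sd.p:.3f}"),
            ("Model II: turning point (K)", f"{self.K_hat:.1f}", "",
             f"{self.K_hat_sd:.2f}", ""),
            ("Model II: ratio < K", fmt(self.or_below), f"{self.or_below.p:.3f}",
             fmt(self.or_below_sd), f"{self.or_below_sd.p:.3f}"),
            ("Model II: ratio >= K", fmt(self.or_above), f"{self.or_above.p:.3f}",
             fmt(self.or_above_sd), f"{self.or_above_sd.p:.3f}"),
            ("LRT p (one-line vs two-piecewise)", f"{self.lrt_p:.3f}", "",
             f"{self.lrt_p:.3f}", ""),
            ("95% CI for turning point", f"{self.K_ci[0]:.1f}, {self.K_ci[1]:.1f}", "",
             f"{self.K_ci_sd[0]:.2f}, {self.K_ci_sd[1]:.2f}", ""),
        ]
        return pd.DataFrame(rows, columns=["model", "per_unit_or", "per_unit_p",
                                           "per_sd_or", "per_sd_p"])


def threshold_effect_analysis(
    y,
    x,
    covariates: pd.DataFrame | None = None,
    grid_spec: GridSpec | None = None,
    n_boot: int = 500,
    seed: int = 0,
    conf: float = 0.95,
) -> ThresholdResult:
    """One-line vs two-piecewise analysis end to end.

    Runs the profile search for K, fits both models, forms the df=1 LRT,
    bootstraps the percentile CI for K, and rescales every exposure OR to
    per-SD units using the cohort sample mean/SD of the exposure.
    """
    x = np.asarray(x, dtype=float)
    mean, sd = float(np.mean(x)), float(np.std(x, ddof=1))
    spec = grid_spec or GridSpec()
    K_hat, grid, profile = search_turning_point(y, x, covariates, grid=spec)
    fit1, eff1, eff1_sd = fit_one_line(y, x, covariates, sd=sd, conf=conf)
    fit2, eff_lo, eff_hi = fit_two_piecewise(y, x, K_hat, covariates, conf=conf)
    statistic, p = lrt_one_vs_two(fit1, fit2)
    lo, hi, ks = bootstrap_turning_point_ci(
        y, x, covariates, n_boot=n_boot, seed=seed, grid_spec=spec, conf=conf
    )
    if not lo <= K_hat <= hi:
        logger.warning("percentile CI (%.2f, %.2f) does not contain K_hat=%.2f", lo, hi, K_hat)
    return ThresholdResult(
        K_hat=K_hat, K_ci=(lo, hi),
        or_below=eff_lo, or_above=eff_hi,
        or_below_sd=eff_lo.per_sd(sd), or_above_sd=eff_hi.per_sd(sd),
        one_line_or=eff1, one_line_or_sd=eff1_sd,
        lrt_statistic=statistic, lrt_p=p,
        grid=grid, profile_loglik=profile,
        sd_used=sd, mean_used=mean, n_boot=n_boot, seed=seed,
    )
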