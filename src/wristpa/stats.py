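"""Repeated-measures models on daily summaries.

Linear mixed models with a per-subject random intercept for day-of-week,
weekend-by-week, reactivity (measurement-day) and season effects, adjusted
for age, sex and peak VO2 (plus daily wear time for activity outcomes);
an ordinary-least-squares weekday/weekend sleep contrast; and a two-sided
Wilcoxon rank-sum comparison of wear time between groups.

The mixed-model engine is a profiled (RE)ML fit of
``y = X b + u_subject + e`` with optional known residual variance weights
(``Var(e_ij) = sigma^2 / w_ij``), optimizing the single variance ratio
``theta = tau^2 / sigma^2`` by bounded scalar search. Factor significance
is a likelihood-ratio test of the factor's columns using ML fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from wristpa.errors import ConfigError, InputError

__all__ = [
    "ModelSpec",
    "ModelResult",
    "RegressionEstimate",
    "RankTestResult",
    "fit_mixed",
    "weekend_week_contrast",
    "sleep_weekday_regression",
    "weartime_rank_test",
    "OUTCOME_COLUMNS",
    "FACTORS",
]

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile

OUTCOME_COLUMNS = {
    "sedentary": "sedentary_minutes",
    "lpa": "lpa_minutes",
    "mpa": "mpa_minutes",
    "mvpa": "mvpa_minutes",
    "bouted_mvpa": "bouted_mvpa_minutes",
    "vpa": "vpa_minutes",
    "tpa": "tpa_minutes",
    "wear": "wear_minutes",
    "sleep": "sleep_minutes",
}

FACTORS = ("day_of_week", "weekend_week", "measurement_day", "season")

_DOW_LEVELS = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday",
               "Saturday", "Sunday")
_SEASON_LEVELS = ("Spring", "Summer", "Autumn", "Winter")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, factor of interest, adjustment set, weights.

    Covariates are always age, sex (reference male) and peak VO2; daily
    wear time is added for activity outcomes and never when the outcome is
    wear time itself. ``weights`` is None (unweighted), a mapping from
    factor level to a known variance weight, or ``"by_factor_level"`` to
    estimate inverse per-level residual variances from one unweighted pass.
    """

    outcome: str
    factor: str
    weights: object = None
    reml: bool = True

    def __post_init__(self):
        if self.outcome not in OUTCOME_COLUMNS:
            raise ConfigError(f"unknown outcome {self.outcome!r}")
        if self.factor not in FACTORS:
            raise ConfigError(f"unknown factor {self.factor!r}")

    @property
    def include_wear(self) -> bool:
        return self.outcome not in ("wear", "sleep")


class FactorTest(NamedTuple):
    statistic: float
    df: int
    pvalue: float


@dataclass
class ModelResult:
    """Fixed effects, joint factor test and variance components."""

    params: pd.DataFrame  # index term; columns estimate, se, ci_low, ci_high
    factor_test: FactorTest
    tau2: float  # random-intercept variance
    sigma2: float  # residual variance
    n_obs: int
    n_subjects: int
    converged: bool
    loglik: float
    spec: ModelSpec | None = None

    def to_dict(self) -> dict:
        return {
            "spec": None if self.spec is None else {
                "outcome": self.spec.outcome,
                "factor": self.spec.factor,
                "weights": str(self.spec.weights),
                "reml": self.spec.reml,
            },
            "params": self.params.reset_index()
            .rename(columns={"index": "term"})
            .to_dict(orient="records"),
            "factor_test": {
                "statistic": self.factor_test.statistic,
                "df": self.factor_test.df,
                "pvalue": self.factor_test.pvalue,
            },
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "loglik": self.loglik,
        }


class RegressionEstimate(NamedTuple):
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_obs: int


class RankTestResult(NamedTuple):
    statistic: float
    pvalue: float


# ---------------------------------------------------------------------------
# random-intercept (RE)ML engine


class _RandomInterceptFit(NamedTuple):
    beta: np.ndarray
    cov: np.ndarray
    sigma2: float
    tau2: float
    loglik_ml: float
    converged: bool
    theta: float


def _prepare_blocks(X, y, codes, w):
    """Sort rows by subject and precompute theta-independent pieces."""
    order = np.argsort(codes, kind="stable")
    X, y, codes, w = X[order], y[order], codes[order], w[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(codes)) + 1])
    wX = X * w[:, None]
    return {
        "X": X, "y": y, "w": w, "starts": starts,
        "s": np.add.reduceat(w, starts),  # per-group sum of weights
        "C": np.add.reduceat(wX, starts, axis=0),  # per-group X' W 1
        "d": np.add.reduceat(w * y, starts),  # per-group 1' W y
        "XtWX": wX.T @ X,
        "XtWy": X.T @ (w * y),
        "ytWy": float(y @ (w * y)),
        "sum_log_w": float(np.sum(np.log(w))),
    }


def _solve_at_theta(theta, B, reml):
    """Profiled -2 log-likelihood at a given variance ratio theta."""
    n, p = B["X"].shape
    k = theta / (1.0 + theta * B["s"])
    XtVX = B["XtWX"] - B["C"].T @ (k[:, None] * B["C"])
    XtVy = B["XtWy"] - B["C"].T @ (k * B["d"])
    ytVy = B["ytWy"] - float(k @ B["d"] ** 2)
    try:
        cf = scipy.linalg.cho_factor(XtVX)
        beta = scipy.linalg.cho_solve(cf, XtVy)
        logdet_XtVX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    except np.linalg.LinAlgError:
        return np.inf, None
    quad = max(ytVy - float(beta @ XtVy), 1e-300)
    logdet_sigma = float(np.sum(np.log1p(theta * B["s"]))) - B["sum_log_w"]
    if reml:
        sigma2 = quad / (n - p)
        crit = (n - p) * np.log(sigma2) + logdet_sigma + logdet_XtVX
    else:
        sigma2 = quad / n
        crit = n * np.log(sigma2) + logdet_sigma
    return crit, (beta, XtVX, sigma2)


def _fit_random_intercept(X, y, codes, w=None, reml=True) -> _RandomInterceptFit:
    n, p = X.shape
    if w is None:
        w = np.ones(n)
    B = _prepare_blocks(np.asarray(X, float), np.asarray(y, float),
                        np.asarray(codes), np.asarray(w, float))
    # coarse log-grid then local refinement; theta = tau^2 / sigma^2 >= 0
    grid = np.concatenate([[0.0], np.logspace(-6, 4, 41)])
    crits = np.array([_solve_at_theta(t, B, reml)[0] for t in grid])
    i = int(np.nanargmin(crits))
    converged = np.isfinite(crits[i])
    if i == 0:
        lo, hi = 0.0, grid[1]
    elif i == len(grid) - 1:
        lo, hi = grid[i - 1], grid[i] * 10
    else:
        lo, hi = grid[i - 1], grid[i + 1]
    res = scipy.optimize.minimize_scalar(
        lambda t: _solve_at_theta(t, B, reml)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    theta = float(res.x) if res.fun <= crits[i] else float(grid[i])
    crit, sol = _solve_at_theta(theta, B, reml)
    if sol is None:
        return _RandomInterceptFit(
            np.full(p, np.nan), np.full((p, p), np.nan),
            np.nan, np.nan, np.nan, False, np.nan,
        )
    beta, XtVX, sigma2 = sol
    cov = sigma2 * np.linalg.inv(XtVX)
    # ML log-likelihood at this theta (needed for LRTs even after REML fits)
    _, ml_sol = _solve_at_theta(theta, B, reml=False)
    sigma2_ml = ml_sol[2]
    logdet_sigma = float(np.sum(np.log1p(theta * B["s"]))) - B["sum_log_w"]
    loglik_ml = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet_sigma + n)
    return _RandomInterceptFit(
        beta=beta, cov=cov, sigma2=sigma2, tau2=theta * sigma2,
        loglik_ml=float(loglik_ml), converged=bool(converged and np.isfinite(crit)),
        theta=theta,
    )


# ---------------------------------------------------------------------------
# design matrices


def _check_rank(X: pd.DataFrame):
    Q, R, piv = scipy.linalg.qr(X.to_numpy(), pivoting=True, mode="economic")
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = [X.columns[j] for j in piv[rank:]]
        raise InputError(f"rank-deficient design; collinear columns: {bad}")


def _factor_columns(data: pd.DataFrame, factor: str) -> pd.DataFrame:
    if factor == "day_of_week":
        levels = [l for l in _DOW_LEVELS[1:] if (data["day_of_week"] == l).any()]
        if not levels:
            raise InputError("day_of_week has a single level")
        return pd.DataFrame(
            {f"day_of_week[{l}]": (data["day_of_week"] == l).astype(float)
             for l in levels}
        )
    if factor == "season":
        levels = [l for l in _SEASON_LEVELS[1:] if (data["season"] == l).any()]
        if not levels:
            raise InputError("season has a single level")
        return pd.DataFrame(
            {f"season[{l}]": (data["season"] == l).astype(float) for l in levels}
        )
    if factor == "weekend_week":
        return pd.DataFrame(
            {
                "is_weekend": data["is_weekend"].astype(float),
                "week2": (data["week_index"] == 2).astype(float),
            }
        )
    if factor == "measurement_day":
        return pd.DataFrame(
            {"measurement_day": data["measurement_day"].astype(float)}
        )
    raise ConfigError(f"unknown factor {factor!r}")


def _design(data: pd.DataFrame, spec: ModelSpec):
    ycol = OUTCOME_COLUMNS[spec.outcome]
    for col in (ycol, "subject_id", "age", "sex", "vo2peak"):
        if col not in data.columns:
            raise InputError(f"daily table lacks required column {col!r}")
    data = data.reset_index(drop=True)
    y = data[ycol].astype(float)
    if y.isna().any():
        keep = ~y.isna()
        data, y = data[keep].reset_index(drop=True), y[keep].reset_index(drop=True)
    fac = _factor_columns(data, spec.factor).reset_index(drop=True)
    cov = pd.DataFrame(
        {
            "age": data["age"].astype(float),
            "sex[female]": (data["sex"] == "female").astype(float),
            "vo2peak": data["vo2peak"].astype(float),
        }
    )
    if cov["sex[female]"].nunique() == 1:
        # single-sex data makes the dummy a constant (inestimable); drop it
        logger.debug("single sex level; dropping sex dummy from the design")
        cov = cov.drop(columns="sex[female]")
    if spec.include_wear:
        cov["wear_minutes"] = data["wear_minutes"].astype(float)
    intercept = pd.DataFrame({"Intercept": np.ones(len(data))})
    X_full = pd.concat([intercept, fac, cov], axis=1)
    X_red = pd.concat([intercept, cov], axis=1)
    codes = pd.factorize(data["subject_id"])[0]
    return X_full, X_red, y.to_numpy(), codes, list(fac.columns), data


def _row_weights(data, spec: ModelSpec, X_full, y, codes) -> np.ndarray | None:
    if spec.weights is None:
        return None
    fac_level = _factor_level_labels(data, spec.factor)
    if isinstance(spec.weights, dict):
        w = fac_level.map(spec.weights).astype(float)
        if w.isna().any():
            missing = sorted(set(fac_level[w.isna()]))
            raise ConfigError(f"weights missing for factor levels {missing}")
        return w.to_numpy()
    if spec.weights == "by_factor_level":
        pilot = _fit_random_intercept(X_full.to_numpy(), y, codes, reml=spec.reml)
        resid = _blup_residuals(X_full.to_numpy(), y, codes, pilot)
        var = pd.Series(resid).groupby(fac_level.to_numpy()).var(ddof=1)
        w = fac_level.map(1.0 / var).astype(float).to_numpy()
        return w / w.mean()
    raise ConfigError(f"unknown weights spec {spec.weights!r}")


def _factor_level_labels(data, factor) -> pd.Series:
    if factor == "day_of_week":
        return data["day_of_week"]
    if factor == "season":
        return data["season"]
    if factor == "weekend_week":
        kind = pd.Series(
            np.where(data["is_weekend"], "weekend", "weekday"), index=data.index
        )
        return kind + "/w" + data["week_index"].astype(str)
    if factor == "measurement_day":
        return data["measurement_day"].astype(str)
    raise ConfigError(factor)


def _blup_residuals(X, y, codes, fit: _RandomInterceptFit) -> np.ndarray:
    """Conditional residuals y - X beta - BLUP(subject intercept)."""
    r = y - X @ fit.beta
    theta = fit.theta
    out = np.empty_like(r)
    for g in np.unique(codes):
        m = codes == g
        s = m.sum()
        b = theta * r[m].sum() / (1.0 + theta * s)
        out[m] = r[m] - b
    return out


# ---------------------------------------------------------------------------
# public operations


def fit_mixed(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit a random-intercept linear mixed model for ``spec`` on a daily
    summary table (one row per subject-day, included subjects only).

    Estimates and standard errors come from the (RE)ML fit; the factor's
    joint significance is a likelihood-ratio test of its columns against
    the covariates-only model, both fit by maximum likelihood. Reference
    levels: Monday for day of week, Spring for season, male for sex.
    Non-convergence is flagged on the result, not raised.
    """
    X_full, X_red, y, codes, fac_cols, data2 = _design(data, spec)
    counts = np.bincount(codes)
    if len(counts) < 2 or np.sum(counts >= 2) < 2:
        raise InputError("need at least 2 subjects with at least 2 days each")
    _check_rank(X_full)
    w = _row_weights(data2, spec, X_full, y, codes)
    fit = _fit_random_intercept(X_full.to_numpy(), y, codes, w, reml=spec.reml)
    full_ml = (
        fit if not spec.reml
        else _fit_random_intercept(X_full.to_numpy(), y, codes, w, reml=False)
    )
    red_ml = _fit_random_intercept(X_red.to_numpy(), y, codes, w, reml=False)
    lr = max(2.0 * (full_ml.loglik_ml - red_ml.loglik_ml), 0.0)
    df = len(fac_cols)
    test = FactorTest(
        statistic=float(lr), df=df, pvalue=float(scipy.stats.chi2.sf(lr, df))
    )
    se = np.sqrt(np.diag(fit.cov))
    params = pd.DataFrame(
        {
            "estimate": fit.beta,
            "se": se,
            "ci_low": fit.beta - Z95 * se,
            "ci_high": fit.beta + Z95 * se,
        },
        index=X_full.columns,
    )
    return ModelResult(
        params=params,
        factor_test=test,
        tau2=fit.tau2,
        sigma2=fit.sigma2,
        n_obs=len(y),
        n_subjects=int(len(counts)),
        converged=bool(fit.converged and full_ml.converged and red_ml.converged),
        loglik=full_ml.loglik_ml,
        spec=spec,
    )


def weekend_week_contrast(
    data: pd.DataFrame, outcome: str, weights=None, reml: bool = True
) -> ModelResult:
    """Mixed model with weekend and week-2 indicators as the factor of
    interest (joint 2-df test), same adjustment set as :func:`fit_mixed`."""
    return fit_mixed(
        data, ModelSpec(outcome=outcome, factor="weekend_week",
                        weights=weights, reml=reml)
    )


def sleep_weekday_regression(data: pd.DataFrame) -> RegressionEstimate:
    """OLS of daily sleep minutes on a weekend indicator; the reported
    estimate is the weekend minus weekday difference with a 95% CI."""
    if "sleep_minutes" not in data.columns:
        raise InputError("daily table lacks sleep_minutes")
    sub = data[["sleep_minutes", "is_weekend"]].dropna()
    if sub.empty:
        raise InputError("no non-missing sleep minutes")
    X = sm.add_constant(sub["is_weekend"].astype(float).to_numpy())
    fit = sm.OLS(sub["sleep_minutes"].to_numpy(), X).fit()
    est, se = float(fit.params[1]), float(fit.bse[1])
    return RegressionEstimate(
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        pvalue=float(fit.pvalues[1]),
        n_obs=int(fit.nobs),
    )


def weartime_rank_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test of daily wear
    minutes between two groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return RankTestResult(statistic=float(a.size * b.size / 2.0), pvalue=1.0)
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return RankTestResult(statistic=float(res.statistic), pvalue=float(res.pvalue))
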