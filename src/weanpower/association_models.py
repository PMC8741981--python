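"""Group comparisons, logistic regression and correlation analyses.

Continuous between-group differences are tested with Student's t when both
groups pass a Kolmogorov-Smirnov (Lilliefors) normality screen and with the
Mann-Whitney U-test otherwise; categorical differences with the chi-square
test, or Fisher's exact test when any expected cell is below five.  The
logistic layer fits maximum-likelihood binary models (Newton/IRLS via
statsmodels) with Wald odds-ratio intervals per caller-chosen unit, greedy
forward selection by likelihood-ratio test, Hosmer-Lemeshow calibration and
Nagelkerke pseudo-R2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                             PerfectSeparationError,
                                             PerfectSeparationWarning)

from .indices import DomainError

logger = logging.getLogger(__name__)

NORMALITY_ALPHA = 0.05


class SeparationError(RuntimeError):
    """The outcome is perfectly separated by the covariates."""


class FitConvergenceError(RuntimeError):
    """The likelihood maximization did not converge."""


# --------------------------------------------------------------------------
# bivariate group comparisons

@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    test: str                 # "t" | "mann-whitney" | "chi-square" | "fisher"
    statistic: float
    p_value: float
    group_summaries: dict


def _is_normal(x: np.ndarray) -> bool:
    if len(x) < 4 or np.ptp(x) == 0:
        return False
    _, p = lilliefors(x, dist="norm")
    return p > NORMALITY_ALPHA


def compare_groups(values, labels, variable_kind: str,
                   name: str = "") -> ComparisonResult:
    """Two-group comparison with the study's test-selection rule.

    Continuous: Lilliefors-corrected KS normality screen per group at
    alpha 0.05, then Student's t (both normal) or Mann-Whitney U.
    Categorical: chi-square, or Fisher's exact when an expected cell < 5.
    Two-sided p-values throughout.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise DomainError("values and labels must align")
    groups = np.unique(labels)
    if len(groups) != 2:
        raise DomainError(f"need exactly two groups, found {len(groups)}")
    a = values[labels == groups[0]]
    b = values[labels == groups[1]]
    if len(a) == 0 or len(b) == 0:
        raise DomainError("both groups must be non-empty")

    if variable_kind == "continuous":
        a = a.astype(float)
        b = b.astype(float)
        summaries = {g: {"n": len(x), "mean": float(np.mean(x)),
                         "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
                         "median": float(np.median(x))}
                     for g, x in zip(groups, (a, b))}
        if _is_normal(a) and _is_normal(b):
            stat, p = stats.ttest_ind(a, b)
            return ComparisonResult(name, "t", float(stat), float(p), summaries)
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult(name, "mann-whitney", float(stat), float(p),
                                summaries)

    if variable_kind == "categorical":
        table = pd.crosstab(pd.Series(labels), pd.Series(values)).to_numpy()
        if table.shape[1] < 2:
            raise DomainError(f"variable {name!r} is constant")
        summaries = {g: {"n": int(np.sum(labels == g)),
                         "count": int(np.sum((labels == g) & (values == values.max())))}
                     for g in groups}
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any() and table.shape == (2, 2):
            stat, p = stats.fisher_exact(table)
            return ComparisonResult(name, "fisher", float(stat), float(p),
                                    summaries)
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return ComparisonResult(name, "chi-square", float(stat), float(p),
                                summaries)

    raise DomainError(f"unknown variable kind {variable_kind!r}")


# --------------------------------------------------------------------------
# logistic regression

@dataclass(frozen=True)
class LogisticFit:
    """A fitted binary logistic model with inference metadata.

    ``unit_scales`` maps covariate name -> reporting unit (e.g. 1000 for an
    odds ratio per 1000 cmH2O^2/min); odds ratios are exp(coef x unit).
    """

    names: tuple[str, ...]          # covariates, excluding the intercept
    params: np.ndarray              # [intercept, *covariates]
    bse: np.ndarray
    loglike: float
    loglike_null: float
    nobs: int
    fitted: np.ndarray              # in-sample probabilities
    outcomes: np.ndarray
    converged: bool
    n_iter: int
    unit_scales: dict

    def wald_p(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.params / self.bse
        return 2 * stats.norm.sf(np.abs(z))

    def odds_ratios(self, confidence: float = 0.95) -> pd.DataFrame:
        """OR per reporting unit with Wald CIs and p-values, one covariate/row."""
        z = stats.norm.ppf(0.5 + confidence / 2)
        p = self.wald_p()
        rows = []
        for i, name in enumerate(self.names, start=1):
            scale = self.unit_scales.get(name, 1.0)
            beta, se = self.params[i] * scale, self.bse[i] * scale
            rows.append({"variable": name, "unit": scale,
                         "or": math.exp(beta),
                         "or_lo": math.exp(beta - z * se),
                         "or_hi": math.exp(beta + z * se),
                         "p": p[i]})
        return pd.DataFrame(rows)


def _null_loglike(y: np.ndarray) -> float:
    n1 = y.sum()
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return 0.0
    p = n1 / len(y)
    return float(n1 * math.log(p) + n0 * math.log(1 - p))


def _check_separation(fitted: np.ndarray, y: np.ndarray) -> None:
    eps = 1e-10
    if np.all((fitted > 1 - eps) == (y == 1)) and np.all((fitted < eps) == (y == 0)):
        raise SeparationError("complete separation: fitted probabilities are "
                              "0/1 and classify the outcome perfectly")


def fit_logistic(design, outcomes, names: Optional[Sequence[str]] = None,
                 unit_scales: Optional[dict] = None) -> LogisticFit:
    """Maximum-likelihood binary logistic regression.

    ``design`` holds the covariates (no intercept column; one is added).
    Newton/IRLS, at most 50 iterations; non-convergence and complete
    separation raise explicit errors rather than returning silently.
    """
    X = pd.DataFrame(design)
    if names is not None:
        X.columns = list(names)
    elif not all(isinstance(c, str) for c in X.columns):
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(outcomes, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise DomainError("outcomes must be coded 0/1")
    if len(y) <= X.shape[1]:
        raise DomainError("need more observations than covariates")
    const_cols = [c for c in X.columns if X[c].nunique() <= 1]
    if const_cols:
        raise DomainError(f"constant covariate(s): {const_cols}")

    Xc = sm.add_constant(X.astype(float), prepend=True)
    model = sm.Logit(y, Xc)
    try:
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("error", ConvergenceWarning)
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(method="newton", maxiter=50, tol=1e-10, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(str(exc)) from exc
    except ConvergenceWarning as exc:
        raise FitConvergenceError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        raise FitConvergenceError("Newton iterations did not converge "
                                  "within 50 steps")
    fitted = np.asarray(res.predict())
    _check_separation(fitted, y)
    return LogisticFit(
        names=tuple(X.columns),
        params=np.asarray(res.params, dtype=float),
        bse=np.asarray(res.bse, dtype=float),
        loglike=float(res.llf),
        loglike_null=_null_loglike(y),
        nobs=len(y),
        fitted=fitted,
        outcomes=y.astype(int),
        converged=True,
        n_iter=int(res.mle_retvals.get("iterations", 0)),
        unit_scales=dict(unit_scales or {}),
    )


def _intercept_only(y: np.ndarray) -> LogisticFit:
    p = float(np.mean(y))
    ll = _null_loglike(y)
    return LogisticFit(names=(), params=np.array([math.log(p / (1 - p))]),
                       bse=np.array([1.0 / math.sqrt(len(y) * p * (1 - p))]),
                       loglike=ll, loglike_null=ll, nobs=len(y),
                       fitted=np.full(len(y), p), outcomes=y.astype(int),
                       converged=True, n_iter=0, unit_scales={})


def likelihood_ratio_p(full: LogisticFit, reduced: LogisticFit) -> float:
    """Two-sided LRT p-value for nested logistic models."""
    df = len(full.names) - len(reduced.names)
    if df <= 0:
        raise DomainError("models are not nested in the stated order")
    lr = 2 * (full.loglike - reduced.loglike)
    return float(stats.chi2.sf(max(lr, 0.0), df))


def forward_select(candidates, outcomes, a_priori: Sequence[str] = (),
                   entry_p: float = 0.05, screen_p: float = 0.2,
                   unit_scales: Optional[dict] = None) -> LogisticFit:
    """Greedy forward selection by likelihood-ratio test.

    The candidate pool is every column whose univariable logistic LRT
    p-value is below ``screen_p``, unioned with the a-priori covariates
    (which always enter the pool regardless of screening).  Variables are
    added while the best addition's LRT p is below ``entry_p``; ties break
    alphabetically, making the path deterministic.
    """
    X = pd.DataFrame(candidates)
    y = np.asarray(outcomes, dtype=float)
    unknown = set(a_priori) - set(X.columns)
    if unknown:
        raise DomainError(f"a-priori variables not in candidates: {sorted(unknown)}")

    pool = set(a_priori)
    for col in X.columns:
        if col in pool:
            continue
        try:
            uni = fit_logistic(X[[col]], y, unit_scales=unit_scales)
        except (SeparationError, FitConvergenceError) as exc:
            logger.warning("screening %s failed (%s); excluded", col, exc)
            continue
        if likelihood_ratio_p(uni, _intercept_only(y)) < screen_p:
            pool.add(col)

    selected: list[str] = []
    current = _intercept_only(y)
    while True:
        best_name, best_p, best_fit = None, math.inf, None
        for col in sorted(pool - set(selected)):
            try:
                trial = fit_logistic(X[selected + [col]], y,
                                     unit_scales=unit_scales)
            except (SeparationError, FitConvergenceError):
                continue
            p = likelihood_ratio_p(trial, current)
            if p < best_p:
                best_name, best_p, best_fit = col, p, trial
        if best_fit is None or best_p >= entry_p:
            break
        selected.append(best_name)
        current = best_fit
    return current


def hosmer_lemeshow(fit_or_probs, outcomes=None,
                    groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow calibration chi-square over risk deciles.

    Returns (statistic, df, p) with df = bins - 2.  Bins with duplicate
    quantile boundaries are merged (df adjusted, logged).
    """
    if isinstance(fit_or_probs, LogisticFit):
        probs = fit_or_probs.fitted
        y = fit_or_probs.outcomes if outcomes is None else np.asarray(outcomes)
    else:
        probs = np.asarray(fit_or_probs, dtype=float)
        if outcomes is None:
            raise DomainError("outcomes required when passing raw probabilities")
        y = np.asarray(outcomes)
    n = len(probs)
    if n < 2 * groups:
        raise DomainError(f"need at least {2 * groups} observations")
    bins = pd.qcut(probs, groups, duplicates="drop")
    n_bins = bins.categories.size
    if n_bins < groups:
        logger.warning("merged %d duplicate risk bins", groups - n_bins)
    df = n_bins - 2
    if df < 1:
        raise DomainError(f"only {n_bins} distinct risk bins; df would be {df}")
    frame = pd.DataFrame({"bin": bins, "y": y, "p": probs})
    stat = 0.0
    for _, g in frame.groupby("bin", observed=True):
        o1, e1 = g["y"].sum(), g["p"].sum()
        o0, e0 = len(g) - o1, len(g) - e1
        if e1 > 0:
            stat += (o1 - e1) ** 2 / e1
        if e0 > 0:
            stat += (o0 - e0) ** 2 / e0
    return float(stat), int(df), float(stats.chi2.sf(stat, df))


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Cox-Snell R2 rescaled to a [0, 1] maximum."""
    n = fit.nobs
    cox_snell = 1.0 - math.exp(2.0 * (fit.loglike_null - fit.loglike) / n)
    max_cs = 1.0 - math.exp(2.0 * fit.loglike_null / n)
    if max_cs <= 0:
        return 0.0
    return max(0.0, cox_snell / max_cs)


def pearson_with_ci(x, y, confidence: float = 0.95) -> tuple[float, float, float, float]:
    """Pearson r with Fisher-z CI and two-sided p: returns (r, lo, hi, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 4:
        raise DomainError(f"need at least 4 pairs, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DomainError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("zero variance in an input vector")
    r, p = stats.pearsonr(x, y)
    z = math.atanh(min(max(r, -1 + 1e-15), 1 - 1e-15))
    half = stats.norm.ppf(0.5 + confidence / 2) / math.sqrt(n - 3)
    return float(r), math.tanh(z - half), math.tanh(z + half), float(p)
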