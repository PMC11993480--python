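"""Validation statistics for a scored cohort.

Reproduces the full analysis pipeline used to evaluate a discrete
surgical-quality score against a binary mechanical-complication
outcome: group comparisons (Mann-Whitney U, chi-square, two-proportion
z), uni-/multivariable logistic regression with Wald inference and VIF
collinearity diagnostics, ROC analysis with a Youden-optimal cutoff
mapped back to the score scale, confusion metrics, Hosmer-Lemeshow
calibration, McFadden pseudo-R2 and the likelihood-ratio test, and a
per-score-level observed-vs-predicted calibration table.

Conventions: a LOWER score flags HIGHER complication risk, so the ROC
risk marker is the fitted probability when a model is supplied and the
negated score otherwise; a positive screening call is ``score <=
cutoff``.  All p-values are two-sided and unadjusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.stats.proportion import proportions_ztest
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .cohort import Cohort
from .errors import (
    DomainError,
    GroupingError,
    SeparationError,
    SingularDesignError,
    UndefinedCorrelationError,
)

__all__ = [
    "LogisticFit",
    "RocResult",
    "FitDiagnostics",
    "GroupComparison",
    "ConfusionMetrics",
    "fit_logistic",
    "odds_ratio_transform",
    "vif",
    "roc_analysis",
    "confusion_metrics",
    "hosmer_lemeshow",
    "fit_statistics",
    "group_compare",
    "proportion_z_test",
    "spearman_correlation",
    "calibration_by_score",
    "cohort_report",
]

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class LogisticFit:
    """Converged binary-logistic MLE with Wald inference.

    ``terms`` lists the covariate names; index 0 of every array is the
    intercept.  CIs are 95% Wald intervals (estimate +/- 1.96 SE);
    odds ratios and their CIs are the exponentials.
    """

    terms: Tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    converged: bool
    n_iterations: int
    n_obs: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coefficients)

    @property
    def or_ci_low(self) -> np.ndarray:
        return np.exp(self.ci_low)

    @property
    def or_ci_high(self) -> np.ndarray:
        return np.exp(self.ci_high)

    @property
    def df_model(self) -> int:
        return len(self.terms) - 1

    def coefficient(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        """Fitted complication probabilities for rows of ``frame``."""
        eta = np.full(len(frame), self.coefficients[0], dtype=float)
        for name, beta in zip(self.terms[1:], self.coefficients[1:]):
            eta += beta * frame[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC of a risk marker with the Youden-optimal cutoff."""

    points: np.ndarray  # (1-specificity, sensitivity) pairs, fpr-ascending
    auc: float
    youden_threshold_probability: Optional[float]
    youden_tss_cutoff: int
    sensitivity: float
    specificity: float
    accuracy: float
    youden_j: float


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fn: int
    tn: int
    fp: int


@dataclass(frozen=True)
class FitDiagnostics:
    """Calibration and fit statistics for a logistic model.

    :func:`fit_statistics` fills the likelihood-based fields,
    :func:`hosmer_lemeshow` the ``hl_*`` fields; :func:`cohort_report`
    merges both.
    """

    mcfadden_r2: Optional[float] = None
    lr_statistic: Optional[float] = None
    lr_p: Optional[float] = None
    hosmer_lemeshow_statistic: Optional[float] = None
    hl_df: Optional[int] = None
    hl_p: Optional[float] = None


@dataclass(frozen=True)
class GroupComparison:
    """Two-group test with per-group descriptives."""

    column: str
    kind: str
    statistic: float
    p: float
    summaries: Dict[str, dict] = field(default_factory=dict)
    contingency: Optional[pd.DataFrame] = None
    low_expected_counts: bool = False


def _design_matrix(cohort: Cohort, covariates: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    frame = cohort.frame
    missing = [c for c in covariates if c not in frame.columns]
    if missing:
        raise DomainError(f"covariates not in cohort: {missing}")
    X = frame[list(covariates)].to_numpy(dtype=float)
    y = cohort.outcome
    if len(np.unique(y)) < 2:
        raise DomainError("both outcome classes must be present")
    if np.any(X.std(axis=0) == 0):
        dead = [c for c, s in zip(covariates, X.std(axis=0)) if s == 0]
        raise SingularDesignError(f"zero-variance covariate(s): {dead}")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    return y, Xc


def fit_logistic(cohort: Cohort, covariates: Sequence[str]) -> LogisticFit:
    """Maximum-likelihood binary logistic fit of outcome on ``covariates``.

    Newton-Raphson ascent with standard errors from the observed
    information at the optimum.  Raises :class:`SeparationError` when
    the MLE does not exist (perfectly separated classes) and
    :class:`SingularDesignError` for collinear or constant designs.
    """
    y, Xc = _design_matrix(cohort, covariates)
    model = sm.Logit(y, Xc)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = model.fit(method="newton", maxiter=100, tol=1e-10, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"perfect separation detected: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    if not res.mle_retvals.get("converged", False) or np.any(np.abs(params) > 50):
        raise SeparationError(
            "logistic MLE did not converge to a finite optimum "
            "(quasi-separation or runaway coefficients)"
        )
    bse = np.asarray(res.bse, dtype=float)
    return LogisticFit(
        terms=("const",) + tuple(covariates),
        coefficients=params,
        standard_errors=bse,
        ci_low=params - _Z95 * bse,
        ci_high=params + _Z95 * bse,
        log_likelihood=float(res.llf),
        null_log_likelihood=float(res.llnull),
        converged=True,
        n_iterations=int(res.mle_retvals.get("iterations", 0)),
        n_obs=int(res.nobs),
    )


def odds_ratio_transform(fit: LogisticFit) -> pd.DataFrame:
    """Per-term odds ratios with exp-transformed 95% CIs."""
    if not fit.converged:
        raise DomainError("odds ratios require a converged fit")
    return pd.DataFrame(
        {
            "term": fit.terms,
            "beta": fit.coefficients,
            "se": fit.standard_errors,
            "ci_low": fit.ci_low,
            "ci_high": fit.ci_high,
            "odds_ratio": fit.odds_ratios,
            "or_ci_low": fit.or_ci_low,
            "or_ci_high": fit.or_ci_high,
        }
    )


def vif(cohort: Cohort, covariates: Sequence[str]) -> Dict[str, float]:
    """Variance inflation factors, 1/(1-R2_j), for each covariate.

    Perfectly collinear covariates are reported as ``inf`` rather than
    raised, mirroring the usual diagnostic-table behaviour.
    """
    if len(covariates) < 2:
        raise DomainError("VIF needs at least two covariates")
    frame = cohort.frame
    X = frame[list(covariates)].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        dead = [c for c, s in zip(covariates, X.std(axis=0)) if s == 0]
        raise DomainError(f"zero-variance covariate(s): {dead}")
    Xc = sm.add_constant(X, has_constant="add")
    out: Dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, name in enumerate(covariates):
            value = float(variance_inflation_factor(Xc, j + 1))
            out[name] = np.inf if not np.isfinite(value) else value
    return out


def roc_analysis(
    cohort: Cohort,
    score_column: str = "tss_total",
    fit: Optional[LogisticFit] = None,
) -> RocResult:
    """Empirical ROC of the score (or fitted probability) vs outcome.

    The risk marker is the fitted probability when ``fit`` is given and
    the negated score otherwise; with a monotone-decreasing fit the two
    rankings — hence the AUCs — are identical.  AUC is the trapezoid
    area, equal to the tie-corrected Mann-Whitney concordance
    probability.  The Youden cutoff maximises sensitivity +
    specificity - 1, breaking ties toward the more sensitive (lower
    probability / higher score) threshold, and is reported on the score
    scale as the largest score still called positive.
    """
    y = cohort.outcome
    if len(np.unique(y)) < 2:
        raise DomainError("both outcome classes must be present for ROC analysis")
    score = cohort.frame[score_column].to_numpy(dtype=float)
    if fit is not None:
        risk = fit.predict(cohort.frame)
    else:
        risk = -score
    fpr, tpr, thresholds = roc_curve(y, risk, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    # thresholds descend; the last argmax is the lowest risk threshold,
    # i.e. the most sensitive of the tied cutoffs
    idx = int(np.flatnonzero(j == j.max())[-1])
    threshold = float(thresholds[idx])

    if fit is not None:
        prob_threshold: Optional[float] = threshold
        levels = np.arange(0, 9)
        level_probs = fit.predict(pd.DataFrame({score_column: levels}))
        called = levels[level_probs >= threshold - 1e-12]
        cutoff = int(called.max()) if len(called) else -1
    else:
        prob_threshold = None
        cutoff = int(round(-threshold)) if np.isfinite(threshold) else -1

    cm = confusion_metrics(cohort, cutoff, score_column=score_column)
    return RocResult(
        points=np.column_stack([fpr, tpr]),
        auc=auc,
        youden_threshold_probability=prob_threshold,
        youden_tss_cutoff=cutoff,
        sensitivity=cm.sensitivity,
        specificity=cm.specificity,
        accuracy=cm.accuracy,
        youden_j=float(j[idx]),
    )


def confusion_metrics(
    cohort: Cohort, tss_cutoff: int, score_column: str = "tss_total"
) -> ConfusionMetrics:
    """Sensitivity/specificity/accuracy of the call ``score <= cutoff``."""
    y = cohort.outcome
    if len(np.unique(y)) < 2:
        raise DomainError("both outcome classes must be present")
    score = cohort.frame[score_column].to_numpy(dtype=float)
    positive = score <= tss_cutoff
    tp = int(np.sum(positive & (y == 1)))
    fn = int(np.sum(~positive & (y == 1)))
    tn = int(np.sum(~positive & (y == 0)))
    fp = int(np.sum(positive & (y == 0)))
    return ConfusionMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / len(y),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )


def hosmer_lemeshow(
    cohort: Cohort,
    fit: Optional[LogisticFit] = None,
    n_groups: int = 10,
    probabilities: Optional[np.ndarray] = None,
) -> FitDiagnostics:
    """Hosmer-Lemeshow goodness-of-fit of predicted probabilities.

    Patients are grouped by fitted probability into ``n_groups``
    quantile bins; bins tied on a single discrete prediction collapse
    into one group (on a 9-level score deciles are ill-defined, so the
    effective groups are score levels).  The statistic sums
    (O-E)^2 / (E (1 - E/n_g)) over groups, covering both outcome
    classes; p comes from chi-square with groups - 2 df.

    Predictions come from ``fit`` unless an explicit ``probabilities``
    vector is supplied (e.g. to test an externally calibrated model).
    Only the ``hl_*`` fields of the result are set.
    """
    if n_groups < 2:
        raise GroupingError(f"n_groups must be at least 2, got {n_groups}")
    if probabilities is not None:
        p = np.asarray(probabilities, dtype=float)
        if len(p) != cohort.n:
            raise DomainError("probabilities length must match the cohort size")
    elif fit is not None:
        p = fit.predict(cohort.frame)
    else:
        raise DomainError("either a fit or a probabilities vector is required")
    y = cohort.outcome
    distinct = np.unique(np.round(p, 12))
    if len(distinct) < 3:
        raise GroupingError(
            f"only {len(distinct)} distinct predicted probabilities; "
            "reduce n_groups or refit with a richer covariate"
        )
    bins = pd.qcut(p, q=min(n_groups, len(distinct)), duplicates="drop")
    table = pd.DataFrame({"y": y, "p": p, "bin": bins}).groupby("bin", observed=True)
    stat = 0.0
    n_used = 0
    for _, g in table:
        n_g = len(g)
        if n_g == 0:
            continue
        observed = float(g["y"].sum())
        expected = float(g["p"].sum())
        denom = expected * (1.0 - expected / n_g)
        if denom <= 0:
            continue
        stat += (observed - expected) ** 2 / denom
        n_used += 1
    df = n_used - 2
    if df < 1:
        raise GroupingError("fewer than 3 usable groups after collapsing ties")
    return FitDiagnostics(
        hosmer_lemeshow_statistic=float(stat),
        hl_df=int(df),
        hl_p=float(stats.chi2.sf(stat, df)),
    )


def fit_statistics(fit: LogisticFit) -> FitDiagnostics:
    """McFadden pseudo-R2 and the likelihood-ratio test vs the null model."""
    if not fit.converged:
        raise DomainError("fit statistics require a converged fit")
    mcfadden = 1.0 - fit.log_likelihood / fit.null_log_likelihood
    lr = 2.0 * (fit.log_likelihood - fit.null_log_likelihood)
    lr = max(lr, 0.0)
    return FitDiagnostics(
        mcfadden_r2=float(mcfadden),
        lr_statistic=float(lr),
        lr_p=float(stats.chi2.sf(lr, fit.df_model)) if fit.df_model else 1.0,
    )


def _describe(x: np.ndarray) -> dict:
    return {
        "n": int(len(x)),
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "median": float(np.median(x)),
    }


def group_compare(cohort: Cohort, column: str, kind: str) -> GroupComparison:
    """Compare a column between complication and non-complication groups.

    ``kind='continuous'`` runs the Mann-Whitney U test (normal
    approximation with continuity and tie correction) and returns
    per-group descriptives; ``kind='categorical'`` runs the Pearson
    chi-square test on the outcome-by-level table, flagging low
    expected counts rather than failing.
    """
    comp, noncomp = cohort.split_by_outcome()
    if len(comp) == 0 or len(noncomp) == 0:
        raise DomainError("both outcome groups must be non-empty")
    if kind == "continuous":
        x = comp[column].to_numpy(dtype=float)
        y = noncomp[column].to_numpy(dtype=float)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return GroupComparison(
            column=column,
            kind=kind,
            statistic=float(res.statistic),
            p=float(res.pvalue),
            summaries={"complication": _describe(x), "non_complication": _describe(y)},
        )
    if kind == "categorical":
        table = pd.crosstab(cohort.frame["outcome"], cohort.frame[column])
        table = table.loc[:, table.sum(axis=0) > 0]
        chi2, p, _, expected = stats.chi2_contingency(table)
        return GroupComparison(
            column=column,
            kind=kind,
            statistic=float(chi2),
            p=float(p),
            contingency=table,
            low_expected_counts=bool(np.min(expected) < 5),
        )
    raise DomainError(f"kind must be 'continuous' or 'categorical', got {kind!r}")


def proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> Tuple[float, float]:
    """Pooled two-proportion z-test, two-sided."""
    if n1 <= 0 or n2 <= 0:
        raise DomainError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise DomainError("event counts must lie in [0, n] for each group")
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def spearman_correlation(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) != len(x):
        raise DomainError("need two equal-length vectors with at least 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def calibration_by_score(
    cohort: Cohort,
    fit: LogisticFit,
    score_column: str = "tss_total",
) -> pd.DataFrame:
    """Observed vs model-predicted complication rate per score level.

    One row per score level 0-8: patient count, observed complication
    fraction, and mean fitted probability.  Levels absent from the
    cohort are flagged (``present=False``); their predicted rate is the
    model value when the fit is the single-covariate score model, never
    a fabricated observation.
    """
    frame = cohort.frame
    p = fit.predict(frame)
    rows: List[dict] = []
    single = fit.terms == ("const", score_column)
    for level in range(9):
        mask = frame[score_column].to_numpy(dtype=int) == level
        n = int(mask.sum())
        if n > 0:
            observed = float(frame.loc[mask, "outcome"].mean())
            predicted = float(p[mask].mean())
        else:
            observed = np.nan
            predicted = (
                float(fit.predict(pd.DataFrame({score_column: [level]}))[0])
                if single
                else np.nan
            )
        rows.append(
            {
                "tss_total": level,
                "n": n,
                "present": n > 0,
                "observed_rate": observed,
                "predicted_rate": predicted,
            }
        )
    return pd.DataFrame(rows)


def cohort_report(
    cohort: Cohort,
    hl_groups: int = 10,
    cutoff: Optional[int] = None,
    score_column: str = "tss_total",
) -> dict:
    """Run the whole validation battery on a scored cohort.

    Returns a plain nested dict (JSON-ready): cohort summary, the
    Mann-Whitney group comparison of the total score, the per-point
    logistic fit with odds ratios, ROC/Youden analysis, confusion
    metrics at the Youden (or overridden) cutoff, fit and calibration
    diagnostics, per-sub-score Spearman correlations with outcome, and
    the per-level calibration table.
    """
    from .scoring import SUBSCORE_FIELDS  # local to avoid cycle at import

    fit = fit_logistic(cohort, [score_column])
    compare = group_compare(cohort, score_column, kind="continuous")
    roc = roc_analysis(cohort, score_column, fit=fit)
    used_cutoff = roc.youden_tss_cutoff if cutoff is None else int(cutoff)
    cm = confusion_metrics(cohort, used_cutoff, score_column=score_column)
    likelihood = fit_statistics(fit)
    hl = hosmer_lemeshow(cohort, fit, n_groups=hl_groups)
    calibration = calibration_by_score(cohort, fit, score_column=score_column)
    spearman = {}
    for name in SUBSCORE_FIELDS:
        rho, p = spearman_correlation(
            cohort.frame[name].to_numpy(dtype=float), cohort.outcome
        )
        spearman[name] = {"rho": rho, "p": p}

    or_table = odds_ratio_transform(fit)
    return {
        "cohort": {
            "n": cohort.n,
            "n_complication": int(cohort.outcome.sum()),
            "prevalence": cohort.prevalence,
        },
        "group_comparison": {
            "test": "mann_whitney_u",
            "statistic": compare.statistic,
            "p": compare.p,
            "summaries": compare.summaries,
        },
        "logistic_fit": {
            "terms": list(fit.terms),
            "coefficients": fit.coefficients.tolist(),
            "standard_errors": fit.standard_errors.tolist(),
            "ci_low": fit.ci_low.tolist(),
            "ci_high": fit.ci_high.tolist(),
            "odds_ratios": or_table["odds_ratio"].tolist(),
            "or_ci_low": or_table["or_ci_low"].tolist(),
            "or_ci_high": or_table["or_ci_high"].tolist(),
            "log_likelihood": fit.log_likelihood,
            "null_log_likelihood": fit.null_log_likelihood,
            "n_iterations": fit.n_iterations,
        },
        "roc": {
            "auc": roc.auc,
            "youden_j": roc.youden_j,
            "youden_threshold_probability": roc.youden_threshold_probability,
            "youden_tss_cutoff": roc.youden_tss_cutoff,
        },
        "confusion_at_cutoff": {
            "cutoff": used_cutoff,
            "sensitivity": cm.sensitivity,
            "specificity": cm.specificity,
            "accuracy": cm.accuracy,
            "tp": cm.tp,
            "fn": cm.fn,
            "tn": cm.tn,
            "fp": cm.fp,
        },
        "fit_diagnostics": {
            "mcfadden_r2": likelihood.mcfadden_r2,
            "lr_statistic": likelihood.lr_statistic,
            "lr_p": likelihood.lr_p,
            "hosmer_lemeshow_statistic": hl.hosmer_lemeshow_statistic,
            "hl_df": hl.hl_df,
            "hl_p": hl.hl_p,
        },
        "spearman": spearman,
        "calibration_by_score": calibration.to_dict(orient="records"),
    }
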