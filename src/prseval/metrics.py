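"""Case-control and age-at-onset discrimination statistics.

Logistic regression with Wald tests (statsmodels MLE behind
:func:`fit_logistic`), Nagelkerke's pseudo-R², ROC curves and AUC with
DeLong 95% confidence intervals, decile odds ratios against the lowest
control-score decile, and the early- vs late-onset quartile analysis.

The AUC is the Mann-Whitney statistic scaled to [0, 1] with ties counted
1/2 — the probability that a random case scores above a random control.
Its variance is estimated with DeLong's structural-components method, the
same nonparametric machinery pROC uses for its default CIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io import Cohort

__all__ = [
    "LogisticFit",
    "RocCurve",
    "AucEstimate",
    "DecileOrTable",
    "AaoQuartileResult",
    "fit_logistic",
    "nagelkerke_r2",
    "roc_curve",
    "auc_delong",
    "roc_and_auc",
    "decile_or",
    "aao_quartile_analysis",
    "case_control_analysis",
]


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge (e.g. separation)."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit with Wald inference."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    llf: float
    n: int

    def __post_init__(self) -> None:
        if (self.bse <= 0).any():
            raise ValueError("standard errors must be positive")
        if self.llf > 1e-9:
            raise ValueError("log-likelihood of a Bernoulli model must be <= 0")


@dataclass
class RocCurve:
    """Threshold-wise sensitivity/specificity.

    Thresholds are midpoints between consecutive distinct scores with
    -inf/+inf sentinels; an individual is test-positive when their score
    strictly exceeds the threshold. Sorted by ascending threshold, so
    sensitivity is non-increasing and specificity non-decreasing, with
    endpoints (sens, spec) = (1, 0) and (0, 1).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray


@dataclass
class AucEstimate:
    auc: float
    ci_low: float
    ci_high: float
    method: str = "delong"

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.auc <= self.ci_high <= 1):
            raise ValueError("require 0 <= ci_low <= auc <= ci_high <= 1")


@dataclass
class DecileOrTable:
    """Odds ratios for control-score deciles 2..10 vs decile 1.

    ``table`` columns: decile (2..10), n_case, n_control, odds_ratio,
    ci_low, ci_high (Wald 95%). ``boundaries`` are the nine control-score
    quantile cut points; reference-decile counts are stored separately.
    """

    table: pd.DataFrame
    boundaries: np.ndarray
    ref_case: int
    ref_control: int
    covariate_adjusted: bool = False  # plain 2x2 ORs, not model-adjusted


def fit_logistic(outcome: np.ndarray, design: pd.DataFrame) -> LogisticFit:
    """Fit a logistic regression by Newton-type IRLS.

    ``design`` must already contain an intercept column if one is wanted.
    Raises :class:`ConvergenceError` on separation or non-convergence,
    naming the most suspect covariate.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X = design.astype(float)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-10)
    except Exception as exc:
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        worst = res.params.abs().idxmax()
        raise ConvergenceError(
            f"logistic fit did not converge; covariate {worst!r} is the likely culprit "
            "(possible separation)"
        )
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        zvalues=res.tvalues,
        pvalues=res.pvalues,
        llf=float(res.llf),
        n=int(res.nobs),
    )


def nagelkerke_r2(full: LogisticFit, null: LogisticFit) -> float:
    """Nagelkerke's pseudo-R²: Cox-Snell R² rescaled by its maximum.

    R²_CS = 1 - exp(2(l0 - l1)/n), divided by 1 - exp(2*l0/n).
    """
    if full.n != null.n:
        raise ValueError("full and null fits must share the same sample")
    l1, l0, n = full.llf, null.llf, full.n
    if l1 < l0 - 1e-8:
        raise ValueError("null model is not nested in the full model (l1 < l0)")
    cox_snell = 1.0 - np.exp(2.0 * (l0 - l1) / n)
    max_cs = 1.0 - np.exp(2.0 * l0 / n)
    return float(cox_snell / max_cs)


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve over all distinct-score midpoint thresholds."""
    scores, labels = _check_scores_labels(scores, labels)
    cases = np.sort(scores[labels == 1])
    controls = np.sort(scores[labels == 0])
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    # positive test: score strictly above threshold
    sens = 1.0 - np.searchsorted(cases, thresholds, side="right") / len(cases)
    spec = np.searchsorted(controls, thresholds, side="right") / len(controls)
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec)


def _delong_components(case_scores, control_scores):
    """DeLong structural components V10 (per case) and V01 (per control)."""
    m, n = len(case_scores), len(control_scores)
    both = np.concatenate([case_scores, control_scores])
    r_all = stats.rankdata(both)
    r_case = stats.rankdata(case_scores)
    r_ctrl = stats.rankdata(control_scores)
    v10 = (r_all[:m] - r_case) / n
    v01 = 1.0 - (r_all[m:] - r_ctrl) / m
    return v10, v01


def auc_delong(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> AucEstimate:
    """AUC (ties 1/2) with a DeLong normal-approximation CI."""
    scores, labels = _check_scores_labels(scores, labels)
    v10, v01 = _delong_components(scores[labels == 1], scores[labels == 0])
    auc = float(np.mean(v10))
    var = 0.0
    if len(v10) > 1:
        var += np.var(v10, ddof=1) / len(v10)
    if len(v01) > 1:
        var += np.var(v01, ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return AucEstimate(
        auc=auc,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
    )


def roc_and_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[RocCurve, AucEstimate]:
    """ROC curve and AUC with DeLong 95% CI for binary labels."""
    return roc_curve(scores, labels), auc_delong(scores, labels)


def decile_or(scores: np.ndarray, labels: np.ndarray) -> DecileOrTable:
    """Disease odds ratios across control-score deciles.

    Cut points are the control-score quantiles at 10%..90% (linear
    interpolation); everyone is binned by them, ties at a boundary going
    to the lower decile. OR_k = (case_k * control_1)/(case_1 * control_k)
    with Wald 95% CI exp(log OR +- 1.96 * sqrt(sum of reciprocal cells)).
    """
    scores, labels = _check_scores_labels(scores, labels)
    controls = scores[labels == 0]
    if len(controls) < 10:
        raise ValueError("need at least 10 controls for decile cut points")
    cuts = np.quantile(controls, np.arange(1, 10) / 10.0)
    bins = np.searchsorted(cuts, scores, side="left")
    n_case = np.bincount(bins[labels == 1], minlength=10)
    n_ctrl = np.bincount(bins[labels == 0], minlength=10)
    if (n_case == 0).any() or (n_ctrl == 0).any():
        raise ValueError(
            "empty decile cell: odds ratios undefined (continuity corrections are "
            "out of scope)"
        )
    a1, b1 = n_case[0], n_ctrl[0]
    rows = []
    for k in range(1, 10):
        ak, bk = n_case[k], n_ctrl[k]
        log_or = np.log(ak * b1 / (a1 * bk))
        se = np.sqrt(1 / ak + 1 / bk + 1 / a1 + 1 / b1)
        rows.append(
            (k + 1, ak, bk, np.exp(log_or),
             np.exp(log_or - 1.96 * se), np.exp(log_or + 1.96 * se))
        )
    table = pd.DataFrame(
        rows, columns=["decile", "n_case", "n_control", "odds_ratio", "ci_low", "ci_high"]
    )
    return DecileOrTable(
        table=table, boundaries=cuts, ref_case=int(a1), ref_control=int(b1)
    )


@dataclass
class AaoQuartileResult:
    """Early- vs late-onset discrimination among cases."""

    fit: LogisticFit
    roc: RocCurve
    auc: AucEstimate
    q1_cut: float
    q3_cut: float
    n_early: int
    n_late: int


def aao_quartile_analysis(
    cohort: Cohort, standardized_scores: np.ndarray
) -> AaoQuartileResult:
    """Discriminate earliest- from latest-onset cases with the score.

    Cases are split at the age-at-onset quartiles; only the first
    (AAO <= Q1) and fourth (AAO > Q3) quartiles are retained. Quartile
    membership (1 = early onset) is regressed on the score, sex and
    PC1-3 — age-at-sampling is deliberately excluded — and the score's
    ROC/AUC for early vs late onset is computed.
    """
    scores = np.asarray(standardized_scores, dtype=float)
    case_mask = cohort.is_case
    aao = cohort.samples["age_at_onset"].to_numpy()[case_mask]
    if np.sum(np.isfinite(aao)) < 8:
        raise ValueError("need >= 8 cases with an age-at-onset")
    q1, q3 = np.nanquantile(aao, [0.25, 0.75])
    early = aao <= q1
    late = aao > q3
    keep = early | late
    sub = cohort.samples[case_mask].loc[keep]
    s = scores[case_mask][keep]
    y = early[keep].astype(float)
    design = pd.DataFrame(
        {
            "const": 1.0,
            "prs": s,
            "sex": sub["sex"].to_numpy(dtype=float),
            "PC1": sub["PC1"].to_numpy(),
            "PC2": sub["PC2"].to_numpy(),
            "PC3": sub["PC3"].to_numpy(),
        }
    )
    fit = fit_logistic(y, design)
    roc, auc = roc_and_auc(s, y.astype(int))
    return AaoQuartileResult(
        fit=fit, roc=roc, auc=auc,
        q1_cut=float(q1), q3_cut=float(q3),
        n_early=int(early.sum()), n_late=int(late.sum()),
    )


def case_control_analysis(
    cohort: Cohort, standardized_scores: np.ndarray
) -> dict:
    """Headline case-control validation of a standardized score.

    Fits status ~ score + sex + age_at_sampling + PC1-3 and the same
    model without the score, and returns the score's ROC/AUC with
    DeLong CI, both Nagelkerke pseudo-R² values, and the score's Wald p.
    """
    scores = np.asarray(standardized_scores, dtype=float)
    y = cohort.is_case.astype(float)
    base = {
        "const": 1.0,
        "sex": cohort.samples["sex"].to_numpy(dtype=float),
        "age_at_sampling": cohort.samples["age_at_sampling"].to_numpy(),
        "PC1": cohort.samples["PC1"].to_numpy(),
        "PC2": cohort.samples["PC2"].to_numpy(),
        "PC3": cohort.samples["PC3"].to_numpy(),
    }
    full = fit_logistic(
        y,
        pd.DataFrame(
            {"const": 1.0, "prs": scores,
             **{k: v for k, v in base.items() if k != "const"}}
        ),
    )
    covars_only = fit_logistic(y, pd.DataFrame(base))
    intercept_only = fit_logistic(y, pd.DataFrame({"const": np.ones_like(y)}))
    roc, auc = roc_and_auc(scores, cohort.is_case.astype(int))
    return {
        "n": len(cohort),
        "roc": roc,
        "auc": auc,
        "fit_full": full,
        "fit_null": covars_only,
        "r2_with_prs": nagelkerke_r2(full, intercept_only),
        "r2_without_prs": nagelkerke_r2(covars_only, intercept_only),
        "prs_p_value": float(full.pvalues["prs"]),
        "prs_log_or_per_sd": float(full.params["prs"]),
    }


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    uniq = set(np.unique(labels).tolist())
    if uniq != {0, 1}:
        raise ValueError("labels must contain both classes coded 0/1")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    return scores, labels
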