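"""Theoretical prognostic value of a risk score.

A score threshold turns the PRS into a screening test. The operating
point is chosen by maximizing a weighted Youden index,

    costs * sensitivity + specificity,

where ``costs`` >= 1 is the relative severity of a false negative versus
a false positive; the grid 1 … 5 in steps of 1e-4 traces the full
trade-off. Predictive values follow from Bayes' formula with the
*residual lifetime incidence* in place of prevalence: the probability
that a currently disease-free individual of a given age develops the
disease before death. For 5-year age intervals with interval incidence
I and annual death probability D (interval survival S = (1 - D)^5), the
residual incidence accumulates over later intervals, each discounted by
all earlier survival and disease-free factors; it is evaluated by the
equivalent backward recursion

    R_last = I_last,    R_k = I_k + S_k * (1 - I_k) * R_{k+1},

with the open-ended terminal interval contributing its incidence once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LifeTable
from .metrics import RocCurve

__all__ = [
    "CostGridResult",
    "ResidualIncidence",
    "PredictiveValueTable",
    "weighted_youden_threshold",
    "cost_grid",
    "residual_lifetime_incidence",
    "predictive_values",
    "prognosis_report",
]


@dataclass
class CostGridResult:
    """Optimal operating point per cost value.

    ``table`` columns: costs, threshold, sensitivity, specificity,
    objective (= costs * sens + spec at the optimum). Sensitivity is
    non-decreasing and specificity non-increasing in costs.
    """

    table: pd.DataFrame


@dataclass
class ResidualIncidence:
    """Residual lifetime incidence per starting age interval.

    ``table`` columns: interval, age_start, survival (S = (1-D)^5),
    residual_incidence (probability of disease onset before death from
    that interval onwards).
    """

    table: pd.DataFrame

    @property
    def values(self) -> np.ndarray:
        return self.table["residual_incidence"].to_numpy()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.table["interval"])


@dataclass
class PredictiveValueTable:
    """ppv/npv per age group x cost level (columns are a MultiIndex of
    (costs, 'ppv'|'npv'); rows are age-interval labels)."""

    table: pd.DataFrame
    operating_points: pd.DataFrame


def weighted_youden_threshold(
    roc: RocCurve, costs: float
) -> tuple[float, float, float]:
    """Curve point maximizing costs * sensitivity + specificity.

    Ties are broken toward higher sensitivity (lower threshold).
    Returns (threshold, sensitivity, specificity).
    """
    if costs < 1:
        raise ValueError("costs must be >= 1 (false negatives at least as severe)")
    if roc.thresholds.size == 0:
        raise ValueError("empty ROC curve")
    obj = costs * roc.sensitivity + roc.specificity
    # thresholds ascend, sensitivity descends: first argmax = highest sens
    i = int(np.argmax(obj))
    return (
        float(roc.thresholds[i]),
        float(roc.sensitivity[i]),
        float(roc.specificity[i]),
    )


def cost_grid(
    roc: RocCurve,
    c_min: float = 1.0,
    c_max: float = 5.0,
    step: float = 0.0001,
    chunk: int = 1024,
) -> CostGridResult:
    """Optimal operating point at every grid cost, endpoints inclusive.

    Grid values are generated by integer indexing (c_min + i * step) to
    avoid floating-point drift over the 40001-point default grid. The
    argmax is exhaustive over all curve points, evaluated in chunks.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((c_max - c_min) / step))
    costs = c_min + np.arange(n + 1) * step
    sens, spec, thr = roc.sensitivity, roc.specificity, roc.thresholds
    out_i = np.empty(costs.size, dtype=np.int64)
    for lo in range(0, costs.size, chunk):
        block = costs[lo : lo + chunk]
        obj = block[:, None] * sens[None, :] + spec[None, :]
        out_i[lo : lo + block.size] = np.argmax(obj, axis=1)
    table = pd.DataFrame(
        {
            "costs": costs,
            "threshold": thr[out_i],
            "sensitivity": sens[out_i],
            "specificity": spec[out_i],
            "objective": costs * sens[out_i] + spec[out_i],
        }
    )
    if np.any(np.diff(table["sensitivity"].to_numpy()) < 0) or np.any(
        np.diff(table["specificity"].to_numpy()) > 0
    ):
        raise AssertionError(
            "cost-grid monotonicity violated: sensitivity must be non-decreasing "
            "and specificity non-increasing in costs"
        )
    return CostGridResult(table=table)


def residual_lifetime_incidence(table: LifeTable) -> ResidualIncidence:
    """Residual lifetime incidence for every starting interval.

    Backward recursion over the ten 5-year intervals; the terminal
    [95+] interval contributes its incidence once with no further
    survival weighting.
    """
    inc = table.incidence
    death = table.annual_death_rate
    surv = (1.0 - death) ** 5
    k = len(inc)
    resid = np.empty(k)
    resid[-1] = inc[-1]
    for i in range(k - 2, -1, -1):
        resid[i] = inc[i] + surv[i] * (1.0 - inc[i]) * resid[i + 1]
    out = table.intervals[["interval", "age_start"]].copy()
    out["survival"] = surv
    out["residual_incidence"] = resid
    return ResidualIncidence(table=out)


def predictive_values(
    sensitivity: float | np.ndarray,
    specificity: float | np.ndarray,
    incidence: float | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Bayes positive and negative predictive values.

    ``incidence`` is the pre-test disease probability — here the
    residual lifetime incidence of the age group. Degenerate 0/0
    denominators yield nan (undefined), never 0. Scalars broadcast.
    """
    sens = np.asarray(sensitivity, dtype=float)
    spec = np.asarray(specificity, dtype=float)
    p = np.asarray(incidence, dtype=float)
    for name, a in (("sensitivity", sens), ("specificity", spec), ("incidence", p)):
        if np.any((a < 0) | (a > 1) | ~np.isfinite(a)):
            raise ValueError(f"{name} must lie in [0, 1]")
    pos = sens * p
    ppv_den = pos + (1.0 - spec) * (1.0 - p)
    neg = spec * (1.0 - p)
    npv_den = neg + (1.0 - sens) * p
    with np.errstate(invalid="ignore", divide="ignore"):
        ppv = np.where(ppv_den > 0, pos / np.where(ppv_den > 0, ppv_den, 1.0), np.nan)
        npv = np.where(npv_den > 0, neg / np.where(npv_den > 0, npv_den, 1.0), np.nan)
    return ppv, npv


def prognosis_report(
    grid: CostGridResult,
    residual: ResidualIncidence,
    costs: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0),
) -> PredictiveValueTable:
    """Age-group x cost-level table of predictive values.

    For each requested cost level the grid's operating point supplies
    (sensitivity, specificity); each age group's residual lifetime
    incidence supplies the pre-test probability.
    """
    g = grid.table
    rows = []
    for c in costs:
        i = np.flatnonzero(np.isclose(g["costs"].to_numpy(), c, atol=1e-9))
        if i.size == 0:
            raise ValueError(f"cost level {c} not present in the grid")
        rows.append(g.iloc[i[0]])
    ops = pd.DataFrame(rows).reset_index(drop=True)
    p = residual.values
    data = {}
    for _, op in ops.iterrows():
        ppv, npv = predictive_values(op["sensitivity"], op["specificity"], p)
        data[(op["costs"], "ppv")] = ppv
        data[(op["costs"], "npv")] = npv
    table = pd.DataFrame(data, index=list(residual.labels))
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["costs", "value"])
    return PredictiveValueTable(table=table, operating_points=ops)
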