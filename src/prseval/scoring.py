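"""Polygenic risk score computation.

Score variants are matched to the genotype panel by (chromosome,
position), requiring that the weight table's allele pair equals the
panel's {ref, alt} as a set, and filtered on minor-allele frequency and
(when available) imputation info score. The raw score for an individual
is

    PRS_i = sum_j w_j * d_ij

over matched variants, where ``d_ij`` is the dosage of the *effect*
allele: the panel's alt dosage when the effect allele is alt, and
``2 - dosage`` when it is ref. Scores are standardized to zero mean and
unit (sample) standard deviation among controls; the stored parameters
can be re-applied to new individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort, DosagePanel, VariantWeightTable

__all__ = [
    "MatchReport",
    "StandardizedScore",
    "match_variants",
    "effect_allele_dosages",
    "contribution_matrix",
    "compute_prs",
    "standardize",
]

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class MatchReport:
    """Outcome of matching score variants to a dosage panel.

    ``matched`` columns: weight_index, panel_index, chrom, pos, weight,
    orientation ('alt' if the effect allele is the panel alt, else
    'ref'), strand_ambiguous. ``omitted`` columns: weight_index, chrom,
    pos, reason (absent | allele-mismatch | maf-filtered | info-filtered).
    """

    matched: pd.DataFrame
    omitted: pd.DataFrame

    @property
    def n_requested(self) -> int:
        return len(self.matched) + len(self.omitted)

    @property
    def n_matched(self) -> int:
        return len(self.matched)

    @property
    def n_omitted(self) -> int:
        return len(self.omitted)


@dataclass
class StandardizedScore:
    """Raw and control-standardized scores with the standardization
    parameters (control mean and sample SD of the raw score)."""

    raw: np.ndarray
    standardized: np.ndarray
    control_mean: float
    control_sd: float

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Apply the stored parameters to new raw scores."""
        return (np.asarray(raw, dtype=float) - self.control_mean) / self.control_sd


def match_variants(
    weights: VariantWeightTable,
    panel: DosagePanel,
    maf_min: float = 0.01,
    info_min: float = 0.7,
) -> MatchReport:
    """Match score variants to the panel and record omissions.

    A variant matches iff its (chrom, pos) is present in the panel, its
    allele pair equals the panel's {ref, alt}, its panel MAF is at least
    ``maf_min`` and — when the panel carries an ``info`` column — its
    info score is at least ``info_min``. Strand-ambiguous (A/T, C/G)
    pairs are matched as-is with a warning; no frequency-based flipping
    is attempted. Unmatched variants are reported, never fatal.
    """
    site_index = {
        (c, p): j
        for j, (c, p) in enumerate(
            zip(panel.variants["chrom"], panel.variants["pos"])
        )
    }
    freqs = panel.alt_frequencies()
    info = (
        panel.variants["info"].to_numpy(dtype=float)
        if "info" in panel.variants.columns
        else None
    )
    matched_rows, omitted_rows = [], []
    n_ambiguous = 0
    for i, row in weights.variants.iterrows():
        key = (row["chrom"], row["pos"])
        j = site_index.get(key)
        if j is None:
            omitted_rows.append((i, *key, "absent"))
            continue
        ref = panel.variants["ref"].iat[j]
        alt = panel.variants["alt"].iat[j]
        pair = {row["effect_allele"], row["other_allele"]}
        if pair != {ref, alt}:
            omitted_rows.append((i, *key, "allele-mismatch"))
            continue
        f = freqs[j]
        maf = min(f, 1.0 - f) if np.isfinite(f) else np.nan
        if np.isfinite(maf) and maf < maf_min:
            omitted_rows.append((i, *key, "maf-filtered"))
            continue
        if info is not None and info[j] < info_min:
            omitted_rows.append((i, *key, "info-filtered"))
            continue
        ambiguous = pair in _AMBIGUOUS
        n_ambiguous += ambiguous
        orientation = "alt" if row["effect_allele"] == alt else "ref"
        matched_rows.append(
            (i, j, *key, row["weight"], orientation, ambiguous)
        )
    if n_ambiguous:
        warnings.warn(
            f"{n_ambiguous} strand-ambiguous (A/T or C/G) variant(s) matched as-is; "
            "verify strand alignment of the weight table",
            stacklevel=2,
        )
    matched = pd.DataFrame(
        matched_rows,
        columns=[
            "weight_index", "panel_index", "chrom", "pos",
            "weight", "orientation", "strand_ambiguous",
        ],
    )
    omitted = pd.DataFrame(
        omitted_rows, columns=["weight_index", "chrom", "pos", "reason"]
    )
    return MatchReport(matched=matched, omitted=omitted)


def effect_allele_dosages(
    panel: DosagePanel,
    match: MatchReport,
    cohort: Cohort | None = None,
    missing_policy: str = "mean",
) -> np.ndarray:
    """Orientation-corrected effect-allele dosage matrix for the matched
    variants (individuals x matched variants).

    Missing dosages are handled per ``missing_policy``: ``"mean"``
    substitutes twice the effect-allele frequency — computed among the
    cohort's controls if a cohort is supplied, otherwise panel-wide —
    and ``"drop"`` sets the variant's contribution to zero for that
    individual.
    """
    if missing_policy not in ("mean", "drop"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    cols = match.matched["panel_index"].to_numpy()
    d = panel.dosages[:, cols].copy()
    flip = (match.matched["orientation"] == "ref").to_numpy()
    d[:, flip] = 2.0 - d[:, flip]
    nan_mask = np.isnan(d)
    if nan_mask.any():
        if missing_policy == "drop":
            d[nan_mask] = 0.0
        else:
            if cohort is not None:
                rows = ~cohort.is_case
                ref_block = d[rows]
            else:
                ref_block = d
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fill = np.nanmean(ref_block, axis=0)
            fill = np.where(np.isnan(fill), 0.0, fill)
            d[nan_mask] = np.broadcast_to(fill, d.shape)[nan_mask]
    return d


def contribution_matrix(
    panel: DosagePanel,
    match: MatchReport,
    cohort: Cohort | None = None,
    missing_policy: str = "mean",
) -> np.ndarray:
    """Per-variant score contributions w_j * d_ij (individuals x matched
    variants); the raw PRS is its row sum."""
    d = effect_allele_dosages(panel, match, cohort, missing_policy)
    return d * match.matched["weight"].to_numpy()


def compute_prs(
    panel: DosagePanel,
    weights: VariantWeightTable,
    match: MatchReport,
    cohort: Cohort | None = None,
    missing_policy: str = "mean",
) -> np.ndarray:
    """Raw PRS per individual over the matched variant set."""
    if match.n_matched == 0:
        raise ValueError("no matched variants: cannot compute a score")
    return contribution_matrix(panel, match, cohort, missing_policy).sum(axis=1)


def standardize(raw: np.ndarray, cohort: Cohort) -> StandardizedScore:
    """Standardize raw scores against the cohort's controls.

    Subtracts the control mean and divides by the control sample SD
    (n-1 denominator); the parameters are stored for reuse.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape[0] != len(cohort):
        raise ValueError("score vector and cohort sizes differ")
    controls = raw[~cohort.is_case]
    if len(np.unique(controls)) < 2:
        raise ValueError("need >= 2 controls with distinct raw scores")
    mean = float(np.mean(controls))
    sd = float(np.std(controls, ddof=1))
    if sd == 0.0:
        raise ValueError("control standard deviation is zero")
    return StandardizedScore(
        raw=raw,
        standardized=(raw - mean) / sd,
        control_mean=mean,
        control_sd=sd,
    )
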