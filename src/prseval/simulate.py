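"""Synthetic genotype, phenotype, weight-table and life-table generation.

The generator produces data with exactly the statistical structure the
downstream analysis assumes, so every stage can be tested against known
ground truth:

* genotypes are independent Hardy-Weinberg allele-count draws (dosage =
  Binomial(2, MAF)), optionally blurred with truncated Gaussian noise to
  mimic imputed dosages;
* disease status follows a logistic model whose linear predictor
  combines the *standardized true score* (per-SD log-odds
  ``prs_effect``), sex and age at sampling; the intercept is calibrated
  by quadrature so the population case fraction matches the requested
  case:control ratio;
* age-at-onset for cases is Gaussian around ``aao_mean`` with a negative
  slope on the standardized score (higher genetic burden, earlier
  onset);
* the default life table mimics registry-style age-specific disease
  incidence and death rates for a late-onset neurodegenerative disease,
  yielding a residual lifetime incidence of ~1.7% at age 50.

One global seed fans out to per-stage child seeds, so stages can be
regenerated independently and identical seeds give bit-identical output.
No linkage disequilibrium, population structure or relatedness is
simulated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special

from .io import (
    LIFE_TABLE_LABELS,
    Cohort,
    DosagePanel,
    LifeTable,
    VariantWeightTable,
    write_cohort,
    write_dosages,
    write_life_table,
    write_weights,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "generate_genotypes",
    "generate_weight_table",
    "generate_cohort",
    "generate_life_table",
    "calibrate_intercept",
    "expected_case_fraction",
    "simulate_case_control_study",
    "write_study",
    "DEFAULT_INCIDENCE",
    "DEFAULT_ANNUAL_DEATH",
]

# Default age-interval profiles for the packaged life table ([50-54] ... [95+]).
# Interval disease-onset probabilities rise to a plateau around 80 and fall in
# the oldest groups (registry-style incidence for a late-onset disease);
# annual death probabilities follow an all-cause mortality-like gradient.
DEFAULT_INCIDENCE = (
    0.0003, 0.0006, 0.0011, 0.0019, 0.0030,
    0.0043, 0.0050, 0.0050, 0.0040, 0.0030,
)
DEFAULT_ANNUAL_DEATH = (
    0.004, 0.006, 0.009, 0.014, 0.022,
    0.035, 0.060, 0.100, 0.170, 0.280,
)

_NON_AMBIGUOUS_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)


@dataclass
class SimulationConfig:
    """Study-design parameters for a synthetic case-control cohort.

    Defaults mirror the shape of a replication study of a published
    Parkinson's disease score: 1743 SNPs, 1914 cases, 4464 controls, a
    per-SD log-odds of 0.60 on the true score (case-control AUC ~= 0.65)
    and an onset-age slope of -1.3 years per score SD (early- vs
    late-onset quartile AUC ~= 0.59).
    """

    n_cases: int = 1914
    n_controls: int = 4464
    n_snps: int = 1743
    maf_range: tuple[float, float] = (0.05, 0.5)
    weight_mean: float = 0.0
    weight_sd: float = 0.03
    large_effect_fraction: float = 0.027  # ~47/1743 genome-wide significant SNPs
    large_effect_sd: float = 0.12
    prs_effect: float = 0.60  # log-odds per SD of the true score
    intercept: float | None = None  # None -> calibrated to the case fraction
    sex_effect: float = 0.35  # log-odds, male vs female
    age_effect: float = 0.05  # log-odds per year of age at sampling
    age_range: tuple[float, float] = (50.0, 85.0)
    aao_mean: float = 62.0
    aao_sd: float = 10.0
    aao_prs_slope: float = -1.3  # years per SD of the true score
    dosage_noise: float = 0.0  # SD of optional imputation-style noise
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("weight_sd", "large_effect_sd", "aao_sd", "dosage_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.large_effect_fraction <= 1.0):
            raise ValueError("large_effect_fraction must lie in [0, 1]")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range must be increasing")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total


@dataclass
class SyntheticTruth:
    """Generator ground truth for recovery tests."""

    true_weights: np.ndarray
    true_mafs: np.ndarray
    liability: np.ndarray  # raw true score per individual
    standardized_liability: np.ndarray  # (liability - mu) / sigma, theoretical
    assigned_status: np.ndarray  # 1 = case
    assigned_aao: np.ndarray  # nan for controls
    intercept: float
    prs_effect: float


@dataclass
class SyntheticStudy:
    """A complete simulated study: the four analysis inputs plus truth."""

    panel: DosagePanel
    cohort: Cohort
    weights: VariantWeightTable
    life_table: LifeTable
    truth: SyntheticTruth
    config: SimulationConfig


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _variant_metadata(n_snps: int, rng: np.random.Generator) -> pd.DataFrame:
    chroms = [str(1 + i % 22) for i in range(n_snps)]
    pos = 10_000 + 1_000 * (np.arange(n_snps) // 22)
    pairs = [_NON_AMBIGUOUS_PAIRS[k] for k in rng.integers(0, len(_NON_AMBIGUOUS_PAIRS), n_snps)]
    ref, alt = zip(*pairs)
    return pd.DataFrame(
        {"chrom": chroms, "pos": pos.astype(np.int64), "ref": ref, "alt": alt}
    )


def generate_genotypes(
    mafs: np.ndarray,
    n_individuals: int,
    seed,
    dosage_noise: float = 0.0,
    id_prefix: str = "I",
) -> DosagePanel:
    """Hardy-Weinberg allele-count dosages at the given alt-allele MAFs.

    Each dosage is the sum of two Bernoulli(maf) allele draws, i.e.
    Binomial(2, maf); with ``dosage_noise`` > 0 a truncated Gaussian
    perturbation keeps values in [0, 2] (imputation realism, off by
    default). Deterministic given the seed.
    """
    mafs = np.asarray(mafs, dtype=float)
    if mafs.ndim != 1 or mafs.size == 0:
        raise ValueError("mafs must be a non-empty 1-d array")
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("each MAF must lie in (0, 0.5]")
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    rng = _rng(seed)
    meta = _variant_metadata(mafs.size, rng)
    dosages = rng.binomial(2, mafs, size=(n_individuals, mafs.size)).astype(float)
    if dosage_noise > 0:
        dosages = np.clip(
            dosages + rng.normal(0.0, dosage_noise, dosages.shape), 0.0, 2.0
        )
    ids = [f"{id_prefix}{k:06d}" for k in range(n_individuals)]
    return DosagePanel(individual_ids=pd.Index(ids), variants=meta, dosages=dosages)


def generate_weight_table(
    config: SimulationConfig, seed
) -> tuple[VariantWeightTable, np.ndarray, np.ndarray]:
    """Draw per-SNP MAFs and log-odds weights; effect allele = panel alt.

    A ``large_effect_fraction`` of SNPs receives extra-variance weights,
    mimicking the handful of genome-wide significant hits among many
    small contributors. Returns (table, weights, mafs); the table's
    variant metadata matches :func:`generate_genotypes` for the same
    MAF vector length and seed stream.
    """
    rng = _rng(seed)
    mafs = rng.uniform(*config.maf_range, config.n_snps)
    w = rng.normal(config.weight_mean, config.weight_sd, config.n_snps)
    n_large = int(round(config.large_effect_fraction * config.n_snps))
    if n_large:
        big = rng.choice(config.n_snps, n_large, replace=False)
        w[big] = rng.normal(config.weight_mean, config.large_effect_sd, n_large)
    meta = _variant_metadata(config.n_snps, rng)
    table = VariantWeightTable(
        variants=pd.DataFrame(
            {
                "chrom": meta["chrom"],
                "pos": meta["pos"],
                "effect_allele": meta["alt"],
                "other_allele": meta["ref"],
                "weight": w,
            }
        )
    )
    return table, w, mafs


def _liability_moments(weights: np.ndarray, mafs: np.ndarray) -> tuple[float, float]:
    """Theoretical mean and SD of the raw score under HWE."""
    mu = float(np.sum(weights * 2.0 * mafs))
    var = float(np.sum(weights**2 * 2.0 * mafs * (1.0 - mafs)))
    return mu, np.sqrt(var)


def expected_case_fraction(config: SimulationConfig, intercept: float) -> float:
    """Population case probability under the generating logistic model,
    by Gauss-Hermite (score) x Gauss-Legendre (age) x sex quadrature."""
    zk, wk = special.roots_hermitenorm(61)
    wk = wk / wk.sum()
    ak, awk = np.polynomial.legendre.leggauss(41)
    lo, hi = config.age_range
    ages = 0.5 * (hi - lo) * ak + 0.5 * (hi + lo)
    awk = awk / awk.sum()
    mid = 0.5 * (lo + hi)
    total = 0.0
    for sex in (0.0, 1.0):
        eta = (
            intercept
            + config.prs_effect * zk[:, None]
            + config.sex_effect * (sex - 0.5)
            + config.age_effect * (ages[None, :] - mid)
        )
        total += 0.5 * float(wk @ special.expit(eta) @ awk)
    return total


def calibrate_intercept(config: SimulationConfig) -> float:
    """Intercept for which the population case fraction equals
    ``n_cases / (n_cases + n_controls)``."""
    if config.intercept is not None:
        return config.intercept
    target = config.case_fraction
    return float(
        optimize.brentq(
            lambda a: expected_case_fraction(config, a) - target, -30.0, 30.0
        )
    )


def generate_cohort(
    panel: DosagePanel,
    weights: np.ndarray,
    config: SimulationConfig,
    seed=None,
) -> tuple[Cohort, SyntheticTruth]:
    """Assign phenotypes to the panel's individuals from the true model.

    Status is Bernoulli with logit = intercept + prs_effect * Z +
    sex_effect * (sex - 1/2) + age_effect * (age - midrange), where Z is
    the theoretically standardized raw true score. Cases get an
    age-at-onset of N(aao_mean + aao_prs_slope * Z, aao_sd^2). PCs are
    standard-normal noise covariates (no confounding is simulated).
    """
    if panel.n_individuals == 0 or panel.n_variants == 0:
        raise ValueError("panel is empty")
    weights = np.asarray(weights, dtype=float)
    if weights.size != panel.n_variants:
        raise ValueError("weights length must equal the panel's variant count")
    rng = _rng(config.seed + 1 if seed is None else seed)
    n = panel.n_individuals
    mafs = panel.alt_frequencies()
    liability = np.nan_to_num(panel.dosages) @ weights
    mu, sd = _liability_moments(weights, mafs)
    z = (liability - mu) / sd if sd > 0 else np.zeros(n)
    sex = rng.integers(0, 2, n).astype(float)
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, n)
    intercept = calibrate_intercept(config)
    eta = (
        intercept
        + config.prs_effect * z
        + config.sex_effect * (sex - 0.5)
        + config.age_effect * (age - 0.5 * (lo + hi))
    )
    status = (rng.uniform(size=n) < special.expit(eta)).astype(int)
    aao = np.full(n, np.nan)
    is_case = status == 1
    aao[is_case] = (
        config.aao_mean
        + config.aao_prs_slope * z[is_case]
        + rng.normal(0.0, config.aao_sd, int(is_case.sum()))
    )
    pcs = rng.normal(size=(n, 3))
    cohort = Cohort(
        samples=pd.DataFrame(
            {
                "individual_id": list(panel.individual_ids),
                "status": np.where(is_case, "case", "control"),
                "sex": sex.astype(int),
                "age_at_sampling": age,
                "age_at_onset": aao,
                "PC1": pcs[:, 0],
                "PC2": pcs[:, 1],
                "PC3": pcs[:, 2],
            }
        )
    )
    truth = SyntheticTruth(
        true_weights=weights,
        true_mafs=mafs,
        liability=liability,
        standardized_liability=z,
        assigned_status=status,
        assigned_aao=aao,
        intercept=intercept,
        prs_effect=config.prs_effect,
    )
    return cohort, truth


def generate_life_table(
    incidence_profile=None, death_profile=None
) -> LifeTable:
    """A 10-interval life table; the packaged default profile gives a
    residual lifetime incidence of ~1.7% at age 50."""
    inc = DEFAULT_INCIDENCE if incidence_profile is None else tuple(incidence_profile)
    dth = DEFAULT_ANNUAL_DEATH if death_profile is None else tuple(death_profile)
    if len(inc) != 10 or len(dth) != 10:
        raise ValueError("profiles must cover the 10 intervals [50-54] ... [95+]")
    return LifeTable(
        intervals=pd.DataFrame(
            {
                "interval": list(LIFE_TABLE_LABELS),
                "incidence": inc,
                "annual_death_rate": dth,
            }
        )
    )


def simulate_case_control_study(config: SimulationConfig) -> SyntheticStudy:
    """Simulate a full study with exact case and control counts.

    Population batches are drawn from the generating model and the first
    ``n_cases`` cases and ``n_controls`` controls retained (case-control
    sampling). Child seeds are spawned from ``config.seed``, so the
    whole study is reproducible bit-for-bit.
    """
    root = np.random.SeedSequence(config.seed)
    ss_weights, ss_batches = root.spawn(2)
    wtab, w, mafs = generate_weight_table(config, np.random.default_rng(ss_weights))

    batch_seeds = ss_batches.spawn(64)
    panels, cohorts, truths = [], [], []
    n_cases = n_controls = 0
    batch_size = max(64, int(1.4 * config.n_total))
    for b, ss in enumerate(batch_seeds):
        g_rng, c_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        panel = generate_genotypes(
            mafs, batch_size, g_rng,
            dosage_noise=config.dosage_noise, id_prefix=f"B{b}I",
        )
        # metadata must match the weight table, not a fresh draw
        meta = wtab.variants.rename(
            columns={"effect_allele": "alt", "other_allele": "ref"}
        )[["chrom", "pos", "ref", "alt"]].copy()
        meta["alt_freq"] = mafs
        panel = DosagePanel(
            individual_ids=panel.individual_ids, variants=meta, dosages=panel.dosages
        )
        cohort, truth = generate_cohort(panel, w, config, seed=c_rng)
        panels.append(panel)
        cohorts.append(cohort)
        truths.append(truth)
        n_cases += int(truth.assigned_status.sum())
        n_controls += int((1 - truth.assigned_status).sum())
        if n_cases >= config.n_cases and n_controls >= config.n_controls:
            break
    else:
        raise RuntimeError("failed to reach requested case/control counts")

    dosages = np.vstack([p.dosages for p in panels])
    ids = pd.Index(np.concatenate([p.individual_ids for p in panels]))
    samples = pd.concat([c.samples for c in cohorts], ignore_index=True)
    status = np.concatenate([t.assigned_status for t in truths])
    keep_case = np.flatnonzero(status == 1)[: config.n_cases]
    keep_ctrl = np.flatnonzero(status == 0)[: config.n_controls]
    keep = np.sort(np.concatenate([keep_case, keep_ctrl]))

    panel = DosagePanel(
        individual_ids=ids[keep], variants=panels[0].variants, dosages=dosages[keep]
    )
    cohort = Cohort(samples=samples.iloc[keep].reset_index(drop=True))
    t0 = truths[0]
    truth = SyntheticTruth(
        true_weights=w,
        true_mafs=mafs,
        liability=np.concatenate([t.liability for t in truths])[keep],
        standardized_liability=np.concatenate(
            [t.standardized_liability for t in truths]
        )[keep],
        assigned_status=status[keep],
        assigned_aao=np.concatenate([t.assigned_aao for t in truths])[keep],
        intercept=t0.intercept,
        prs_effect=config.prs_effect,
    )
    return SyntheticStudy(
        panel=panel,
        cohort=cohort,
        weights=wtab,
        life_table=generate_life_table(),
        truth=truth,
        config=config,
    )


def write_study(study: SyntheticStudy, outdir: str | Path, dosage_format: str = "tsv") -> None:
    """Write the four analysis inputs plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_weights(study.weights, outdir / "weights.tsv")
    ext = "vcf" if dosage_format == "vcf" else "tsv"
    write_dosages(study.panel, outdir / f"dosages.{ext}", format=dosage_format)
    write_cohort(study.cohort, outdir / "cohort.csv")
    write_life_table(study.life_table, outdir / "life_table.csv")
    truth = {
        "true_weights": study.truth.true_weights.tolist(),
        "true_mafs": study.truth.true_mafs.tolist(),
        "intercept": study.truth.intercept,
        "prs_effect": study.truth.prs_effect,
        "config": asdict(study.config),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
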