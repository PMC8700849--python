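"""File formats and the shared tabular data model.

Four external inputs are supported, all plain text:

* variant weight table — TSV with columns ``chrom, pos, effect_allele,
  other_allele, weight`` (log-odds per effect-allele copy), optionally
  preceded by ``#genome_build=`` comment lines;
* allele-dosage panel — variants-by-individuals TSV (``chrom, pos, ref,
  alt`` then one column per individual, dosages in [0, 2], missing ``.``)
  or an uncompressed VCF carrying a per-genotype ``DS`` field;
* phenotype table — CSV with case/control status, sex, age at sampling,
  age at onset (cases only) and the first three principal components;
* life table — CSV of 5-year age intervals [50-54] … [95+] with the
  interval probability of disease onset and the annual death probability.

Readers validate and reject rather than coerce; ``read`` after ``write``
is the identity on valid objects. Coordinates are 1-based (VCF
convention). Dosages always count the panel's alt allele; re-orientation
to the score's effect allele happens in :mod:`prseval.scoring`.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "VariantWeightTable",
    "DosagePanel",
    "Cohort",
    "LifeTable",
    "LIFE_TABLE_LABELS",
    "read_weights",
    "write_weights",
    "read_dosages",
    "write_dosages",
    "read_cohort",
    "write_cohort",
    "read_life_table",
    "write_life_table",
]

_BASES = frozenset("ACGT")
MISSING_TOKEN = "."

#: canonical 5-year intervals from [50-54] to the open-ended [95+]
LIFE_TABLE_LABELS = tuple(f"{a}-{a + 4}" for a in range(50, 95, 5)) + ("95+",)
LIFE_TABLE_STARTS = tuple(range(50, 100, 5))


class ParseError(ValueError):
    """Raised when an input file is malformed or violates an invariant."""


def _check_alleles(series: pd.Series, what: str) -> None:
    bad = ~series.isin(_BASES)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"invalid {what} {series.iloc[i]!r} at data row {i + 1}")


def _check_no_duplicate_sites(df: pd.DataFrame, what: str) -> None:
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ParseError(
            f"duplicate (chrom, pos) = ({df['chrom'].iloc[i]}, {df['pos'].iloc[i]}) "
            f"at data row {i + 1} of {what}"
        )


@dataclass
class VariantWeightTable:
    """Published score variants: site, allele pair and per-allele weight.

    ``variants`` columns: chrom (str), pos (int, 1-based), effect_allele,
    other_allele, weight (log-odds per effect-allele copy). The optional
    ``genome_build`` tag is informational only.
    """

    variants: pd.DataFrame
    genome_build: str | None = None

    def __post_init__(self) -> None:
        required = ["chrom", "pos", "effect_allele", "other_allele", "weight"]
        missing = [c for c in required if c not in self.variants.columns]
        if missing:
            raise ParseError(f"weight table missing columns {missing}")
        df = self.variants.reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(np.int64)
        if (df["pos"] <= 0).any():
            raise ParseError("variant positions must be positive 1-based coordinates")
        _check_alleles(df["effect_allele"], "effect allele")
        _check_alleles(df["other_allele"], "other allele")
        if (df["effect_allele"] == df["other_allele"]).any():
            raise ParseError("effect and other allele must differ")
        df["weight"] = pd.to_numeric(df["weight"], errors="raise").astype(float)
        if not np.isfinite(df["weight"]).all():
            raise ParseError("weights must be finite")
        _check_no_duplicate_sites(df, "weight table")
        self.variants = df

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class DosagePanel:
    """Individuals x variants allele-dosage matrix with variant metadata.

    ``dosages[i, j]`` is the expected count in [0, 2] of variant *j*'s alt
    allele carried by individual *i*; ``nan`` marks a missing value.
    ``variants`` columns: chrom, pos, ref, alt, and optionally
    ``alt_freq`` and ``info`` (imputation quality).
    """

    individual_ids: pd.Index
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = pd.Index(self.individual_ids, dtype=str)
        if self.individual_ids.has_duplicates:
            raise ParseError("individual IDs must be unique")
        required = ["chrom", "pos", "ref", "alt"]
        missing = [c for c in required if c not in self.variants.columns]
        if missing:
            raise ParseError(f"panel metadata missing columns {missing}")
        df = self.variants.reset_index(drop=True).copy()
        df["chrom"] = df["chrom"].astype(str)
        df["pos"] = pd.to_numeric(df["pos"], errors="raise").astype(np.int64)
        _check_alleles(df["ref"], "ref allele")
        _check_alleles(df["alt"], "alt allele")
        _check_no_duplicate_sites(df, "dosage panel")
        self.variants = df
        d = np.asarray(self.dosages, dtype=float)
        if d.shape != (len(self.individual_ids), len(df)):
            raise ParseError(
                f"dosage matrix shape {d.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(df)} variants"
            )
        finite = d[~np.isnan(d)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ParseError("dosages must lie in [0, 2]")
        self.dosages = d

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def alt_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per variant: stored metadata if present,
        otherwise half the mean observed dosage."""
        if "alt_freq" in self.variants.columns:
            return self.variants["alt_freq"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_individuals(self, index: np.ndarray) -> "DosagePanel":
        return DosagePanel(
            individual_ids=self.individual_ids[index],
            variants=self.variants,
            dosages=self.dosages[index],
        )


@dataclass
class Cohort:
    """Per-individual phenotypes and covariates.

    ``samples`` columns: individual_id, status ('case'/'control'),
    sex (0 = female, 1 = male), age_at_sampling (years), age_at_onset
    (years; cases only, nan otherwise), PC1..PC3.
    """

    samples: pd.DataFrame

    STATUS = ("control", "case")

    def __post_init__(self) -> None:
        required = [
            "individual_id", "status", "sex", "age_at_sampling",
            "age_at_onset", "PC1", "PC2", "PC3",
        ]
        missing = [c for c in required if c not in self.samples.columns]
        if missing:
            raise ParseError(f"cohort table missing columns {missing}")
        df = self.samples.reset_index(drop=True).copy()
        df["individual_id"] = df["individual_id"].astype(str)
        if df["individual_id"].duplicated().any():
            raise ParseError("individual IDs must be unique")
        if not df["status"].isin(self.STATUS).all():
            raise ParseError("status must be 'case' or 'control'")
        if not df["sex"].isin([0, 1]).all():
            raise ParseError("sex must be coded 0 (female) / 1 (male)")
        df["age_at_sampling"] = pd.to_numeric(df["age_at_sampling"]).astype(float)
        df["age_at_onset"] = pd.to_numeric(df["age_at_onset"]).astype(float)
        is_control = (df["status"] == "control").to_numpy()
        if np.isfinite(df["age_at_onset"].to_numpy()[is_control]).any():
            raise ParseError("controls must not carry an age-at-onset")
        for c in ("PC1", "PC2", "PC3"):
            df[c] = pd.to_numeric(df[c]).astype(float)
        self.samples = df

    @property
    def is_case(self) -> np.ndarray:
        return (self.samples["status"] == "case").to_numpy()

    @property
    def n_cases(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_controls(self) -> int:
        return len(self.samples) - self.n_cases

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class LifeTable:
    """Age-interval disease incidence and annual death probabilities.

    Exactly the ten 5-year intervals [50-54] … [95+]; ``incidence`` is the
    probability of disease onset within the interval for a disease-free
    entrant, ``annual_death_rate`` the per-year death probability.
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["interval", "incidence", "annual_death_rate"]
        missing = [c for c in required if c not in self.intervals.columns]
        if missing:
            raise ParseError(f"life table missing columns {missing}")
        df = self.intervals.reset_index(drop=True).copy()
        labels = tuple(df["interval"].astype(str))
        if labels != LIFE_TABLE_LABELS:
            raise ParseError(
                f"life table must cover exactly {list(LIFE_TABLE_LABELS)}, got {list(labels)}"
            )
        for c in ("incidence", "annual_death_rate"):
            df[c] = pd.to_numeric(df[c]).astype(float)
            if ((df[c] < 0) | (df[c] > 1)).any():
                raise ParseError(f"{c} must lie in [0, 1]")
        df["age_start"] = list(LIFE_TABLE_STARTS)
        self.intervals = df

    @property
    def incidence(self) -> np.ndarray:
        return self.intervals["incidence"].to_numpy()

    @property
    def annual_death_rate(self) -> np.ndarray:
        return self.intervals["annual_death_rate"].to_numpy()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.intervals["interval"])


# ---------------------------------------------------------------------------
# weight table I/O

def read_weights(path: str | Path) -> VariantWeightTable:
    path = Path(path)
    build = None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        if line.startswith("#genome_build="):
            build = line.strip().split("=", 1)[1]
        body_start += 1
    try:
        df = pd.read_csv(_stdio.StringIO("".join(lines[body_start:])), sep="\t")
    except Exception as exc:  # malformed TSV
        raise ParseError(f"cannot parse weight table {path}: {exc}") from exc
    return VariantWeightTable(variants=df, genome_build=build)


def write_weights(table: VariantWeightTable, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if table.genome_build:
            fh.write(f"#genome_build={table.genome_build}\n")
        table.variants.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# dosage panel I/O

def read_dosages(path: str | Path, format: str = "tsv") -> DosagePanel:
    """Read a dosage panel from variants-by-individuals TSV or VCF.

    Missing dosages (``.`` in TSV, absent/``.`` DS in VCF) become ``nan``
    — flagged, never silently zeroed.
    """
    if format == "tsv":
        return _read_dosages_tsv(Path(path))
    if format == "vcf":
        return _read_dosages_vcf(Path(path))
    raise ValueError(f"unknown dosage format {format!r}")


def _read_dosages_tsv(path: Path) -> DosagePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    meta_cols = ["chrom", "pos", "ref", "alt"]
    opt_cols = [c for c in ("alt_freq", "info") if c in df.columns]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ParseError(f"dosage TSV missing metadata columns {missing}")
    id_cols = [c for c in df.columns if c not in meta_cols + opt_cols]
    if not id_cols:
        raise ParseError("dosage TSV has no individual columns")
    raw = df[id_cols].to_numpy(dtype=object)
    dosages = np.full(raw.shape, np.nan)
    mask = raw != MISSING_TOKEN
    try:
        dosages[mask] = raw[mask].astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric dosage in {path}: {exc}") from exc
    finite = dosages[mask.astype(bool)]
    if finite.size and (np.min(finite) < 0 or np.max(finite) > 2):
        bad = np.argwhere((dosages < 0) | (dosages > 2))[0]
        raise ParseError(
            f"dosage {dosages[tuple(bad)]} outside [0, 2] at data row {bad[0] + 1}"
        )
    meta = df[meta_cols + opt_cols].copy()
    for c in opt_cols:
        meta[c] = pd.to_numeric(meta[c]).astype(float)
    return DosagePanel(
        individual_ids=pd.Index(id_cols), variants=meta, dosages=dosages.T
    )


def write_dosages(panel: DosagePanel, path: str | Path, format: str = "tsv") -> None:
    if format == "tsv":
        _write_dosages_tsv(panel, Path(path))
    elif format == "vcf":
        _write_dosages_vcf(panel, Path(path))
    else:
        raise ValueError(f"unknown dosage format {format!r}")


def _write_dosages_tsv(panel: DosagePanel, path: Path) -> None:
    out = panel.variants.copy()
    mat = panel.dosages.T  # variants x individuals
    block = pd.DataFrame(mat, columns=list(panel.individual_ids))
    block = block.astype(object).where(~np.isnan(mat), MISSING_TOKEN)
    pd.concat([out, block], axis=1).to_csv(path, sep="\t", index=False)


def _read_dosages_vcf(path: Path) -> DosagePanel:
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        if "DS" not in vcf.header.formats:
            raise ParseError("VCF lacks a per-genotype DS (dosage) FORMAT field")
        ids = list(vcf.header.samples)
        rows, dose_rows = [], []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(f"biallelic records required at {rec.chrom}:{rec.pos}")
            rows.append((str(rec.chrom), rec.pos, rec.ref, rec.alts[0]))
            vals = []
            for s in ids:
                ds = rec.samples[s].get("DS")
                if isinstance(ds, tuple):
                    ds = ds[0] if ds else None
                vals.append(np.nan if ds is None else float(ds))
            dose_rows.append(vals)
    meta = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = np.asarray(dose_rows, dtype=float).T if dose_rows else np.empty((len(ids), 0))
    finite = dosages[~np.isnan(dosages)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ParseError("VCF dosage outside [0, 2]")
    return DosagePanel(individual_ids=pd.Index(ids), variants=meta, dosages=dosages)


def _write_dosages_vcf(panel: DosagePanel, path: Path) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line(
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alt allele dosage">'
    )
    for chrom in pd.unique(panel.variants["chrom"]):
        header.add_line(f"##contig=<ID={chrom}>")
    for s in panel.individual_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, row in panel.variants.iterrows():
            rec = out.new_record(
                contig=row["chrom"],
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]),
                alleles=(row["ref"], row["alt"]),
            )
            for i, s in enumerate(panel.individual_ids):
                d = panel.dosages[i, j]
                if not np.isnan(d):
                    rec.samples[s]["DS"] = float(d)
            out.write(rec)


# ---------------------------------------------------------------------------
# cohort and life table I/O

def read_cohort(path: str | Path) -> Cohort:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse cohort CSV {path}: {exc}") from exc
    return Cohort(samples=df)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    cohort.samples.to_csv(path, index=False)


def read_life_table(path: str | Path) -> LifeTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse life table CSV {path}: {exc}") from exc
    return LifeTable(intervals=df)


def write_life_table(table: LifeTable, path: str | Path) -> None:
    table.intervals[["interval", "incidence", "annual_death_rate"]].to_csv(
        path, index=False
    )
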