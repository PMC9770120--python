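"""Core domain types shared by every analysis stage.

Conventions
-----------
* Variants are keyed positionally by ``(chrom, pos, ref, alt)`` with 1-based
  positions (VCF convention); rsIDs are carried along but are advisory only.
* Genotypes are stored as effect-allele dosage matrices of shape
  ``(n_samples, n_variants)`` with entries in ``{0, 1, 2}`` and ``NaN`` for
  missing calls.
* The cohort table holds the phenotype (case/control), demographic
  covariates, an ancestry label and principal components per sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantKey",
    "GenotypeMatrix",
    "ScoringRecord",
    "ScoringFile",
    "CohortTable",
    "VariantAnnotation",
    "SUMSTATS_COLUMNS",
    "KNOWN_LOCI_COLUMNS",
]

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: Canonical column order for summary-statistics tables (one row per variant).
SUMSTATS_COLUMNS = ["CHR", "POS", "RSID", "EA", "NEA", "BETA", "SE", "P", "EAF"]

#: Canonical column order for known-locus catalogs.
KNOWN_LOCI_COLUMNS = ["CHR", "POS", "RSID", "LOCUS"]


@dataclass(frozen=True)
class VariantKey:
    """Positional identity of a sequence variant.

    Parameters
    ----------
    chrom : str
        Chromosome label (``"1"`` and ``"chr1"`` are distinct; callers must
        use one convention consistently).
    pos : int
        1-based position of the first reference base.
    ref, alt : str
        Reference and alternate alleles, uppercase over ``{A, C, G, T}``.
        Symbolic alleles (``<DEL>``, breakends, ...) are rejected.
    rsid : str, optional
        dbSNP identifier, advisory only — never used for equality.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ValueError(
                    f"{name} allele {allele!r} is not an uppercase ACGT string"
                )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self.ref}")

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def __str__(self) -> str:  # chr19:8438638:C:A style
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


class GenotypeMatrix:
    """Samples x variants matrix of alternate-allele dosages.

    Dosages are floats in ``{0.0, 1.0, 2.0}``; missing genotypes are ``NaN``.
    """

    def __init__(
        self,
        sample_ids: list[str],
        variants: list[VariantKey],
        dosage: np.ndarray,
    ) -> None:
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(sample_ids), len(variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"({len(sample_ids)} samples, {len(variants)} variants)"
            )
        valid = np.isnan(dosage) | np.isin(dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = dosage[~valid].flat[0]
            raise ValueError(f"dosage entries must be 0, 1, 2 or NaN; found {bad}")
        self.sample_ids = list(sample_ids)
        self.variants = list(variants)
        self.dosage = dosage

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def missing_rate(self) -> np.ndarray:
        """Per-variant fraction of missing genotypes."""
        return np.isnan(self.dosage).mean(axis=0)

    def alt_allele_freq(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing calls.

        This is the effect-allele frequency convention used throughout:
        no minor-allele folding, so values span [0, 1].
        """
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def subset_samples(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in index], self.variants, self.dosage[index]
        )

    def subset_variants(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.sample_ids,
            [self.variants[i] for i in index],
            self.dosage[:, index],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.variants == other.variants
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_variants} variants)"


@dataclass(frozen=True)
class ScoringRecord:
    """One weighted variant of a published polygenic score."""

    effect_allele: str
    weight: float
    chrom: str | None = None
    pos: int | None = None
    other_allele: str | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise ValueError("effect weight must be finite")
        if self.other_allele is not None and self.effect_allele == self.other_allele:
            raise ValueError(
                f"effect and other allele are identical: {self.effect_allele}"
            )
        if self.chrom is None and self.rsid is None:
            raise ValueError("scoring record needs a (chrom, pos) locus or an rsid")


@dataclass
class ScoringFile:
    """A published PRS scoring file: an identifier plus weighted variants."""

    pgs_id: str
    records: list[ScoringRecord]
    n_rejected: int = 0  # malformed rows dropped at parse time

    def __post_init__(self) -> None:
        if not self.pgs_id:
            raise ValueError("pgs_id must be nonempty")

    def __len__(self) -> int:
        return len(self.records)


class CohortTable:
    """Per-sample phenotype and covariates.

    Wraps a DataFrame with columns ``sample_id``, ``status`` (1=case,
    0=control), ``age``, ``sex`` (``male``/``female``), optional ``bmi``,
    ``ancestry``, principal components ``pc1..pcK`` and any extra covariate
    columns (e.g. ``t2d``).
    """

    _CORE = ("sample_id", "status", "age", "sex")

    def __init__(self, df: pd.DataFrame) -> None:
        for col in self._CORE:
            if col not in df.columns:
                raise ValueError(f"cohort table is missing required column {col!r}")
        df = df.reset_index(drop=True).copy()
        if not set(df["status"].unique()) <= {0, 1}:
            raise ValueError("status must be binary 0/1")
        if (df["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad_sex = set(df["sex"].unique()) - {"male", "female"}
        if bad_sex:
            raise ValueError(f"unrecognized sex labels: {sorted(bad_sex)}")
        self.df = df

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    @property
    def status(self) -> np.ndarray:
        """Case indicator (1=case, 0=control) as an int array."""
        return self.df["status"].to_numpy(dtype=int)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.status).sum())

    @property
    def pc_columns(self) -> list[str]:
        cols = [c for c in self.df.columns if re.fullmatch(r"pc\d+", c)]
        return sorted(cols, key=lambda c: int(c[2:]))

    @property
    def ancestry(self) -> np.ndarray:
        if "ancestry" not in self.df.columns:
            raise ValueError("cohort table has no ancestry column")
        return self.df["ancestry"].to_numpy()

    def covariate_matrix(self, names: list[str]) -> tuple[np.ndarray, list[str]]:
        """Build a numeric design block for the requested covariates.

        ``"sex"`` becomes a male indicator; ``"pcs"`` expands to all pc
        columns. Returns ``(matrix, expanded column names)``.
        """
        cols: list[str] = []
        blocks: list[np.ndarray] = []
        for name in names:
            if name == "sex":
                blocks.append((self.df["sex"] == "male").to_numpy(float)[:, None])
                cols.append("sex_male")
            elif name == "pcs":
                pcs = self.pc_columns
                if pcs:
                    blocks.append(self.df[pcs].to_numpy(float))
                    cols.extend(pcs)
            elif name in self.df.columns:
                blocks.append(self.df[name].to_numpy(float)[:, None])
                cols.append(name)
            else:
                raise KeyError(f"covariate {name!r} not in cohort table")
        if not blocks:
            return np.empty((len(self.df), 0)), []
        return np.hstack(blocks), cols

    def subset(self, index: np.ndarray | list[int]) -> "CohortTable":
        return CohortTable(self.df.iloc[np.asarray(index)].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"CohortTable({self.n_cases} cases, {self.n_controls} controls)"


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional annotation of one variant for burden filtering."""

    key: VariantKey
    gene: str
    impact: str  # high | moderate | low
    clinvar: str = "none"  # P/LP | VUS | benign | none

    _IMPACTS = ("high", "moderate", "low")
    _CLINVAR = ("P/LP", "VUS", "benign", "none")

    def __post_init__(self) -> None:
        if self.impact not in self._IMPACTS:
            raise ValueError(f"impact must be one of {self._IMPACTS}")
        if self.clinvar not in self._CLINVAR:
            raise ValueError(f"clinvar class must be one of {self._CLINVAR}")
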