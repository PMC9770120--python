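"""Readers, writers and allele harmonization for the standard file formats.

Formats handled:

* VCF v4.2 with GT genotypes (read via cyvcf2; a minimal writer is provided
  so simulated cohorts round-trip through the same reader used for real data)
* PGS Catalog scoring files (tab-separated, ``#`` comment lines, header
  ``rsID chr_name chr_position effect_allele other_allele effect_weight``)
* cohort phenotype/covariate TSV
* GWAS summary-statistics TSV (``CHR POS RSID EA NEA BETA SE P EAF``)
* known-loci catalog TSV (``CHR POS RSID LOCUS``)
* variant annotation TSV (``CHR POS REF ALT GENE IMPACT CLINVAR``)
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .types import (
    KNOWN_LOCI_COLUMNS,
    SUMSTATS_COLUMNS,
    CohortTable,
    GenotypeMatrix,
    ScoringFile,
    ScoringRecord,
    VariantAnnotation,
    VariantKey,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_scoring_file",
    "write_scoring_file",
    "read_cohort_table",
    "write_cohort_table",
    "read_summary_stats",
    "write_summary_stats",
    "read_known_loci",
    "write_known_loci",
    "read_annotations",
    "write_annotations",
    "harmonize",
    "Harmonization",
    "complement",
    "is_ambiguous_pair",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def complement(allele: str) -> str:
    """Reverse-strand complement of an ACGT allele string."""
    return allele.translate(_COMPLEMENT)[::-1]


def is_ambiguous_pair(a1: str, a2: str | None) -> bool:
    """True for strand-ambiguous SNP pairs (A/T or C/G)."""
    if a2 is None:
        return False
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, sample_subset: list[str] | None = None) -> GenotypeMatrix:
    """Read GT genotypes from a VCF into a dosage matrix.

    Dosage is the alternate-allele count of the GT call; missing calls become
    NaN. Records must be biallelic (split multiallelics upstream) and unique
    by (chrom, pos, ref, alt).
    """
    vcf = VCF(str(path), gts012=True)
    if sample_subset is not None:
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)
    keys: list[VariantKey] = []
    rows: list[np.ndarray] = []
    seen: set[tuple] = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"record {rec.CHROM}:{rec.POS} is not biallelic "
                f"(ALT={rec.ALT}); split multiallelics upstream"
            )
        rsid = rec.ID if rec.ID not in (None, ".") else None
        key = VariantKey(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], rsid)
        ident = (key.chrom, key.pos, key.ref, key.alt)
        if ident in seen:
            raise ValueError(f"duplicate variant record {key}")
        seen.add(ident)
        gt = rec.gt_types.astype(float)  # 0/1/2 = dosage, 3 = unknown
        gt[gt == 3] = np.nan
        keys.append(key)
        rows.append(gt)
    dosage = (
        np.array(rows).T if rows else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, keys, dosage)


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes."""
    chroms = []
    for v in geno.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=prscohort\n")
    for c in chroms:
        buf.write(f"##contig=<ID={c}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(geno.sample_ids)
        + "\n"
    )
    for j, v in enumerate(geno.variants):
        col = geno.dosage[:, j]
        gts = "\t".join(
            "./." if np.isnan(d) else _GT_STRINGS[d] for d in col
        )
        buf.write(
            f"{v.chrom}\t{v.pos}\t{v.rsid or '.'}\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{gts}\n"
        )
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# PGS Catalog scoring files
# ---------------------------------------------------------------------------

def read_scoring_file(path: str | Path, pgs_id: str | None = None) -> ScoringFile:
    """Parse a PGS Catalog style scoring file.

    Lines starting with ``#`` are comments; a ``#pgs_id=...`` comment, when
    present, names the score (falling back to the file stem). Rows lacking an
    effect allele or a parseable weight are dropped; the count of dropped
    rows is kept on the returned object and reported as a warning.
    """
    path = Path(path)
    header_pgs_id = None
    for line in path.read_text().splitlines():
        if line.startswith("#pgs_id="):
            header_pgs_id = line.split("=", 1)[1].strip()
        if not line.startswith("#"):
            break
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "effect_allele" not in df.columns or "effect_weight" not in df.columns:
        raise ValueError(
            f"{path} lacks effect_allele/effect_weight columns: {list(df.columns)}"
        )
    records: list[ScoringRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:  # float() round-trips repr exactly, unlike pandas' fast parser
            weight = float(d.get("effect_weight"))
        except (TypeError, ValueError):
            weight = float("nan")
        ea = d.get("effect_allele")
        if pd.isna(weight) or not isinstance(ea, str) or not ea:
            n_rejected += 1
            continue
        pos = pd.to_numeric(d.get("chr_position"), errors="coerce")
        records.append(
            ScoringRecord(
                effect_allele=ea,
                weight=float(weight),
                chrom=d.get("chr_name") if pd.notna(d.get("chr_name")) else None,
                pos=int(pos) if pd.notna(pos) else None,
                other_allele=(
                    d.get("other_allele") if pd.notna(d.get("other_allele")) else None
                ),
                rsid=d.get("rsID") if pd.notna(d.get("rsID")) else None,
            )
        )
    if not records:
        raise ValueError(f"no parseable scoring records in {path}")
    if n_rejected:
        warnings.warn(
            f"{path.name}: dropped {n_rejected} malformed scoring rows",
            stacklevel=2,
        )
    return ScoringFile(
        pgs_id=pgs_id or header_pgs_id or path.stem,
        records=records,
        n_rejected=n_rejected,
    )


def write_scoring_file(scoring: ScoringFile, path: str | Path) -> None:
    lines = [f"#pgs_id={scoring.pgs_id}"]
    lines.append(
        "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight"
    )
    for r in scoring.records:
        lines.append(
            "\t".join(
                [
                    r.rsid or "",
                    r.chrom or "",
                    "" if r.pos is None else str(r.pos),
                    r.effect_allele,
                    r.other_allele or "",
                    repr(r.weight),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cohort / summary stats / catalogs / annotations
# ---------------------------------------------------------------------------

def read_cohort_table(path: str | Path) -> CohortTable:
    df = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str}, float_precision="round_trip"
    )
    if df["status"].dtype == object:
        mapping = {"case": 1, "control": 0}
        bad = set(df["status"].unique()) - set(mapping)
        if bad:
            raise ValueError(f"unrecognized status labels: {sorted(bad)}")
        df["status"] = df["status"].map(mapping)
    return CohortTable(df)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    df = cohort.df.copy()
    df["status"] = np.where(df["status"] == 1, "case", "control")
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a summary-statistics TSV and validate SE/P ranges."""
    df = pd.read_csv(
        path, sep="\t", dtype={"CHR": str, "RSID": str}, float_precision="round_trip"
    )
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns and c != "EAF"]
    if missing:
        raise ValueError(f"summary stats missing columns {missing}")
    if (df["SE"] <= 0).any():
        raise ValueError("summary stats contain SE <= 0")
    if ((df["P"] <= 0) | (df["P"] > 1)).any():
        raise ValueError("summary stats contain P outside (0, 1]")
    return df


def write_summary_stats(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMSTATS_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols, float_format="%.17g")


def read_known_loci(path: str | Path) -> pd.DataFrame:
    """Read a known-loci catalog; deduplicate on (CHR, POS)."""
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str, "RSID": str})
    missing = [c for c in KNOWN_LOCI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"known-loci catalog missing columns {missing}")
    if (df["POS"] < 1).any():
        raise ValueError("known-loci positions must be 1-based")
    return df.drop_duplicates(subset=["CHR", "POS"]).reset_index(drop=True)


def write_known_loci(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=KNOWN_LOCI_COLUMNS)


def read_annotations(path: str | Path) -> list[VariantAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    return [
        VariantAnnotation(
            key=VariantKey(r.CHR, int(r.POS), r.REF, r.ALT),
            gene=r.GENE,
            impact=r.IMPACT,
            clinvar=r.CLINVAR,
        )
        for r in df.itertuples(index=False)
    ]


def write_annotations(annots: list[VariantAnnotation], path: str | Path) -> None:
    rows = [
        {
            "CHR": a.key.chrom,
            "POS": a.key.pos,
            "REF": a.key.ref,
            "ALT": a.key.alt,
            "GENE": a.gene,
            "IMPACT": a.impact,
            "CLINVAR": a.clinvar,
        }
        for a in annots
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

@dataclass
class Harmonization:
    """Alignment of a scoring file onto a genotype matrix.

    ``variant_index[i]`` is the column of the genotype matrix matched to
    weight ``weights[i]``; where ``flip[i]`` is True the effect allele is the
    reference allele, so the effective dosage is ``2 - dosage``.
    """

    variant_index: np.ndarray
    weights: np.ndarray
    flip: np.ndarray
    n_matched: int
    n_unmatched: int
    n_ambiguous_dropped: int

    def effective_dosage(self, geno: GenotypeMatrix) -> np.ndarray:
        """Effect-allele dosage block (NaN preserved for missing calls)."""
        d = geno.dosage[:, self.variant_index].copy()
        d[:, self.flip] = 2.0 - d[:, self.flip]
        return d


def _alleles_match(
    effect: str, other: str | None, ref: str, alt: str
) -> bool | None:
    """Orientation of a scoring record against a ref/alt pair.

    Returns False (keep dosage), True (flip: effect allele is REF), or None
    if the alleles are irreconcilable.
    """
    if effect == alt and (other is None or other == ref):
        return False
    if effect == ref and (other is None or other == alt):
        return True
    return None


def harmonize(
    scoring: ScoringFile,
    geno: GenotypeMatrix,
    drop_ambiguous: bool = False,
) -> Harmonization:
    """Align scoring-file records to genotype-matrix columns.

    Records are matched by (chrom, pos) — or rsID when no position is given —
    then oriented by allele comparison: effect allele equal to ALT keeps the
    dosage, equal to REF flips it (``2 - dosage``), and the same rules are
    retried on the strand-complemented alleles. Unmatched records are dropped
    and counted. Strand-ambiguous (A/T, C/G) records are kept and matched
    positionally by default (same-build sequencing data) or dropped when
    ``drop_ambiguous`` is set.
    """
    by_locus: dict[tuple[str, int], list[int]] = {}
    by_rsid: dict[str, list[int]] = {}
    for j, v in enumerate(geno.variants):
        by_locus.setdefault(v.locus, []).append(j)
        if v.rsid:
            by_rsid.setdefault(v.rsid, []).append(j)

    idx: list[int] = []
    wts: list[float] = []
    flips: list[bool] = []
    n_unmatched = 0
    n_ambiguous = 0
    for rec in scoring.records:
        if drop_ambiguous and is_ambiguous_pair(rec.effect_allele, rec.other_allele):
            n_ambiguous += 1
            continue
        if rec.chrom is not None and rec.pos is not None:
            candidates = by_locus.get((rec.chrom, rec.pos), [])
        elif rec.rsid is not None:
            candidates = by_rsid.get(rec.rsid, [])
        else:
            candidates = []
        matched = False
        for j in candidates:
            v = geno.variants[j]
            flip = _alleles_match(rec.effect_allele, rec.other_allele, v.ref, v.alt)
            if flip is None:
                flip = _alleles_match(
                    complement(rec.effect_allele),
                    None if rec.other_allele is None else complement(rec.other_allele),
                    v.ref,
                    v.alt,
                )
            if flip is not None:
                idx.append(j)
                wts.append(rec.weight)
                flips.append(flip)
                matched = True
                break
        if not matched:
            n_unmatched += 1
    if not idx:
        raise ValueError(
            f"no scoring records of {scoring.pgs_id} matched the genotype matrix"
        )
    return Harmonization(
        variant_index=np.array(idx, dtype=int),
        weights=np.array(wts, dtype=float),
        flip=np.array(flips, dtype=bool),
        n_matched=len(idx),
        n_unmatched=n_unmatched,
        n_ambiguous_dropped=n_ambiguous,
    )
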