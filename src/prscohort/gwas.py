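"""Post-GWAS machinery: genomic inflation, clumping, replication, meta-analysis.

Per-variant association itself is an ordinary covariate-adjusted logistic
regression (see :func:`prscohort.evaluate.fit_logistic`); this module turns
a table of per-variant results into loci and replication calls:

* genomic inflation factor λ (median association chi-square over its null
  median, 0.4549);
* greedy distance-based clumping of significant variants into independent
  loci around lowest-p leads;
* known-locus replication within a genomic window (default 300 kb) and
  exact-match replication under a Bonferroni threshold;
* inverse-variance fixed-effect meta-analysis of several summary-statistics
  tables with effect-allele harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .io import complement, is_ambiguous_pair

__all__ = [
    "genomic_lambda",
    "genomic_lambda_chi2",
    "clump",
    "Locus",
    "replicate_loci",
    "ReplicationResult",
    "exact_match_replication",
    "meta_fixed",
]

#: Median of the 1-df chi-square distribution.
CHI2_NULL_MEDIAN = 0.4549364231195724


def genomic_lambda_chi2(chi2_values: np.ndarray) -> float:
    """Genomic inflation factor from 1-df association chi-square statistics."""
    chi2_values = np.asarray(chi2_values, dtype=float)
    if chi2_values.size == 0:
        raise ValueError("genomic lambda needs at least one statistic")
    return float(np.median(chi2_values) / CHI2_NULL_MEDIAN)


def genomic_lambda(pvalues: np.ndarray) -> float:
    """Genomic inflation factor λ from association p-values.

    Each p is converted to its 1-df chi-square quantile; λ is the median of
    those statistics divided by the null median 0.4549. λ ≈ 1 indicates a
    well-calibrated test; λ > 1 inflation (stratification), λ < 1 deflation.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("genomic lambda needs at least one p-value")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return genomic_lambda_chi2(chi2.isf(p, df=1))


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    """One clumped locus: the lead (lowest-p) variant plus absorbed members."""

    lead: pd.Series
    members: pd.DataFrame  # includes the lead
    chrom: str
    span: tuple[int, int]


def clump(
    stats: pd.DataFrame, p_threshold: float = 1e-4, window_bp: int = 300_000
) -> list[Locus]:
    """Greedy distance-based clumping into independent loci.

    Only variants with ``P < p_threshold`` participate. Repeatedly take the
    unassigned variant with the lowest p as a lead and absorb every
    unassigned variant on the same chromosome within ``window_bp`` of it.
    Leads of distinct loci are therefore pairwise separated by more than the
    window. Ties on p are broken by input order.
    """
    sig = stats[stats["P"] < p_threshold].copy()
    loci: list[Locus] = []
    order = np.argsort(sig["P"].to_numpy(), kind="stable")
    assigned = np.zeros(len(sig), dtype=bool)
    chrom = sig["CHR"].to_numpy()
    pos = sig["POS"].to_numpy()
    for i in order:
        if assigned[i]:
            continue
        near = (
            (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp) & ~assigned
        )
        assigned |= near
        members = sig.iloc[np.flatnonzero(near)]
        loci.append(
            Locus(
                lead=sig.iloc[i],
                members=members,
                chrom=str(chrom[i]),
                span=(int(members["POS"].min()), int(members["POS"].max())),
            )
        )
    return loci


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicationResult:
    """Window-based replication of known loci by lead variants."""

    matched_leads: pd.DataFrame
    unmatched_leads: pd.DataFrame
    replicated_loci: list[str]  # deduplicated catalog locus names
    n_replicated: int


def replicate_loci(
    leads: pd.DataFrame, catalog: pd.DataFrame, window_bp: int = 300_000
) -> ReplicationResult:
    """Match lead variants to a known-loci catalog by genomic distance.

    A lead matches a catalog entry when both share a chromosome and their
    positions differ by at most ``window_bp``. The replication count is over
    distinct catalog locus names, not catalog rows.
    """
    cat_chrom = catalog["CHR"].to_numpy()
    cat_pos = catalog["POS"].to_numpy()
    cat_locus = catalog["LOCUS"].to_numpy()
    matched_rows = []
    hit_loci: list[str] = []
    is_match = np.zeros(len(leads), dtype=bool)
    for i, row in enumerate(leads.itertuples(index=False)):
        near = (cat_chrom == row.CHR) & (np.abs(cat_pos - row.POS) <= window_bp)
        if near.any():
            is_match[i] = True
            matched_rows.append(i)
            for loc in cat_locus[near]:
                if loc not in hit_loci:
                    hit_loci.append(loc)
    return ReplicationResult(
        matched_leads=leads.iloc[np.flatnonzero(is_match)].reset_index(drop=True),
        unmatched_leads=leads.iloc[np.flatnonzero(~is_match)].reset_index(drop=True),
        replicated_loci=hit_loci,
        n_replicated=len(hit_loci),
    )


def exact_match_replication(
    stats: pd.DataFrame,
    catalog: pd.DataFrame,
    alpha: float = 0.05,
    secondary_cutoff: float = 0.01,
) -> dict:
    """Exact-position replication of previously reported variants.

    Intersects the association table with the catalog on (CHR, POS) — or on
    rsID where a catalog position is missing — and applies a Bonferroni
    threshold ``alpha / n_overlap`` plus a looser secondary cutoff.
    """
    keys = set(zip(catalog["CHR"], catalog["POS"]))
    rsids = set(catalog["RSID"].dropna()) if "RSID" in catalog.columns else set()
    in_cat = [
        (row.CHR, row.POS) in keys
        or (getattr(row, "RSID", None) in rsids if rsids else False)
        for row in stats.itertuples(index=False)
    ]
    overlap = stats[np.asarray(in_cat)].reset_index(drop=True)
    n = len(overlap)
    if n == 0:
        raise ValueError("no overlap between association table and catalog")
    threshold = alpha / n
    return {
        "n_overlap": n,
        "bonferroni_threshold": threshold,
        "significant": overlap[overlap["P"] < threshold].reset_index(drop=True),
        "secondary_cutoff": secondary_cutoff,
        "secondary_significant": overlap[
            overlap["P"] < secondary_cutoff
        ].reset_index(drop=True),
    }


# ---------------------------------------------------------------------------
# Fixed-effect meta-analysis
# ---------------------------------------------------------------------------

def meta_fixed(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Inverse-variance fixed-effect meta-analysis of summary statistics.

    Variants are aligned by (CHR, POS); the first study carrying a variant
    defines its effect-allele orientation, and later studies with swapped
    effect/other alleles have their betas sign-flipped. An allele pair that
    matches neither orientation (including strand-ambiguous mismatches) is
    an error. Weights are 1/SE²; the pooled SE is 1/sqrt(sum of weights) and
    the pooled p a two-sided normal tail. ``HET_RANGE`` flags the spread of
    study betas.
    """
    pooled: dict[tuple, dict] = {}
    for k, df in enumerate(studies):
        if (df["SE"] <= 0).any():
            raise ValueError(f"study {k} contains SE <= 0")
        for row in df.itertuples(index=False):
            key = (row.CHR, row.POS)
            beta, ea, nea = float(row.BETA), row.EA, row.NEA
            if key not in pooled:
                pooled[key] = {
                    "CHR": row.CHR,
                    "POS": row.POS,
                    "RSID": getattr(row, "RSID", None),
                    "EA": ea,
                    "NEA": nea,
                    "betas": [],
                    "ses": [],
                }
            ref = pooled[key]
            if (ea, nea) == (ref["EA"], ref["NEA"]):
                pass
            elif (ea, nea) == (ref["NEA"], ref["EA"]):
                beta = -beta
            elif (complement(ea), complement(nea)) == (ref["EA"], ref["NEA"]):
                if is_ambiguous_pair(ea, nea):
                    raise ValueError(
                        f"strand-ambiguous allele mismatch at {key} in study {k}"
                    )
            elif (complement(ea), complement(nea)) == (ref["NEA"], ref["EA"]):
                if is_ambiguous_pair(ea, nea):
                    raise ValueError(
                        f"strand-ambiguous allele mismatch at {key} in study {k}"
                    )
                beta = -beta
            else:
                raise ValueError(
                    f"irreconcilable alleles at {key} in study {k}: "
                    f"{ea}/{nea} vs {ref['EA']}/{ref['NEA']}"
                )
            ref["betas"].append(beta)
            ref["ses"].append(float(row.SE))
    rows = []
    for ref in pooled.values():
        b = np.array(ref["betas"])
        se = np.array(ref["ses"])
        w = 1.0 / se**2
        beta_pooled = float((w * b).sum() / w.sum())
        se_pooled = float(1.0 / np.sqrt(w.sum()))
        rows.append(
            {
                "CHR": ref["CHR"],
                "POS": ref["POS"],
                "RSID": ref["RSID"],
                "EA": ref["EA"],
                "NEA": ref["NEA"],
                "BETA": beta_pooled,
                "SE": se_pooled,
                "P": float(2 * norm.sf(abs(beta_pooled / se_pooled))),
                "N_STUDIES": len(b),
                "HET_RANGE": float(b.max() - b.min()),
            }
        )
    return pd.DataFrame(rows)
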