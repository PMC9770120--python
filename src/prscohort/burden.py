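"""Rare-variant case/control burden statistics.

Central quantity: the case-control ratio (CCR) of a variant, the ratio of
its effect-allele frequency in cases to controls. Variants absent from
controls get a *pseudo-CCR* — the zero control frequency is replaced by the
lowest nonzero control MAF over the analyzed variant set (in a cohort of N
controls a control singleton, 1/(2N)). Variants absent from cases are
ignored. Gene-level burden aggregates carriers (samples with at least one
qualifying alternate allele in the gene) into a 2x2 carrier table with a
Woolf odds ratio and a two-sided Fisher exact collapsing test, plus an
optional variance-component score test over the per-variant genotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, fisher_exact, ncx2

from .evaluate import OddsRatio, odds_ratio_2x2
from .types import CohortTable, GenotypeMatrix, VariantAnnotation

__all__ = [
    "CCRResult",
    "ccr",
    "VariantFilter",
    "carrier_or",
    "collapse_test",
    "vc_score_test",
    "gene_burden",
    "BurdenReport",
]


@dataclass(frozen=True)
class CCRResult:
    """Case/control effect-allele frequency ratio for one variant."""

    value: float  # NaN when the variant is absent from cases (ignored)
    is_pseudo: bool  # control frequency was zero and was substituted
    ignored: bool  # zero case frequency: no ratio is reported


def ccr(
    maf_cases: float,
    maf_controls: float,
    min_nonzero_control_maf: float | None = None,
) -> CCRResult:
    """Case-control frequency ratio with the pseudo-CCR substitution rule.

    ``maf_controls == 0`` substitutes ``min_nonzero_control_maf`` in the
    denominator and flags the result as a pseudo-CCR; ``maf_cases == 0``
    yields the ignored sentinel (NaN value).
    """
    for name, maf in (("maf_cases", maf_cases), ("maf_controls", maf_controls)):
        if not 0.0 <= maf <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {maf}")
    if maf_cases == 0.0:
        return CCRResult(value=math.nan, is_pseudo=False, ignored=True)
    if maf_controls == 0.0:
        if min_nonzero_control_maf is None or min_nonzero_control_maf <= 0:
            raise ValueError(
                "pseudo-CCR needs a positive min_nonzero_control_maf "
                "(lowest nonzero control MAF of the analyzed variant set)"
            )
        return CCRResult(
            value=maf_cases / min_nonzero_control_maf, is_pseudo=True, ignored=False
        )
    return CCRResult(value=maf_cases / maf_controls, is_pseudo=False, ignored=False)


@dataclass(frozen=True)
class VariantFilter:
    """Qualifying-variant rule for burden collapsing.

    A variant qualifies when its impact class or its ClinVar class is in the
    allowed sets (union, mirroring a "high impact OR P/LP" rule) and its
    cohort-wide effect-allele frequency does not exceed ``maf_max``.
    """

    impact: frozenset[str] = frozenset({"high"})
    clinvar: frozenset[str] = frozenset({"P/LP"})
    maf_max: float = 0.01

    def qualifies(self, annot: VariantAnnotation, maf: float) -> bool:
        return (annot.impact in self.impact or annot.clinvar in self.clinvar) and (
            maf <= self.maf_max
        )


def _select_variants(
    geno: GenotypeMatrix,
    annotations: list[VariantAnnotation],
    gene: str | None,
    variant_filter: VariantFilter,
) -> np.ndarray:
    by_key = {
        (a.key.chrom, a.key.pos, a.key.ref, a.key.alt): a for a in annotations
    }
    maf = geno.alt_allele_freq()
    idx = []
    for j, v in enumerate(geno.variants):
        a = by_key.get((v.chrom, v.pos, v.ref, v.alt))
        if a is None or (gene is not None and a.gene != gene):
            continue
        if variant_filter.qualifies(a, maf[j]):
            idx.append(j)
    return np.array(idx, dtype=int)


def _carrier_table(
    geno: GenotypeMatrix, status: np.ndarray, variant_idx: np.ndarray
) -> tuple[int, int, int, int]:
    """(case carriers, control carriers, case non-carriers, control non-carriers)."""
    if len(variant_idx) == 0:
        carrier = np.zeros(geno.n_samples, dtype=bool)
    else:
        d = geno.dosage[:, variant_idx]
        carrier = np.nansum(np.nan_to_num(d), axis=1) > 0
    status = np.asarray(status).astype(bool)
    return (
        int((carrier & status).sum()),
        int((carrier & ~status).sum()),
        int((~carrier & status).sum()),
        int((~carrier & ~status).sum()),
    )


def carrier_or(
    geno: GenotypeMatrix,
    annotations: list[VariantAnnotation],
    cohort: CohortTable,
    gene: str,
    variant_filter: VariantFilter = VariantFilter(),
) -> OddsRatio:
    """Carrier odds ratio for a gene under a qualifying-variant filter.

    A carrier holds at least one alternate allele at any qualifying variant
    of the gene. The OR comes from the carrier 2x2 table with a Woolf CI
    (Haldane-Anscombe corrected and flagged when a cell is zero).
    """
    idx = _select_variants(geno, annotations, gene, variant_filter)
    if len(idx) == 0:
        raise ValueError(f"no qualifying variants in {gene} under the filter")
    a, b, c, d = _carrier_table(geno, cohort.status, idx)
    return odds_ratio_2x2(a, b, c, d)


def collapse_test(
    geno: GenotypeMatrix,
    annotations: list[VariantAnnotation],
    cohort: CohortTable,
    gene: str,
    variant_filter: VariantFilter = VariantFilter(),
) -> float:
    """Two-sided Fisher exact p-value on the gene's carrier 2x2 table."""
    idx = _select_variants(geno, annotations, gene, variant_filter)
    if len(idx) == 0:
        raise ValueError(f"no qualifying variants in {gene} under the filter")
    a, b, c, d = _carrier_table(geno, cohort.status, idx)
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


# ---------------------------------------------------------------------------
# Variance-component (SKAT-style) score test
# ---------------------------------------------------------------------------

def _liu_pvalue(q: float, lambdas: np.ndarray) -> float:
    """Liu et al. moment-matching tail probability for Q ~ sum_i l_i chi2_1.

    Matches the first moments/skewness/kurtosis of the mixture to a
    (noncentral) chi-square; exact when a single eigenvalue remains.
    """
    lambdas = lambdas[lambdas > 1e-12 * lambdas.max()]
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
    mu_x = df + delta
    sigma_x = math.sqrt(2 * (df + 2 * delta))
    t = (q - c1) / math.sqrt(2 * c2)
    if delta > 0:
        return float(ncx2.sf(t * sigma_x + mu_x, df, delta))
    return float(chi2.sf(t * sigma_x + mu_x, df))


def vc_score_test(
    dosage: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[float, float]:
    """Variance-component score test of a variant set against a binary trait.

    Fits the null logistic model (intercept plus optional covariates),
    forms ``Q = sum_j w_j^2 (g_j' (y - mu0))^2`` and evaluates its tail
    under the null mixture-of-chi-squares distribution via Liu
    moment matching (an approximation; no exact Davies inversion).

    Weights default to the usual Beta(1, 25) density of each variant's MAF,
    up-weighting the rarest variants. Returns ``(Q, p)``.
    """
    G = np.asarray(dosage, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    G = np.nan_to_num(G)  # missing treated as homozygous reference
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if m < 1:
        raise ValueError("variant set is empty")
    if weights is None:
        maf = G.mean(axis=0) / 2.0
        from scipy.stats import beta as beta_dist

        weights = beta_dist.pdf(np.minimum(maf, 1 - maf), 1, 25)
    w = np.asarray(weights, dtype=float)
    # Null model
    if covariates is None:
        mu = np.full(n, y.mean())
        X = np.ones((n, 1))
    else:
        from .evaluate import fit_logistic

        X = np.column_stack([np.ones(n), np.atleast_2d(covariates.T).T])
        fit = fit_logistic(y, np.atleast_2d(covariates.T).T, add_const=True)
        eta = X @ fit.beta
        mu = 1.0 / (1.0 + np.exp(-eta))
    v = mu * (1 - mu)
    if not (v > 0).any():
        raise ValueError("degenerate null model: fitted probabilities are 0/1")
    resid = y - mu
    score = (G * w).T @ resid
    q = float(score @ score)
    # Null distribution: eigenvalues of W G' P G W with P = V - VX(X'VX)^-1 X'V
    GW = G * w
    VG = GW * v[:, None]
    GtPG = GW.T @ VG
    XtVX = X.T @ (X * v[:, None])
    B = GW.T @ (X * v[:, None])
    GtPG -= B @ np.linalg.solve(XtVX, B.T)
    lambdas = np.linalg.eigvalsh((GtPG + GtPG.T) / 2)
    lambdas = lambdas[lambdas > 0]
    if lambdas.size == 0:
        return q, 1.0
    return q, _liu_pvalue(q, lambdas)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class BurdenReport:
    """Per-variant and per-gene burden summary."""

    variants: pd.DataFrame  # variant, gene, MAF_cases, MAF_controls, ccr, is_pseudo, ignored
    genes: pd.DataFrame  # gene, carrier counts, OR, CI, fisher p, CCRs, optional VC p
    min_nonzero_control_maf: float
    variant_filter: VariantFilter = field(default_factory=VariantFilter)


def gene_burden(
    geno: GenotypeMatrix,
    annotations: list[VariantAnnotation],
    cohort: CohortTable,
    genes: list[str] | None = None,
    variant_filter: VariantFilter = VariantFilter(),
    vc_test: bool = False,
) -> BurdenReport:
    """Full burden report over the qualifying variants of the given genes.

    Per-variant case/control frequencies and CCRs (pseudo where controls
    carry no copies, the denominator being the minimum nonzero control MAF
    over the analyzed set); per-gene carrier counts, Woolf carrier OR,
    Fisher collapsing p, and two gene-level CCR variants — the ratio of
    summed case/control allele counts (default headline) and the ratio of
    mean per-variant MAFs. ``vc_test`` adds the variance-component p.
    """
    status = cohort.status.astype(bool)
    by_key = {(a.key.chrom, a.key.pos, a.key.ref, a.key.alt): a for a in annotations}
    all_genes = genes or sorted({a.gene for a in annotations})
    sel = _select_variants(geno, annotations, None, variant_filter)
    sel = [
        j
        for j in sel
        if by_key[
            (
                geno.variants[j].chrom,
                geno.variants[j].pos,
                geno.variants[j].ref,
                geno.variants[j].alt,
            )
        ].gene
        in all_genes
    ]
    if not sel:
        raise ValueError("no qualifying variants for the requested genes")
    d = geno.dosage[:, np.array(sel)]
    case_an = 2.0 * (~np.isnan(d[status])).sum(axis=0)
    ctrl_an = 2.0 * (~np.isnan(d[~status])).sum(axis=0)
    case_ac = np.nansum(d[status], axis=0)
    ctrl_ac = np.nansum(d[~status], axis=0)
    maf_cases = np.divide(case_ac, case_an, out=np.zeros_like(case_ac), where=case_an > 0)
    maf_ctrl = np.divide(ctrl_ac, ctrl_an, out=np.zeros_like(ctrl_ac), where=ctrl_an > 0)
    nonzero = maf_ctrl[maf_ctrl > 0]
    min_ctrl_maf = float(nonzero.min()) if nonzero.size else float("nan")
    var_rows = []
    for k, j in enumerate(sel):
        v = geno.variants[j]
        a = by_key[(v.chrom, v.pos, v.ref, v.alt)]
        res = ccr(
            float(maf_cases[k]),
            float(maf_ctrl[k]),
            min_ctrl_maf if min_ctrl_maf > 0 else None,
        )
        var_rows.append(
            {
                "variant": str(v),
                "gene": a.gene,
                "impact": a.impact,
                "clinvar": a.clinvar,
                "maf_cases": float(maf_cases[k]),
                "maf_controls": float(maf_ctrl[k]),
                "ccr": res.value,
                "is_pseudo": res.is_pseudo,
                "ignored": res.ignored,
            }
        )
    variants_df = pd.DataFrame(var_rows)
    gene_rows = []
    for gene in all_genes:
        mask = variants_df["gene"].to_numpy() == gene
        if not mask.any():  # no qualifying variants: no row for this gene
            continue
        gidx = np.array(sel)[mask]
        a_, b_, c_, d_ = _carrier_table(geno, status, gidx)
        orr = odds_ratio_2x2(a_, b_, c_, d_)
        p_fisher = float(
            fisher_exact([[a_, b_], [c_, d_]], alternative="two-sided")[1]
        )
        g_case_ac, g_ctrl_ac = case_ac[mask].sum(), ctrl_ac[mask].sum()
        g_case_an, g_ctrl_an = case_an[mask].sum(), ctrl_an[mask].sum()
        # summed-allele-count CCR (headline) and mean-MAF CCR
        ccr_counts = (
            (g_case_ac / g_case_an) / (g_ctrl_ac / g_ctrl_an)
            if g_ctrl_ac > 0 and g_case_an > 0
            else float("nan")
        )
        mc, mm = maf_cases[mask].mean(), maf_ctrl[mask].mean()
        ccr_meanmaf = mc / mm if mm > 0 else float("nan")
        row = {
            "gene": gene,
            "case_carriers": a_,
            "control_carriers": b_,
            "n_cases": a_ + c_,
            "n_controls": b_ + d_,
            "carrier_or": orr.value,
            "carrier_or_ci_low": orr.ci[0],
            "carrier_or_ci_high": orr.ci[1],
            "or_corrected": orr.corrected,
            "fisher_p": p_fisher,
            "ccr_allele_counts": ccr_counts,
            "ccr_mean_maf": ccr_meanmaf,
        }
        if vc_test and len(gidx):
            _, p_vc = vc_score_test(geno.dosage[:, gidx], status.astype(float))
            row["vc_p"] = p_vc
        gene_rows.append(row)
    return BurdenReport(
        variants=variants_df,
        genes=pd.DataFrame(gene_rows),
        min_nonzero_control_maf=min_ctrl_maf,
        variant_filter=variant_filter,
    )
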