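"""Haplotype frequency estimation from unphased genotypes and case-control
haplotype association.

For a small set of k SNVs (k <= 10) the EM algorithm resolves phase
ambiguity under Hardy-Weinberg equilibrium: each sample's genotype vector is
compatible with a set of (unordered) haplotype pairs; the E-step weights
each compatible pair by the product of current haplotype frequencies, and
the M-step re-estimates frequencies from the expected pair counts. Missing
genotypes are marginalized (the compatible-pair set expands over both
alleles) rather than dropped. Haplotypes are reported as allele strings,
e.g. ``CCAAATT`` over seven SNVs.

The case-control test regresses case status on each sample's posterior
expected dosage of a target haplotype (computed under pooled frequencies),
a score-type association test that needs no phased data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .evaluate import fit_logistic
from .types import CohortTable, GenotypeMatrix

__all__ = [
    "HaplotypeTable",
    "em_haplotype_freq",
    "haplotype_cc_test",
    "haplotype_label",
]


def haplotype_label(hap: int, geno: GenotypeMatrix) -> str:
    """Allele-string label of a haplotype bitmask (bit j set = ALT at SNV j)."""
    return "".join(
        v.alt if (hap >> j) & 1 else v.ref for j, v in enumerate(geno.variants)
    )


def _label_to_mask(label: str, geno: GenotypeMatrix) -> int:
    """Parse an allele string into a haplotype bitmask."""
    if len(label) != len(geno.variants):
        raise ValueError(
            f"haplotype {label!r} has {len(label)} alleles for "
            f"{len(geno.variants)} SNVs"
        )
    mask = 0
    for j, (ch, v) in enumerate(zip(label, geno.variants)):
        if ch == v.alt:
            mask |= 1 << j
        elif ch != v.ref:
            raise ValueError(
                f"allele {ch!r} at SNV {j + 1} matches neither ref {v.ref!r} "
                f"nor alt {v.alt!r}"
            )
    return mask


def _compatible_pairs(gt: tuple) -> list[tuple[int, int]]:
    """Unordered haplotype pairs compatible with one genotype vector.

    Genotype codes per SNV: 0, 1, 2 or None (missing, marginalized over
    both alleles on both haplotypes).
    """
    per_site: list[list[tuple[int, int]]] = []
    for g in gt:
        if g is None:
            per_site.append([(0, 0), (0, 1), (1, 0), (1, 1)])
        elif g == 0:
            per_site.append([(0, 0)])
        elif g == 2:
            per_site.append([(1, 1)])
        else:
            per_site.append([(0, 1), (1, 0)])
    pairs: set[tuple[int, int]] = set()
    for combo in product(*per_site):
        h1 = h2 = 0
        for j, (a1, a2) in enumerate(combo):
            h1 |= a1 << j
            h2 |= a2 << j
        pairs.add((min(h1, h2), max(h1, h2)))
    return sorted(pairs)


@dataclass
class HaplotypeTable:
    """Converged EM haplotype frequency estimates for one sample group."""

    labels: list[str]  # lexicographically ordered haplotype strings
    frequencies: np.ndarray  # same order; sums to 1
    log_likelihood: float
    n_iter: int
    converged: bool

    def freq(self, label: str) -> float:
        try:
            return float(self.frequencies[self.labels.index(label)])
        except ValueError:
            return 0.0


def _em(
    geno: GenotypeMatrix, max_iter: int, tol: float
) -> tuple[dict[int, float], float, int, bool]:
    k = geno.n_variants
    if k > 10:
        raise ValueError(f"haplotype space 2^{k} too large; at most 10 SNVs")
    if np.isnan(geno.dosage).all(axis=0).any():
        raise ValueError("a haplotype SNV has no observed genotypes")
    # Group samples by genotype vector; enumerate compatible pairs once each.
    counts: dict[tuple, int] = {}
    for i in range(geno.n_samples):
        gt = tuple(
            None if np.isnan(d) else int(d) for d in geno.dosage[i]
        )
        counts[gt] = counts.get(gt, 0) + 1
    groups = [(c, _compatible_pairs(gt)) for gt, c in counts.items()]
    observed = sorted({h for _, pairs in groups for pair in pairs for h in pair})
    # uniform initialization over observed-compatible haplotypes; the
    # lexicographic (= numeric-mask within fixed SNV order) ordering makes
    # ties deterministic
    freq = {h: 1.0 / len(observed) for h in observed}
    n_total = geno.n_samples
    loglik = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        new = dict.fromkeys(observed, 0.0)
        loglik = 0.0
        for c, pairs in groups:
            probs = np.array(
                [
                    (1.0 if h1 == h2 else 2.0) * freq[h1] * freq[h2]
                    for h1, h2 in pairs
                ]
            )
            total = probs.sum()
            if total <= 0:
                continue
            loglik += c * np.log(total)
            w = probs / total
            for (h1, h2), wi in zip(pairs, w):
                new[h1] += c * wi
                new[h2] += c * wi
        freq_new = {h: v / (2 * n_total) for h, v in new.items()}
        delta = max(abs(freq_new[h] - freq[h]) for h in observed)
        freq = freq_new
        if delta < tol:
            converged = True
            break
    return freq, float(loglik), n_iter, converged


def em_haplotype_freq(
    geno: GenotypeMatrix, max_iter: int = 1000, tol: float = 1e-8
) -> HaplotypeTable:
    """EM haplotype frequency estimates from unphased genotype dosages.

    Converges when the largest frequency change falls below ``tol``; the
    log-likelihood is non-decreasing across iterations (a property asserted
    in the test suite). Non-convergence yields a warning, not an error.
    """
    freq, loglik, n_iter, converged = _em(geno, max_iter, tol)
    if not converged:
        import warnings

        warnings.warn(
            f"haplotype EM did not converge in {n_iter} iterations", stacklevel=2
        )
    # structural zeros (haplotypes compatible with some genotype but never
    # supported by the data) are dropped from the report
    keep = {h for h, f in freq.items() if f > 1e-12}
    labels = sorted(keep, key=lambda h: haplotype_label(h, geno))
    return HaplotypeTable(
        labels=[haplotype_label(h, geno) for h in labels],
        frequencies=np.array([freq[h] for h in labels]),
        log_likelihood=loglik,
        n_iter=n_iter,
        converged=converged,
    )


@dataclass
class HaplotypeCCResult:
    """Case-control association of one target haplotype."""

    target: str
    freq_cases: float
    freq_controls: float
    beta: float
    p: float
    cases_table: HaplotypeTable
    controls_table: HaplotypeTable


def expected_target_dosage(
    geno: GenotypeMatrix, target: str, freqs: HaplotypeTable
) -> np.ndarray:
    """Posterior expected copies of the target haplotype per sample."""
    mask = _label_to_mask(target, geno)
    fdict = {
        _label_to_mask(lbl, geno): f
        for lbl, f in zip(freqs.labels, freqs.frequencies)
    }
    out = np.empty(geno.n_samples)
    cache: dict[tuple, float] = {}
    for i in range(geno.n_samples):
        gt = tuple(None if np.isnan(d) else int(d) for d in geno.dosage[i])
        if gt not in cache:
            pairs = _compatible_pairs(gt)
            probs = np.array(
                [
                    (1.0 if h1 == h2 else 2.0)
                    * fdict.get(h1, 0.0)
                    * fdict.get(h2, 0.0)
                    for h1, h2 in pairs
                ]
            )
            total = probs.sum()
            if total <= 0:
                cache[gt] = 0.0
            else:
                copies = np.array(
                    [(h1 == mask) + (h2 == mask) for h1, h2 in pairs], dtype=float
                )
                cache[gt] = float((probs / total) @ copies)
        out[i] = cache[gt]
    return out


def haplotype_cc_test(
    geno: GenotypeMatrix,
    cohort: CohortTable,
    target: str,
    covariates: tuple[str, ...] | list[str] = (),
) -> HaplotypeCCResult:
    """Test a target haplotype for case-control frequency difference.

    Frequencies are estimated by EM separately in cases and controls; the
    p-value comes from a logistic regression of status on each sample's
    posterior expected target-haplotype dosage under pooled-cohort
    frequencies (optionally covariate adjusted). beta < 0 marks a
    protective haplotype.
    """
    if cohort.sample_ids != geno.sample_ids:
        raise ValueError("cohort and genotype sample ids differ")
    _label_to_mask(target, geno)  # validate spelling before estimating
    y = cohort.status
    cases = geno.subset_samples(np.flatnonzero(y == 1))
    controls = geno.subset_samples(np.flatnonzero(y == 0))
    table_cases = em_haplotype_freq(cases)
    table_controls = em_haplotype_freq(controls)
    f_ca, f_co = table_cases.freq(target), table_controls.freq(target)
    if f_ca == 0.0 and f_co == 0.0:
        raise ValueError(f"haplotype {target!r} absent from both groups")
    pooled = em_haplotype_freq(geno)
    dose = expected_target_dosage(geno, target, pooled)
    covar, covar_names = cohort.covariate_matrix(list(covariates))
    X = np.column_stack([dose, covar]) if covar.size else dose[:, None]
    fit = fit_logistic(y, X, names=["hap"] + covar_names)
    beta, _, _, p = fit.coef("hap")
    return HaplotypeCCResult(
        target=target,
        freq_cases=f_ca,
        freq_controls=f_co,
        beta=beta,
        p=p,
        cases_table=table_cases,
        controls_table=table_controls,
    )
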