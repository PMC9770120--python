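"""Synthetic case-control cohorts with the structure the analyses assume.

The generator emulates a multi-ancestry WGS case-control cohort:

* common genotypes under the Balding-Nichols model — an ancestral allele
  frequency per variant, per-ancestry frequencies Beta-distributed around it
  with a single Fst knob, genotypes binomial;
* a true polygenic liability (normal weights over the common variants) that
  drives case status through a logistic model together with age and sex
  effects mirroring the demographic imbalance of a hospital-recruited case
  series versus population-biobank controls (cases older and more often
  male); the intercept is tuned by bisection to the configured case
  fraction;
* rare variants with differential case/control carrier rates per gene,
  plus a planted control singleton so the minimum nonzero control MAF (the
  pseudo-CCR denominator) is well defined;
* a block of tightly linked SNVs whose genotypes are sums of two haplotypes
  drawn i.i.d. from group-specific pools — unphased multi-SNP structure for
  the EM machinery.

All generators are pure functions of (config, seed). The default cohort is
a 1:7 scaled version of the post-QC study cohort (145 cases / 860 controls,
six ancestry strata); ``SimConfig.full_scale()`` gives 1014 / 6009.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .prs import PRSVector, standardize
from .types import (
    CohortTable,
    GenotypeMatrix,
    ScoringFile,
    ScoringRecord,
    VariantAnnotation,
    VariantKey,
)

__all__ = [
    "SimConfig",
    "RareGeneSpec",
    "HaplotypeSpec",
    "sim_common_genotypes",
    "sim_phenotypes",
    "sim_rare_variants",
    "sim_haplotypes",
    "simulate_case_status",
    "scoring_file_from_weights",
    "write_fixture_set",
]

import pandas as pd


@dataclass(frozen=True)
class RareGeneSpec:
    """Planted rare-variant burden for one gene."""

    gene: str
    n_variants: int
    case_carrier_rate: float  # P(a case carries >= 1 qualifying allele in gene)
    control_carrier_rate: float
    impact: str = "high"
    clinvar: str = "none"


@dataclass(frozen=True)
class HaplotypeSpec:
    """Haplotype pool of a tightly linked SNV block.

    ``snvs`` are (rsid, allele_a, allele_b) triples; haplotype strings
    spell one allele per SNV. Frequencies are per group and sum to 1.
    """

    snvs: tuple[tuple[str, str, str], ...]
    pool: tuple[str, ...]
    case_freqs: tuple[float, ...]
    control_freqs: tuple[float, ...]
    chrom: str = "9"
    start_pos: int = 22_096_056

    def __post_init__(self) -> None:
        for name, f in (("case", self.case_freqs), ("control", self.control_freqs)):
            if len(f) != len(self.pool):
                raise ValueError(f"{name} frequencies do not match the pool")
            if abs(sum(f) - 1.0) > 1e-9:
                raise ValueError(f"{name} haplotype frequencies must sum to 1")
        for hap in self.pool:
            if len(hap) != len(self.snvs):
                raise ValueError(f"haplotype {hap!r} length != number of SNVs")


# 9p21-style block: seven SNVs, a protective all-"a" haplotype depleted in
# cases (0.17 vs 0.213) and a common risk haplotype with near-equal
# frequencies, plus two recombinants.
_DEFAULT_HAPLOTYPES = HaplotypeSpec(
    snvs=(
        ("rs1333040", "C", "T"),
        ("rs10757272", "C", "T"),
        ("rs4977574", "A", "G"),
        ("rs2891168", "A", "G"),
        ("rs1333042", "A", "G"),
        ("rs1333043", "T", "A"),
        ("rs1333045", "T", "C"),
    ),
    pool=("CCAAATT", "TTGGGAC", "CCAAGAC", "TTGGATT"),
    case_freqs=(0.17, 0.41, 0.25, 0.17),
    control_freqs=(0.213, 0.40, 0.23, 0.157),
)

# Carrier rates chosen to plant the lipid-gene burden excess reported for
# hospital CHD cases: LDLR ~9/1014 case carriers vs ~9/6009 in controls,
# APOB / ANGPTL4 similar excess, PCSK9 a milder one. The CTRL_SINGLETON
# gene exists solely to guarantee one control-only singleton variant.
_DEFAULT_RARE_GENES = (
    RareGeneSpec("LDLR", 7, 9 / 1014, 9 / 6009, impact="high", clinvar="P/LP"),
    RareGeneSpec("APOB", 6, 0.0089, 0.0020, impact="high"),
    RareGeneSpec("PCSK9", 5, 0.0036, 0.0020, impact="high"),
    RareGeneSpec("ANGPTL4", 4, 0.0089, 0.0015, impact="high"),
)

_ANCESTRIES = ("Gulf", "Persian", "Q-AFR", "Levant", "Admixed", "Q-SAS")
_MIXING = (0.5565, 0.3155, 0.049, 0.041, 0.022, 0.016)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the target cohort at one-seventh scale: 145 cases and
    860 controls across six ancestry strata with Fst 0.05 differentiation,
    a true polygenic effect of ln(1.8) per liability SD, and the observed
    age/sex imbalance (cases older and more often male).
    """

    n_cases: int = 145
    n_controls: int = 860
    n_common_variants: int = 500
    ancestries: tuple[str, ...] = _ANCESTRIES
    mixing: tuple[float, ...] = _MIXING
    fst: float = 0.05
    prs_beta: float = float(np.log(1.8))  # log-OR per SD of true liability
    age_beta: float = 1.0  # log-OR per SD of age
    sex_beta: float = 0.55  # log-OR for male sex
    n_pcs: int = 4
    missing_rate: float = 0.0
    rare_genes: tuple[RareGeneSpec, ...] = _DEFAULT_RARE_GENES
    plant_control_singletons: bool = True
    haplotypes: HaplotypeSpec = field(default_factory=lambda: _DEFAULT_HAPLOTYPES)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixing) - 1.0) > 1e-9:
            raise ValueError("ancestry mixing proportions must sum to 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie strictly in (0, 1)")
        for spec in self.rare_genes:
            for r in (spec.case_carrier_rate, spec.control_carrier_rate):
                if not 0.0 <= r <= 1.0:
                    raise ValueError("carrier rates must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_samples

    def full_scale(self) -> "SimConfig":
        """The cohort at its full post-QC size (1014 cases / 6009 controls)."""
        return replace(self, n_cases=1014, n_controls=6009)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "rare_genes" in raw:
            raw["rare_genes"] = tuple(RareGeneSpec(**g) for g in raw["rare_genes"])
        if "haplotypes" in raw:
            h = raw["haplotypes"]
            for k in ("snvs", "pool", "case_freqs", "control_freqs"):
                if k in h:
                    h[k] = tuple(tuple(x) if isinstance(x, list) else x for x in h[k])
            raw["haplotypes"] = HaplotypeSpec(**h)
        for k in ("ancestries", "mixing"):
            if k in raw:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def _rng(config: SimConfig, tag: int, seed: int | None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng([int(base), tag])


# ---------------------------------------------------------------------------
# Common variants: Balding-Nichols structure
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_alleles(rng: np.random.Generator, m: int) -> list[tuple[str, str]]:
    ref = rng.integers(0, 4, size=m)
    alt = (ref + rng.integers(1, 4, size=m)) % 4
    return [(str(_BASES[r]), str(_BASES[a])) for r, a in zip(ref, alt)]


def sim_common_genotypes(
    config: SimConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Simulate structured common genotypes under the Balding-Nichols model.

    Per variant an ancestral frequency p ~ Uniform(0.05, 0.95); each
    ancestry draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) and
    genotypes are Binomial(2, freq). Returns ``(genotypes, per-ancestry
    true frequencies with shape (n_ancestries, n_variants), ancestry label
    per sample)``.
    """
    rng = _rng(config, 1, seed)
    n, m = config.n_samples, config.n_common_variants
    n_anc = len(config.ancestries)
    ancestry_idx = rng.choice(n_anc, size=n, p=np.asarray(config.mixing))
    p_anc = rng.uniform(0.05, 0.95, size=m)
    f = config.fst
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    freqs = rng.beta(a[None, :], b[None, :], size=(n_anc, m))
    dosage = rng.binomial(2, freqs[ancestry_idx]).astype(float)
    if config.missing_rate > 0:
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan
    alleles = _random_alleles(rng, m)
    variants = [
        VariantKey("1", 10_000 * (j + 1), ref, alt, rsid=f"rs{900000 + j}")
        for j, (ref, alt) in enumerate(alleles)
    ]
    sample_ids = [f"S{i:05d}" for i in range(n)]
    geno = GenotypeMatrix(sample_ids, variants, dosage)
    labels = np.array([config.ancestries[i] for i in ancestry_idx])
    return geno, freqs, labels


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_case_status(
    eta: np.ndarray,
    case_fraction: float,
    rng: np.random.Generator,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Draw case status from a logistic model with a bisected intercept.

    Finds b0 such that ``mean(sigmoid(b0 + eta))`` equals ``case_fraction``
    (within ``tol``), then draws Bernoulli status. Returns (status, b0).
    The expected case fraction is exact to tolerance; the realized count
    fluctuates binomially.
    """
    lo, hi = -30.0, 30.0

    def frac(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))))

    if not frac(lo) <= case_fraction <= frac(hi):
        raise ValueError(f"case fraction {case_fraction} unattainable")
    for _ in range(200):
        mid = (lo + hi) / 2
        if frac(mid) < case_fraction:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 or abs(frac(mid) - case_fraction) < tol:
            break
    b0 = (lo + hi) / 2
    p = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    return (rng.random(len(eta)) < p).astype(int), b0


def sim_phenotypes(
    geno: GenotypeMatrix,
    config: SimConfig,
    ancestry: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[CohortTable, PRSVector, np.ndarray]:
    """Simulate phenotypes and covariates on top of a genotype matrix.

    True PRS weights are N(0, 1/n_variants); the standardized weighted
    dosage sum is the liability score entering a logistic disease model
    together with age and sex effects. Ages and sexes are drawn from one
    population and become imbalanced between cases and controls through the
    model itself. Principal components are computed from the centered
    dosage matrix. Returns (cohort, true standardized PRS, true weights).
    """
    rng = _rng(config, 2, seed)
    n, m = geno.n_samples, geno.n_variants
    w = rng.normal(0.0, 1.0 / np.sqrt(m), size=m)
    raw = np.nan_to_num(geno.dosage) @ w
    true_prs = standardize(
        PRSVector("TruePRS", list(geno.sample_ids), raw)
    )
    age = np.clip(rng.normal(48.0, 13.0, size=n), 20.0, 85.0)
    age_z = (age - age.mean()) / age.std(ddof=1)
    male = rng.random(n) < 0.47
    bmi = np.clip(rng.normal(29.0, 5.5, size=n), 15.0, 55.0)
    t2d = (rng.random(n) < 1.0 / (1.0 + np.exp(-(-1.8 + 0.9 * age_z)))).astype(int)
    eta = (
        config.prs_beta * true_prs.z
        + config.age_beta * age_z
        + config.sex_beta * male
    )
    status, _ = simulate_case_status(eta, config.case_fraction, rng)
    x = geno.dosage - np.nanmean(geno.dosage, axis=0)
    x = np.nan_to_num(x)
    n_pcs = min(config.n_pcs, min(x.shape) - 1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    df = pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "status": status,
            "age": np.round(age, 1),
            "sex": np.where(male, "male", "female"),
            "bmi": np.round(bmi, 1),
            "ancestry": ancestry if ancestry is not None else "Gulf",
            "t2d": t2d,
        }
    )
    for k in range(n_pcs):
        df[f"pc{k + 1}"] = pcs[:, k]
    return CohortTable(df), true_prs, w


# ---------------------------------------------------------------------------
# Rare variants
# ---------------------------------------------------------------------------

_GENE_CHROM = {
    "LDLR": ("19", 11_089_000),
    "APOB": ("2", 21_001_000),
    "PCSK9": ("1", 55_039_000),
    "ANGPTL4": ("19", 8_429_000),
}


def sim_rare_variants(
    config: SimConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, list[VariantAnnotation], np.ndarray]:
    """Plant rare heterozygous variants with differential case/control burden.

    Samples are ordered cases first (``n_cases``) then controls; each gene's
    group carrier rate is split evenly over its variants and carriers drawn
    Bernoulli (rare variants are modelled as heterozygous). When
    ``plant_control_singletons`` is set, a ``CTRL_SINGLETON`` gene holding
    exactly one control singleton (and no case alleles) is appended, so the
    minimum nonzero control MAF of the analyzed set is always defined.
    Returns (genotypes, annotations, status).
    """
    rng = _rng(config, 3, seed)
    n_ca, n_co = config.n_cases, config.n_controls
    n = n_ca + n_co
    status = np.concatenate([np.ones(n_ca, int), np.zeros(n_co, int)])
    cols: list[np.ndarray] = []
    variants: list[VariantKey] = []
    annots: list[VariantAnnotation] = []
    for gi, spec in enumerate(config.rare_genes):
        chrom, base = _GENE_CHROM.get(spec.gene, (str(10 + gi), 5_000_000 * (gi + 1)))
        alleles = _random_alleles(rng, spec.n_variants)
        for vi in range(spec.n_variants):
            col = np.zeros(n)
            col[:n_ca] = rng.random(n_ca) < spec.case_carrier_rate / spec.n_variants
            col[n_ca:] = rng.random(n_co) < spec.control_carrier_rate / spec.n_variants
            ref, alt = alleles[vi]
            key = VariantKey(chrom, base + 150 * vi, ref, alt)
            variants.append(key)
            annots.append(
                VariantAnnotation(
                    key=key, gene=spec.gene, impact=spec.impact, clinvar=spec.clinvar
                )
            )
            cols.append(col)
    if config.plant_control_singletons:
        col = np.zeros(n)
        col[n_ca + int(rng.integers(n_co))] = 1.0
        key = VariantKey("6", 160_500_000, "G", "A")
        variants.append(key)
        annots.append(
            VariantAnnotation(key=key, gene="CTRL_SINGLETON", impact="high")
        )
        cols.append(col)
    sample_ids = [f"S{i:05d}" for i in range(n)]
    return (
        GenotypeMatrix(sample_ids, variants, np.column_stack(cols)),
        annots,
        status,
    )


# ---------------------------------------------------------------------------
# Haplotype blocks
# ---------------------------------------------------------------------------

def sim_haplotypes(
    config: SimConfig, seed: int | None = None
) -> tuple[GenotypeMatrix, dict[str, dict[str, float]], np.ndarray]:
    """Draw two haplotypes per sample from group-specific pools.

    Phase is discarded: genotypes are the per-SNV sums of the two drawn
    haplotypes' alternate alleles. Returns (genotypes, true frequencies
    per group keyed ``"case"``/``"control"``, status).
    """
    rng = _rng(config, 4, seed)
    spec = config.haplotypes
    n_ca, n_co = config.n_cases, config.n_controls
    status = np.concatenate([np.ones(n_ca, int), np.zeros(n_co, int)])
    k = len(spec.snvs)
    # allele "a" of each SNV is the reference allele; haplotype strings map
    # to binary alt-allele vectors
    hap_bits = np.array(
        [
            [0 if hap[j] == spec.snvs[j][1] else 1 for j in range(k)]
            for hap in spec.pool
        ]
    )
    for hap, bits in zip(spec.pool, hap_bits):
        for j, bit in enumerate(bits):
            if bit == 1 and hap[j] != spec.snvs[j][2]:
                raise ValueError(
                    f"haplotype {hap!r} allele {hap[j]!r} at SNV {j + 1} matches "
                    "neither configured allele"
                )
    draws_case = rng.choice(len(spec.pool), size=(n_ca, 2), p=np.asarray(spec.case_freqs))
    draws_ctrl = rng.choice(
        len(spec.pool), size=(n_co, 2), p=np.asarray(spec.control_freqs)
    )
    draws = np.vstack([draws_case, draws_ctrl])
    dosage = (hap_bits[draws[:, 0]] + hap_bits[draws[:, 1]]).astype(float)
    variants = [
        VariantKey(spec.chrom, spec.start_pos + 1000 * j, a, b, rsid=rsid)
        for j, (rsid, a, b) in enumerate(spec.snvs)
    ]
    sample_ids = [f"S{i:05d}" for i in range(n_ca + n_co)]
    true = {
        "case": dict(zip(spec.pool, spec.case_freqs)),
        "control": dict(zip(spec.pool, spec.control_freqs)),
    }
    return GenotypeMatrix(sample_ids, variants, dosage), true, status


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def scoring_file_from_weights(
    geno: GenotypeMatrix,
    weights: np.ndarray,
    pgs_id: str,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ScoringFile:
    """Build a scoring file from per-variant weights (optionally noised)."""
    w = np.asarray(weights, dtype=float)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        w = w + rng.normal(0.0, noise_sd, size=len(w))
    records = [
        ScoringRecord(
            effect_allele=v.alt,
            other_allele=v.ref,
            weight=float(w[j]),
            chrom=v.chrom,
            pos=v.pos,
            rsid=v.rsid,
        )
        for j, v in enumerate(geno.variants)
    ]
    return ScoringFile(pgs_id=pgs_id, records=records)


def write_fixture_set(config: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a full cohort and write every fixture file format.

    Emits the common-variant VCF, cohort TSV, two scoring files (the true
    weights and a noised copy), the rare-variant VCF with its annotation
    TSV, the haplotype-block VCF, and a known-loci TSV built from a sample
    of common-variant positions. Returns the path of each artifact.
    """
    from .io import (
        write_annotations,
        write_cohort_table,
        write_known_loci,
        write_scoring_file,
        write_vcf,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geno, _freqs, ancestry = sim_common_genotypes(config)
    cohort, _true_prs, w = sim_phenotypes(geno, config, ancestry=ancestry)
    rng = np.random.default_rng([config.seed, 5])
    paths = {"vcf": out / "common.vcf", "cohort": out / "cohort.tsv"}
    write_vcf(geno, paths["vcf"])
    write_cohort_table(cohort, paths["cohort"])
    for name, noise in (("PGS_SIM001", 0.0), ("PGS_SIM002", 0.02)):
        sf = scoring_file_from_weights(geno, w, name, noise_sd=noise, rng=rng)
        paths[name] = out / f"{name}.txt"
        write_scoring_file(sf, paths[name])
    rare_geno, annots, _status = sim_rare_variants(config)
    paths["rare_vcf"] = out / "rare.vcf"
    paths["annotations"] = out / "annotations.tsv"
    write_vcf(rare_geno, paths["rare_vcf"])
    write_annotations(annots, paths["annotations"])
    hap_geno, _true, _status = sim_haplotypes(config)
    paths["haplo_vcf"] = out / "haplo.vcf"
    write_vcf(hap_geno, paths["haplo_vcf"])
    pick = rng.choice(geno.n_variants, size=min(20, geno.n_variants), replace=False)
    catalog = pd.DataFrame(
        {
            "CHR": [geno.variants[j].chrom for j in pick],
            "POS": [geno.variants[j].pos for j in pick],
            "RSID": [geno.variants[j].rsid for j in pick],
            "LOCUS": [f"LOCUS{i + 1}" for i in range(len(pick))],
        }
    )
    paths["known_loci"] = out / "known_loci.tsv"
    write_known_loci(catalog, paths["known_loci"])
    return paths
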