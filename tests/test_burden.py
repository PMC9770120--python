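"""CCR/pseudo-CCR, carrier collapsing, and the variance-component test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, hypergeom

import prscohort as pc
from prscohort.burden import VariantFilter, _carrier_table
from prscohort.simulate import SimConfig, sim_rare_variants
from prscohort.types import GenotypeMatrix, VariantAnnotation, VariantKey

from conftest import minimal_cohort


class TestCCR:
    def test_simple_ratio(self):
        res = pc.ccr(0.02, 0.01)
        assert res.value == pytest.approx(2.0)
        assert not res.is_pseudo and not res.ignored

    def test_pseudo_substitution(self):
        """Case allele count 2/2028, zero in controls, control-singleton
        denominator 1/12018 -> pseudo-CCR ~ 11.85."""
        res = pc.ccr(2 / (2 * 1014), 0.0, 1 / (2 * 6009))
        assert res.is_pseudo
        assert res.value == pytest.approx(11.85, abs=0.01)

    def test_pseudo_family(self):
        """3 and 4 case alleles give the ~17.8 / 23.7 pseudo-CCR family
        (exact values scale the doubleton's 11.85 by 1.5 and 2)."""
        doubleton = pc.ccr(2 / 2028, 0.0, 1 / 12018).value
        assert pc.ccr(3 / 2028, 0.0, 1 / 12018).value == pytest.approx(
            1.5 * doubleton, rel=1e-12
        )
        assert pc.ccr(4 / 2028, 0.0, 1 / 12018).value == pytest.approx(23.70, abs=0.01)

    def test_zero_case_maf_ignored(self):
        res = pc.ccr(0.0, 0.01)
        assert res.ignored and math.isnan(res.value)

    def test_missing_denominator_errors(self):
        with pytest.raises(ValueError, match="min_nonzero_control_maf"):
            pc.ccr(0.01, 0.0)
        with pytest.raises(ValueError):
            pc.ccr(1.5, 0.1)

    @given(
        st.floats(0.001, 0.5), st.floats(0.001, 0.5)
    )
    @settings(derandomize=True, max_examples=50)
    def test_reciprocal_product(self, a, b):
        assert pc.ccr(a, b).value * pc.ccr(b, a).value == pytest.approx(1.0)


def _burden_fixture(case_carriers, ctrl_carriers, n_cases, n_controls,
                    gene="LDLR", impact="high", clinvar="P/LP"):
    """Single-variant gene with exact carrier counts."""
    n = n_cases + n_controls
    dosage = np.zeros((n, 1))
    dosage[:case_carriers, 0] = 1
    dosage[n_cases:n_cases + ctrl_carriers, 0] = 1
    key = VariantKey("19", 11_089_000, "G", "A")
    geno = GenotypeMatrix([f"S{i:05d}" for i in range(n)], [key], dosage)
    annots = [VariantAnnotation(key=key, gene=gene, impact=impact, clinvar=clinvar)]
    status = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    return geno, annots, minimal_cohort(status)


class TestCarrierOR:
    def test_printed_counts(self):
        """9 carriers among 1014 cases, 9 among 6009 controls -> OR ~ 5.97."""
        geno, annots, cohort = _burden_fixture(9, 9, 1014, 6009)
        orr = pc.carrier_or(geno, annots, cohort, "LDLR")
        assert orr.value == pytest.approx(5.97, abs=0.005)

    def test_equal_rates_unit_or(self):
        geno, annots, cohort = _burden_fixture(5, 20, 100, 400)
        filt = VariantFilter(maf_max=0.5)  # carrier freq 5% exceeds the rare default
        assert pc.carrier_or(
            geno, annots, cohort, "LDLR", filt
        ).value == pytest.approx(1.0)

    def test_no_qualifying_variant_errors(self):
        geno, annots, cohort = _burden_fixture(5, 20, 100, 400)
        with pytest.raises(ValueError, match="no qualifying"):
            pc.carrier_or(geno, annots, cohort, "LDLR",
                          VariantFilter(maf_max=1e-6))

    def test_matches_enumeration_oracle(self, rng):
        """Random multi-variant fixture: carrier table equals per-sample
        exhaustive enumeration."""
        n = 80
        keys = [VariantKey("19", 1000 + i, "G", "A") for i in range(5)]
        dosage = rng.choice([0.0, 0.0, 0.0, 1.0, np.nan], size=(n, 5),
                            p=[0.5, 0.2, 0.15, 0.1, 0.05])
        geno = GenotypeMatrix([f"S{i}" for i in range(n)], keys, dosage)
        status = (rng.random(n) < 0.3).astype(int)
        expected_carriers = [
            any(d == 1.0 for d in row if not np.isnan(d)) for row in dosage
        ]
        a = sum(c and s for c, s in zip(expected_carriers, status))
        b = sum(c and not s for c, s in zip(expected_carriers, status))
        c_ = sum((not c) and s for c, s in zip(expected_carriers, status))
        d_ = sum((not c) and (not s) for c, s in zip(expected_carriers, status))
        assert _carrier_table(geno, status, np.arange(5)) == (a, b, c_, d_)

    def test_carrier_counts_monotone_in_filter(self):
        """Relaxing the qualifying filter never loses carriers."""
        cfg = SimConfig(seed=5)
        geno, annots, status = sim_rare_variants(cfg)
        cohort = minimal_cohort(status)
        strict = VariantFilter(impact=frozenset({"high"}),
                               clinvar=frozenset({"P/LP"}), maf_max=0.001)
        loose = VariantFilter(impact=frozenset({"high", "moderate", "low"}),
                              clinvar=frozenset({"P/LP", "VUS"}), maf_max=0.05)
        for gene in ("LDLR", "APOB"):
            t_strict = pc.carrier_or(geno, annots, cohort, gene, strict).table
            t_loose = pc.carrier_or(geno, annots, cohort, gene, loose).table
            assert t_loose[0] >= t_strict[0] and t_loose[1] >= t_strict[1]


class TestCollapseTest:
    def test_printed_counts_significant(self):
        geno, annots, cohort = _burden_fixture(9, 9, 1014, 6009)
        p = pc.collapse_test(geno, annots, cohort, "LDLR")
        assert p < 0.001
        # independent oracle: two-sided Fisher = sum of hypergeometric
        # probabilities not exceeding the observed table's
        rv = hypergeom(7023, 18, 1014)  # N, total carriers, cases drawn
        probs = rv.pmf(np.arange(0, 19))
        expected = probs[probs <= rv.pmf(9) * (1 + 1e-7)].sum()
        assert p == pytest.approx(expected, rel=1e-6)

    def test_equal_rates_maximal_p(self):
        geno, annots, cohort = _burden_fixture(5, 20, 100, 400)
        p = pc.collapse_test(geno, annots, cohort, "LDLR",
                             VariantFilter(maf_max=0.5))
        assert p == pytest.approx(1.0)

    def test_null_calibration_conservative(self, rng):
        """Exact test never exceeds nominal size under the null."""
        rej = 0
        n_reps = 300
        for _ in range(n_reps):
            geno, annots, cohort = _burden_fixture(
                int(rng.binomial(200, 0.02)), int(rng.binomial(800, 0.02)), 200, 800
            )
            p = pc.collapse_test(geno, annots, cohort, "LDLR",
                                 VariantFilter(maf_max=0.5))
            rej += p < 0.05
        assert rej / n_reps <= 0.07


class TestVcScoreTest:
    def test_single_variant_reduces_to_chi2_score_test(self, rng):
        """One variant: Q/lambda is the classical 1-df score statistic."""
        n = 300
        g = rng.binomial(2, 0.1, size=n).astype(float)
        y = (rng.random(n) < 0.3).astype(float)
        q, p = pc.vc_score_test(g, y, weights=np.array([1.0]))
        mu = y.mean()
        v = mu * (1 - mu)
        u = g @ (y - mu)
        var_u = v * (g @ g - g.sum() ** 2 / n)
        assert q == pytest.approx(u**2, abs=1e-10)
        assert p == pytest.approx(float(chi2.sf(u**2 / var_u, 1)), abs=1e-10)

    def test_planted_signal_matches_permutation_oracle(self, rng):
        """p within 2-fold of a 10,000-permutation p on a planted burden."""
        n = 400
        G = rng.binomial(2, 0.03, size=(n, 6)).astype(float)
        risk = G[:, :3].sum(axis=1)
        y = (rng.random(n) < 1 / (1 + np.exp(1.2 - 1.0 * risk))).astype(float)
        w = np.ones(6)
        q_obs, p_analytic = pc.vc_score_test(G, y, weights=w)
        perm_q = np.empty(10_000)
        for b in range(10_000):
            yp = rng.permutation(y)
            resid = yp - yp.mean()
            perm_q[b] = ((G * w).T @ resid) @ ((G * w).T @ resid)
        p_perm = (1 + (perm_q >= q_obs).sum()) / (1 + 10_000)
        assert p_analytic == pytest.approx(p_perm, rel=1.0)  # within 2-fold

    def test_covariate_adjusted_runs(self, rng):
        n = 500
        G = rng.binomial(2, 0.05, size=(n, 4)).astype(float)
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x + 1))).astype(float)
        _, p = pc.vc_score_test(G, y, covariates=x[:, None])
        assert 0 <= p <= 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            pc.vc_score_test(np.empty((10, 0)), np.zeros(10))


class TestGeneBurden:
    def test_report_on_simulated_cohort(self):
        cfg = SimConfig(seed=3).full_scale()
        geno, annots, status = sim_rare_variants(cfg)
        cohort = minimal_cohort(status)
        rep = pc.gene_burden(geno, annots, cohort, vc_test=True)
        genes = rep.genes.set_index("gene")
        assert genes.loc["LDLR", "carrier_or"] > 1
        assert genes.loc["LDLR", "fisher_p"] < 0.05
        assert rep.min_nonzero_control_maf == pytest.approx(1 / (2 * 6009), rel=0.2)
        pseudo = rep.variants[rep.variants["is_pseudo"]]
        assert (pseudo["maf_controls"] == 0).all()
        assert rep.variants["maf_cases"].between(0, 1).all()
        assert set(rep.genes["vc_p"].dropna().between(0, 1)) <= {True}

    def test_null_median_ccr_near_one(self, rng):
        """Equal-frequency common variants: per-variant CCR medians ~ 1."""
        n_ca, n_co, m = 700, 700, 60
        dosage = rng.binomial(2, 0.08, size=(n_ca + n_co, m)).astype(float)
        keys = [VariantKey("2", 1000 + j, "G", "A") for j in range(m)]
        geno = GenotypeMatrix([f"S{i}" for i in range(n_ca + n_co)], keys, dosage)
        annots = [
            VariantAnnotation(key=k, gene="NULLGENE", impact="high") for k in keys
        ]
        status = np.concatenate([np.ones(n_ca, int), np.zeros(n_co, int)])
        rep = pc.gene_burden(
            geno, annots, minimal_cohort(status),
            variant_filter=VariantFilter(maf_max=1.0),
        )
        med = rep.variants["ccr"].median()
        assert 0.85 <= med <= 1.18
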