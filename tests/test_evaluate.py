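"""Association and discrimination metrics: logistic fits, DeLong, deciles,
matching."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

import prscohort as pc
from prscohort.evaluate import SeparationError, _decile_assign
from prscohort.prs import PRSVector
from prscohort.simulate import simulate_case_status

from conftest import minimal_cohort


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        y = np.array([0, 1] * 25)
        fit = pc.fit_logistic(y, np.empty((50, 0)), names=[])
        assert fit.beta[0] == pytest.approx(0, abs=1e-8)

    def test_two_by_two_closed_form(self):
        """Binary-predictor slope equals the log cross-product-ratio: the
        carrier table (9, 1005, 9, 6000) gives ln(5.97) ~ 1.787."""
        y = np.concatenate([np.ones(9 + 1005), np.zeros(9 + 6000)])
        x = np.concatenate([np.ones(9), np.zeros(1005), np.ones(9), np.zeros(6000)])
        fit = pc.fit_logistic(y, x[:, None], names=["carrier"])
        expected = np.log((9 * 6000) / (1005 * 9))
        assert fit.coef("carrier")[0] == pytest.approx(expected, abs=1e-6)
        assert expected == pytest.approx(1.787, abs=5e-4)

    def test_matches_direct_likelihood_maximizer(self, rng):
        """Coefficients agree with scipy.optimize on the Bernoulli log-lik."""
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        beta_true = np.array([-1.0, 0.8, -0.5])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)

        def nll(b):
            eta = X @ b
            return np.sum(np.log1p(np.exp(eta)) - y * eta)

        ref = minimize(nll, np.zeros(3), method="BFGS", tol=1e-12).x
        fit = pc.fit_logistic(y, X[:, 1:], names=["a", "b"])
        np.testing.assert_allclose(fit.beta, ref, atol=1e-6)

    def test_perfect_separation_raises(self):
        y = np.array([0] * 20 + [1] * 20, dtype=float)
        x = np.arange(40, dtype=float)
        with pytest.raises(SeparationError):
            pc.fit_logistic(y, x[:, None])

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank"):
            pc.fit_logistic((x > 0).astype(float), np.column_stack([x, 2 * x]))


class TestAucDelong:
    def test_perfect_separation(self):
        auc, _, _ = pc.auc_delong(np.array([3.0, 4.0]), np.array([1.0, 2.0]))
        assert auc == 1.0

    def test_hand_counted_pairs(self):
        # cases {3,5} vs controls {1,2,4}: 5 of 6 pairs won
        auc, _, _ = pc.auc_delong(np.array([3.0, 5.0]), np.array([1.0, 2.0, 4.0]))
        assert auc == pytest.approx(5 / 6)

    def test_matches_pair_counting_oracle(self, rng):
        """AUC equals brute-force pair counting with half-credit ties."""
        cases = np.round(rng.normal(size=40), 1)  # rounding induces ties
        controls = np.round(rng.normal(size=60), 1)
        auc, _, _ = pc.auc_delong(cases, controls)
        wins = sum(
            1.0 if c > d else (0.5 if c == d else 0.0)
            for c in cases
            for d in controls
        )
        assert auc == pytest.approx(wins / (40 * 60), abs=1e-12)

    def test_variance_close_to_bootstrap(self, rng):
        cases = rng.normal(0.5, 1, size=50)
        controls = rng.normal(0, 1, size=50)
        _, var, _ = pc.auc_delong(cases, controls)
        pairwise = (cases[:, None] > controls[None, :]).astype(float)
        pairwise += 0.5 * (cases[:, None] == controls[None, :])
        boots = np.empty(10_000)
        for b in range(10_000):
            ci = rng.integers(0, 50, 50)
            di = rng.integers(0, 50, 50)
            boots[b] = pairwise[np.ix_(ci, di)].mean()
        assert var == pytest.approx(boots.var(ddof=1), rel=0.10)

    def test_label_flip_complements_auc(self, rng):
        cases = rng.normal(0.8, 1, 30)
        controls = rng.normal(0, 1, 70)
        auc, _, _ = pc.auc_delong(cases, controls)
        flipped, _, _ = pc.auc_delong(controls, cases)
        assert flipped == pytest.approx(1 - auc, abs=1e-12)

    def test_empty_class_errors(self):
        with pytest.raises(ValueError):
            pc.auc_delong(np.array([]), np.array([1.0]))


class TestDelongPaired:
    def test_identical_scores(self, rng):
        s = rng.normal(size=100)
        labels = rng.random(100) < 0.4
        z, p = pc.delong_paired_test(s, s, labels)
        assert z == 0.0 and p == 1.0

    def test_perfect_vs_random_extreme(self, rng):
        n = 500
        labels = np.concatenate([np.ones(250, bool), np.zeros(250, bool)])
        perfect = labels.astype(float) + rng.normal(scale=1e-3, size=n)
        random_scores = rng.normal(size=n)
        _, p = pc.delong_paired_test(perfect, random_scores, labels)
        assert p < 1e-6


class TestOrPerSd:
    def _fit(self, z, status, covariates=()):
        cohort = minimal_cohort(status)
        prs = pc.standardize(PRSVector("T", cohort.sample_ids, z))
        return pc.or_per_sd(prs, cohort, covariates=covariates)

    def test_null_ci_coverage(self, rng):
        """Under no association the 95% CI covers OR=1 at ~95%."""
        cover = 0
        n_reps = 200
        for _ in range(n_reps):
            z = rng.normal(size=2000)
            status = (rng.random(2000) < 0.15).astype(int)
            rep = self._fit(z, status)
            cover += rep.or_1sd_ci[0] <= 1.0 <= rep.or_1sd_ci[1]
        assert 0.91 <= cover / n_reps <= 0.985

    def test_reciprocal_symmetry(self, rng):
        z = rng.normal(size=1000)
        status, _ = simulate_case_status(0.6 * z, 0.2, rng)
        cohort = minimal_cohort(status)
        fwd = pc.or_per_sd(pc.standardize(PRSVector("T", cohort.sample_ids, z)), cohort)
        rev = pc.or_per_sd(pc.standardize(PRSVector("T", cohort.sample_ids, -z)), cohort)
        assert rev.or_1sd == pytest.approx(1 / fwd.or_1sd, abs=1e-6)

    def test_uncorrelated_covariate_leaves_or(self, rng):
        n = 4000
        z = rng.normal(size=n)
        status, _ = simulate_case_status(np.log(1.8) * z, 1 / 7, rng)
        cohort = minimal_cohort(status, noise=rng.normal(size=n))
        prs = pc.standardize(PRSVector("T", cohort.sample_ids, z))
        plain = pc.or_per_sd(prs, cohort)
        adjusted = pc.or_per_sd(prs, cohort, covariates=("noise",))
        assert adjusted.or_1sd == pytest.approx(plain.or_1sd, rel=0.05)

    def test_full_model_auc_dominates_prs_auc(self, small_cohort, true_scoring):
        """With age/sex driving status, the joint linear predictor separates
        cases at least as well as the score alone."""
        geno, cohort, _, _, _ = small_cohort
        prs = pc.standardize(pc.score_samples(geno, true_scoring))
        covar, names = cohort.covariate_matrix(["age", "sex"])
        X = np.column_stack([prs.z, covar])
        fit = pc.fit_logistic(cohort.status, X, names=["prs"] + names)
        eta = fit.beta[0] + X @ fit.beta[1:]
        y = cohort.status.astype(bool)
        auc_full, _, _ = pc.auc_delong(eta[y], eta[~y])
        auc_prs, _, _ = pc.auc_delong(prs.z[y], prs.z[~y])
        assert auc_full >= auc_prs


class TestDecileAnalysis:
    def test_counts_conserved_and_balanced(self, rng):
        n = 1003  # deliberately not divisible by 10
        z = rng.normal(size=n)
        status = (rng.random(n) < 0.2).astype(int)
        cohort = minimal_cohort(status)
        rep = pc.decile_analysis(
            pc.standardize(PRSVector("T", cohort.sample_ids, z)), cohort
        )
        assert rep.case_counts.sum() == cohort.n_cases
        assert rep.control_counts.sum() == cohort.n_controls
        sizes = rep.case_counts + rep.control_counts
        assert sizes.max() - sizes.min() <= 1

    def test_degenerate_top_decile_flagged(self, rng):
        """Status identical to top-decile membership: zero cell corrected."""
        z = rng.normal(size=200)
        decile = _decile_assign(z)
        status = (decile == 10).astype(int)
        cohort = minimal_cohort(status)
        rep = pc.decile_analysis(
            pc.standardize(PRSVector("T", cohort.sample_ids, z)), cohort
        )
        assert rep.or_vs_all.corrected and np.isfinite(rep.or_vs_all.value)

    def test_null_or_ci_coverage(self, rng):
        cover = 0
        n_reps = 120
        for _ in range(n_reps):
            z = rng.normal(size=800)
            status = (rng.random(800) < 0.3).astype(int)
            cohort = minimal_cohort(status)
            rep = pc.decile_analysis(
                pc.standardize(PRSVector("T", cohort.sample_ids, z)), cohort
            )
            lo, hi = rep.or_vs_all.ci
            cover += lo <= 1.0 <= hi
        assert cover / n_reps >= 0.88

    def test_vs_lowest_exceeds_vs_all_for_risk_prs(self, rng):
        """A risk-increasing PRS concentrates cases in the top decile, so the
        top-vs-bottom OR dominates top-vs-rest."""
        wins = 0
        n_reps = 40
        for _ in range(n_reps):
            z = rng.normal(size=1500)
            status, _ = simulate_case_status(np.log(1.8) * z, 1 / 7, rng)
            cohort = minimal_cohort(status)
            rep = pc.decile_analysis(
                pc.standardize(PRSVector("T", cohort.sample_ids, z)), cohort
            )
            wins += rep.or_vs_lowest.value >= rep.or_vs_all.value
        assert wins / n_reps >= 0.95

    def test_small_cohort_rejected(self):
        cohort = minimal_cohort(np.zeros(10))
        prs = pc.standardize(PRSVector("T", cohort.sample_ids, np.arange(10.0)))
        with pytest.raises(ValueError, match="at least 20"):
            pc.decile_analysis(prs, cohort)


class TestMatchControls:
    @staticmethod
    def _cohort(case_ages, case_sexes, control_ages, control_sexes):
        import pandas as pd

        n_ca, n_co = len(case_ages), len(control_ages)
        df = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n_ca + n_co)],
                "status": [1] * n_ca + [0] * n_co,
                "age": list(case_ages) + list(control_ages),
                "sex": list(case_sexes) + list(control_sexes),
            }
        )
        return pc.CohortTable(df)

    def test_identical_multisets_match_exactly(self):
        ages, sexes = [40, 50, 60], ["male", "female", "male"]
        cohort = self._cohort(ages, sexes, ages, sexes)
        res = pc.match_controls(cohort)
        assert res.n_matched_controls == 3
        assert res.mean_age_diff == 0.0
        assert not res.shortfall

    def test_nearest_age_chosen(self):
        cohort = self._cohort([60], ["male"], [40, 59, 70], ["male"] * 3)
        res = pc.match_controls(cohort)
        matched = res.cohort.df[res.cohort.df["status"] == 0]
        assert matched["age"].tolist() == [59]

    def test_size_bound_exhaustive_small_cases(self, rng):
        """Matched controls never exceed cases x ratio; equality when the
        control pool suffices in every sex stratum."""
        for _ in range(30):
            n_ca = int(rng.integers(1, 6))
            n_co = int(rng.integers(0, 12))
            case_sex = rng.choice(["male", "female"], n_ca)
            ctrl_sex = rng.choice(["male", "female"], n_co)
            cohort = self._cohort(
                rng.integers(30, 80, n_ca), case_sex,
                rng.integers(30, 80, n_co) if n_co else [], ctrl_sex,
            )
            ratio = int(rng.integers(1, 3))
            res = pc.match_controls(cohort, ratio=ratio)
            assert res.n_matched_controls <= n_ca * ratio
            enough = all(
                (ctrl_sex == s).sum() >= ratio * (case_sex == s).sum()
                for s in ("male", "female")
            )
            if enough:
                assert res.n_matched_controls == n_ca * ratio


def test_woolf_or_known_value():
    orr = pc.odds_ratio_2x2(9, 9, 1005, 6000)
    assert orr.value == pytest.approx(5.970149, abs=1e-6)
    # Woolf CI: exp(ln OR +/- 1.96 * sqrt(sum of reciprocals))
    se = np.sqrt(1 / 9 + 1 / 9 + 1 / 1005 + 1 / 6000)
    assert orr.ci[0] == pytest.approx(orr.value * np.exp(-norm.ppf(0.975) * se))
    assert not orr.corrected
    assert pc.odds_ratio_2x2(0, 5, 10, 5).corrected
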