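"""Association and discrimination metrics for a standardized PRS.

The headline quantities of a case-control PRS validation:

* ``OR_1sd`` — odds ratio per 1 SD of the standardized score, from a
  covariate-adjusted logistic regression, with a Wald 95% CI;
* AUC of the score with a DeLong variance and CI, plus DeLong's paired test
  for comparing two correlated AUCs on the same samples;
* decile stratification — odds ratio of the top score decile versus the
  remaining deciles (``OR_vsAll``) and versus the bottom decile
  (``OR_vsLowest``);
* greedy age/sex control matching to neutralize demographic imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .prs import PRSVector
from .types import CohortTable

__all__ = [
    "LogisticFit",
    "AssociationReport",
    "DecileReport",
    "OddsRatio",
    "MatchResult",
    "fit_logistic",
    "or_per_sd",
    "auc_delong",
    "delong_paired_test",
    "decile_analysis",
    "match_controls",
    "odds_ratio_2x2",
]

_Z975 = norm.ppf(0.975)

#: Default adjustment set: principal components plus demographics.
DEFAULT_COVARIATES = ("age", "sex", "bmi", "pcs")


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression results (Wald inference)."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    llf: float
    n: int
    converged: bool

    def coef(self, name: str) -> tuple[float, float, tuple[float, float], float]:
        """(beta, se, (ci_low, ci_high), p) for one term."""
        i = self.names.index(name)
        return (
            float(self.beta[i]),
            float(self.se[i]),
            (float(self.ci_low[i]), float(self.ci_high[i])),
            float(self.p[i]),
        )


class SeparationError(RuntimeError):
    """Raised when the logistic likelihood has no finite maximizer."""


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    add_const: bool = True,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticFit:
    """Fit a logistic regression by maximum likelihood.

    ``X`` holds the predictors column-wise; an intercept is prepended unless
    ``add_const`` is False. Non-convergence and (quasi-)separation raise
    :class:`SeparationError` with a diagnostic rather than returning garbage
    coefficients.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if add_const:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["const"] + names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
    except Exception as exc:  # statsmodels raises on hard separation
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise SeparationError(
            f"logistic fit did not converge in {maxiter} iterations "
            "(possible separation)"
        )
    if np.abs(res.params).max() > 30 or not np.all(np.isfinite(res.bse)):
        raise SeparationError(
            "logistic fit diverged (|beta| > 30); predictors likely separate "
            "the outcome perfectly"
        )
    beta, se = res.params, res.bse
    return LogisticFit(
        names=names,
        beta=beta,
        se=se,
        ci_low=beta - _Z975 * se,
        ci_high=beta + _Z975 * se,
        p=2 * norm.sf(np.abs(beta / se)),
        llf=float(res.llf),
        n=len(y),
        converged=True,
    )


# ---------------------------------------------------------------------------
# DeLong AUC machinery
# ---------------------------------------------------------------------------

def _delong_components(cases: np.ndarray, controls: np.ndarray):
    """AUC and the DeLong structural components (V10 per case, V01 per control)."""
    m, n = len(cases), len(controls)
    if m == 0 or n == 0:
        raise ValueError("auc_delong needs at least one case and one control")
    scores = np.concatenate([cases, controls])
    r_all = rankdata(scores)  # midranks handle ties as 1/2
    r_cases = rankdata(cases)
    r_controls = rankdata(controls)
    auc = (r_all[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (r_all[:m] - r_cases) / n  # P(score_case > score_control | case)
    v01 = 1.0 - (r_all[m:] - r_controls) / m
    return auc, v10, v01


def auc_delong(
    cases: np.ndarray, controls: np.ndarray
) -> tuple[float, float, tuple[float, float]]:
    """AUC with DeLong variance and 95% CI.

    AUC is the Mann-Whitney probability that a random case outscores a
    random control, ties counted one half. Returns ``(auc, variance,
    (ci_low, ci_high))`` with the CI truncated to [0, 1].
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    auc, v10, v01 = _delong_components(cases, controls)
    var10 = v10.var(ddof=1) if len(v10) > 1 else 0.0
    var01 = v01.var(ddof=1) if len(v01) > 1 else 0.0
    var = var10 / len(v10) + var01 / len(v01)
    half = _Z975 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return float(auc), float(var), ci


def delong_paired_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """DeLong's paired test for two correlated AUCs on identical samples.

    Returns ``(z, two-sided p)``. Identical score vectors give z=0, p=1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("score vectors and labels must share one shape")
    auc_a, v10_a, v01_a = _delong_components(scores_a[labels], scores_a[~labels])
    auc_b, v10_b, v01_b = _delong_components(scores_b[labels], scores_b[~labels])
    m, n = labels.sum(), (~labels).sum()
    s10 = np.cov(v10_a, v10_b, ddof=1)  # 2x2 over cases
    s01 = np.cov(v01_a, v01_b, ddof=1)  # 2x2 over controls
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    return float(z), float(2 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Odds ratios and decile stratification
# ---------------------------------------------------------------------------

@dataclass
class OddsRatio:
    """2x2 odds ratio with a Woolf log-SE 95% CI.

    ``corrected`` flags the Haldane-Anscombe +0.5 continuity correction,
    applied only when a cell is zero.
    """

    value: float
    ci: tuple[float, float]
    table: tuple[int, int, int, int]  # (exposed cases, exposed ctrl, rest cases, rest ctrl)
    corrected: bool = False


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> OddsRatio:
    """Odds ratio of the table [[a, b], [c, d]] = [[exposed cases, exposed
    controls], [unexposed cases, unexposed controls]]."""
    table = (a, b, c, d)
    corrected = 0 in table
    if corrected:
        a, b, c, d = (x + 0.5 for x in table)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (float(or_ * np.exp(-_Z975 * se)), float(or_ * np.exp(_Z975 * se)))
    return OddsRatio(value=float(or_), ci=ci, table=table, corrected=corrected)


@dataclass
class AssociationReport:
    """OR per 1 SD and discrimination of one PRS under one covariate model."""

    pgs_id: str
    covariates: list[str]
    or_1sd: float
    or_1sd_ci: tuple[float, float]
    p: float
    auc: float
    auc_ci: tuple[float, float]
    beta: float
    se: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not (self.or_1sd_ci[0] <= self.or_1sd <= self.or_1sd_ci[1]):
            raise ValueError("OR point estimate outside its CI")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0, 1]")


def or_per_sd(
    prs: PRSVector,
    cohort: CohortTable,
    covariates: tuple[str, ...] | list[str] = (),
) -> AssociationReport:
    """Odds ratio per 1 SD of a standardized PRS, covariate adjusted.

    Fits ``status ~ z + covariates`` and exponentiates the PRS coefficient;
    the AUC reported alongside is the crude discrimination of the score
    itself (cases' z versus controls' z).
    """
    if prs.z is None:
        raise ValueError("PRS must be standardized before or_per_sd")
    if cohort.sample_ids != prs.sample_ids:
        raise ValueError("cohort and PRS sample ids differ")
    covar, covar_names = cohort.covariate_matrix(list(covariates))
    X = np.column_stack([prs.z, covar]) if covar.size else prs.z[:, None]
    fit = fit_logistic(cohort.status, X, names=["prs"] + covar_names)
    beta, se, (lo, hi), p = fit.coef("prs")
    y = cohort.status.astype(bool)
    auc, _, auc_ci = auc_delong(prs.z[y], prs.z[~y])
    return AssociationReport(
        pgs_id=prs.pgs_id,
        covariates=covar_names,
        or_1sd=float(np.exp(beta)),
        or_1sd_ci=(float(np.exp(lo)), float(np.exp(hi))),
        p=p,
        auc=auc,
        auc_ci=auc_ci,
        beta=beta,
        se=se,
        n_cases=cohort.n_cases,
        n_controls=cohort.n_controls,
    )


@dataclass
class DecileReport:
    """Top-decile risk stratification of a standardized PRS."""

    decile: np.ndarray  # 1..10 per sample, 10 = highest scores
    case_counts: np.ndarray  # cases per decile
    control_counts: np.ndarray  # controls per decile
    or_vs_all: OddsRatio
    or_vs_lowest: OddsRatio
    or_vs_all_adjusted: tuple[float, tuple[float, float]] | None = None
    or_vs_lowest_adjusted: tuple[float, tuple[float, float]] | None = None


def _decile_assign(z: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Count-balanced decile assignment, ties broken by stable sample order.

    Sorting is stable, so tied scores keep their input order and bin sizes
    differ by at most one sample.
    """
    order = np.argsort(z, kind="stable")
    decile = np.empty(len(z), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins), start=1):
        decile[chunk] = b
    return decile


def decile_analysis(
    prs: PRSVector,
    cohort: CohortTable,
    covariates: tuple[str, ...] | list[str] | None = None,
) -> DecileReport:
    """Bin a standardized PRS into deciles and compute top-decile odds ratios.

    ``OR_vsAll`` compares decile 10 with the nine remaining deciles,
    ``OR_vsLowest`` with decile 1; both are crude 2x2 Woolf estimates
    (Haldane-Anscombe corrected when a cell is zero). When ``covariates``
    are supplied, covariate-adjusted logistic versions are also reported.
    """
    if prs.z is None:
        raise ValueError("PRS must be standardized before decile_analysis")
    if cohort.sample_ids != prs.sample_ids:
        raise ValueError("cohort and PRS sample ids differ")
    if len(prs) < 20:
        raise ValueError("decile analysis needs at least 20 samples")
    decile = _decile_assign(prs.z)
    y = cohort.status
    case_counts = np.array([(y[decile == b] == 1).sum() for b in range(1, 11)])
    control_counts = np.array([(y[decile == b] == 0).sum() for b in range(1, 11)])
    top = decile == 10
    or_all = odds_ratio_2x2(
        int(case_counts[9]),
        int(control_counts[9]),
        int(case_counts[:9].sum()),
        int(control_counts[:9].sum()),
    )
    or_low = odds_ratio_2x2(
        int(case_counts[9]),
        int(control_counts[9]),
        int(case_counts[0]),
        int(control_counts[0]),
    )
    adj_all = adj_low = None
    if covariates:
        covar, covar_names = cohort.covariate_matrix(list(covariates))

        def _adjusted(mask: np.ndarray):
            X = np.column_stack([top[mask].astype(float), covar[mask]])
            fit = fit_logistic(y[mask], X, names=["top"] + covar_names)
            beta, _, (lo, hi), _ = fit.coef("top")
            return float(np.exp(beta)), (float(np.exp(lo)), float(np.exp(hi)))

        adj_all = _adjusted(np.ones(len(y), dtype=bool))
        adj_low = _adjusted(top | (decile == 1))
    return DecileReport(
        decile=decile,
        case_counts=case_counts,
        control_counts=control_counts,
        or_vs_all=or_all,
        or_vs_lowest=or_low,
        or_vs_all_adjusted=adj_all,
        or_vs_lowest_adjusted=adj_low,
    )


# ---------------------------------------------------------------------------
# Age/sex control matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Outcome of greedy age/sex control matching."""

    cohort: CohortTable  # cases + matched controls, original order
    n_matched_controls: int
    shortfall: dict[str, int] = field(default_factory=dict)  # per sex stratum
    mean_age_diff: float = float("nan")


def match_controls(cohort: CohortTable, ratio: int = 1) -> MatchResult:
    """Select age/sex-matched controls for every case.

    Greedy nearest-age matching within exact sex strata: cases are processed
    in input order, each drawing up to ``ratio`` unused controls of the same
    sex with minimal absolute age difference (ties go to the earlier control
    in input order). A shortfall of controls is reported per stratum, never
    fatal.
    """
    df = cohort.df
    status = cohort.status
    case_idx = np.flatnonzero(status == 1)
    keep = list(case_idx)
    shortfall: dict[str, int] = {}
    age_diffs: list[float] = []
    for sex in ("male", "female"):
        in_sex = df["sex"].to_numpy() == sex
        pool = [
            (float(df["age"].iloc[i]), i)
            for i in np.flatnonzero(in_sex & (status == 0))
        ]
        used = np.zeros(len(pool), dtype=bool)
        missed = 0
        for ci in case_idx:
            if not in_sex[ci]:
                continue
            cage = float(df["age"].iloc[ci])
            for _ in range(ratio):
                best, best_diff = -1, np.inf
                for k, (page, _pi) in enumerate(pool):
                    if used[k]:
                        continue
                    diff = abs(page - cage)
                    if diff < best_diff:
                        best, best_diff = k, diff
                if best < 0:
                    missed += 1
                    continue
                used[best] = True
                keep.append(pool[best][1])
                age_diffs.append(best_diff)
        if missed:
            shortfall[sex] = missed
    keep_sorted = np.sort(np.array(keep))
    return MatchResult(
        cohort=cohort.subset(keep_sorted),
        n_matched_controls=len(keep) - len(case_idx),
        shortfall=shortfall,
        mean_age_diff=float(np.mean(age_diffs)) if age_diffs else float("nan"),
    )
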