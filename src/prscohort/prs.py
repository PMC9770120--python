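"""Polygenic risk score computation, standardization, and the ensemble score.

A PRS is the weighted sum of effect-allele dosages over the variants of a
scoring file, ``raw_j = sum_i w_i * d_ij``. Raw scores are z-standardized
either over the whole cohort or within each ancestry stratum (the latter
removes ancestry-driven mean shifts before case-control comparison). The
ensemble score combines several standardized component scores; the default
is the unweighted mean of component z-scores, re-standardized, with an
out-of-fold logistic stacking mode available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import Harmonization, harmonize
from .types import CohortTable, GenotypeMatrix, ScoringFile

__all__ = ["PRSVector", "score_samples", "standardize", "ensemble_prs"]


@dataclass
class PRSVector:
    """Per-sample polygenic score, raw and (optionally) z-standardized."""

    pgs_id: str
    sample_ids: list[str]
    raw: np.ndarray
    z: np.ndarray | None = None
    scope: str | None = None  # standardization scope: overall | per-ancestry

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if len(self.raw) != len(self.sample_ids):
            raise ValueError("raw score length does not match sample_ids")
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)

    @property
    def values(self) -> np.ndarray:
        """z-scores when standardized, raw scores otherwise."""
        return self.raw if self.z is None else self.z

    def __len__(self) -> int:
        return len(self.sample_ids)


def score_samples(
    geno: GenotypeMatrix,
    scoring: ScoringFile,
    missing_policy: str = "impute_af",
    drop_ambiguous: bool = False,
    harmonization: Harmonization | None = None,
) -> PRSVector:
    """Apply a scoring file to a genotype matrix.

    Parameters
    ----------
    missing_policy : {"impute_af", "zero", "error"}
        How missing dosages enter the sum: imputed with twice the cohort
        effect-allele frequency at that variant (standard PRS practice),
        treated as zero, or rejected.
    harmonization : Harmonization, optional
        A precomputed alignment; by default :func:`prscohort.io.harmonize`
        is run on the inputs.

    Samples missing at every matched variant get a NaN score and a warning.
    """
    if harmonization is None:
        harmonization = harmonize(scoring, geno, drop_ambiguous=drop_ambiguous)
    d = harmonization.effective_dosage(geno)
    missing = np.isnan(d)
    if missing_policy == "error":
        if missing.any():
            raise ValueError("missing dosages present with missing_policy='error'")
    elif missing_policy == "zero":
        d = np.where(missing, 0.0, d)
    elif missing_policy == "impute_af":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            eaf2 = np.nanmean(d, axis=0)
        eaf2 = np.where(np.isnan(eaf2), 0.0, eaf2)
        d = np.where(missing, eaf2[None, :], d)
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    raw = d @ harmonization.weights
    all_missing = missing.all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"{all_missing.sum()} samples missing at every scored variant; "
            "their scores are NaN",
            stacklevel=2,
        )
        raw[all_missing] = np.nan
    return PRSVector(pgs_id=scoring.pgs_id, sample_ids=list(geno.sample_ids), raw=raw)


def standardize(
    prs: PRSVector,
    cohort: CohortTable | None = None,
    scope: str = "overall",
) -> PRSVector:
    """z-standardize a PRS overall or within each ancestry stratum.

    Operates on the current values (so re-standardizing a standardized score
    is the identity). Uses the n-1 denominator; a zero-variance stratum is an
    error naming the stratum.
    """
    x = prs.values
    z = np.empty_like(x)
    if scope == "overall":
        strata = {"overall": np.arange(len(x))}
    elif scope == "per-ancestry":
        if cohort is None:
            raise ValueError("per-ancestry standardization requires a cohort table")
        if cohort.sample_ids != prs.sample_ids:
            raise ValueError("cohort and PRS sample ids differ")
        labels = cohort.ancestry
        strata = {a: np.flatnonzero(labels == a) for a in np.unique(labels)}
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for name, idx in strata.items():
        vals = x[idx]
        if len(idx) < 2:
            raise ValueError(f"stratum {name!r} has fewer than 2 samples")
        sd = np.std(vals, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"stratum {name!r} has zero score variance")
        z[idx] = (vals - vals.mean()) / sd
    return replace(prs, z=z, scope=scope)


def ensemble_prs(
    components: list[PRSVector],
    method: str = "mean",
    cohort: CohortTable | None = None,
    n_folds: int = 5,
    seed: int = 42,
    pgs_id: str = "EnsemblePRS",
) -> PRSVector:
    """Combine standardized component PRSs into one ensemble score.

    ``method="mean"``: arithmetic mean of component z-scores, re-standardized
    overall. ``method="stacked"``: out-of-fold linear predictor of a logistic
    regression of case status on the component z-scores (stratified k-fold,
    deterministic seed), re-standardized; requires ``cohort``.
    """
    if not components:
        raise ValueError("ensemble needs at least one component")
    ids = components[0].sample_ids
    for c in components[1:]:
        if c.sample_ids != ids:
            raise ValueError("component PRSs cover different samples")
    for c in components:
        if c.z is None:
            raise ValueError(f"component {c.pgs_id} is not standardized")
    zmat = np.column_stack([c.z for c in components])
    if method == "mean":
        raw = zmat.mean(axis=1)
    elif method == "stacked":
        if cohort is None:
            raise ValueError("stacked ensemble requires a cohort table")
        if cohort.sample_ids != ids:
            raise ValueError("cohort and PRS sample ids differ")
        y = cohort.status
        raw = np.empty(len(y))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        for train, test in skf.split(zmat, y):
            model = LogisticRegression(C=np.inf, max_iter=1000)
            model.fit(zmat[train], y[train])
            raw[test] = model.decision_function(zmat[test])
    else:
        raise ValueError(f"unknown ensemble method {method!r}")
    out = PRSVector(pgs_id=pgs_id, sample_ids=list(ids), raw=raw)
    return standardize(out)
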