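"""Model comparison: per-subject Bayes factors, group positive evidence
ratios, the posterior-sd convergence cut-off, and the initialization
sensitivity scan.

A Bayes factor of 3 marks substantial ("positive") evidence; the interval
convention is used, so BF >= 3 counts as positive for the reference model
and BF <= 1/3 as positive for the alternative. At group level, multiplying
per-subject Bayes factors is fragile under outliers from poorly converged
fits, so models are ranked by the positive evidence ratio x:y — the counts
of subjects with positive evidence for each side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import (
    DEFAULT_ALPHA0,
    DEFAULT_LOGIT_EPS,
    PosteriorFit,
    build_regression,
    evidence_fit,
    pooled_prior_means,
)
from .models import CANDIDATES, SubjectSeries

__all__ = [
    "BF_POSITIVE",
    "ComparisonOutcome",
    "GroupPER",
    "bayes_factor",
    "positive_evidence_ratio",
    "convergence_filter",
    "sensitivity_scan",
    "REPORTED_CUTOFFS",
]

#: Evidence threshold: BF >= 3 is substantial evidence (analogous to p = .05).
BF_POSITIVE = 3.0

#: Posterior-sd cut-offs for (a, b, c) reported for the original trial
#: cohort; usable in place of the data-driven "auto" rule.
REPORTED_CUTOFFS = {"a": 0.316, "b": 6.38, "c": 3.67}


@dataclass
class ComparisonOutcome:
    subject_id: str
    ref_id: str
    alt_id: str
    log_bf: float
    bf: float
    verdict: str  # {"ref_positive", "alt_positive", "inconclusive"}
    flagged: bool = False


@dataclass
class GroupPER:
    """Positive evidence ratio x:y over N subjects; the rest are undecided."""

    ref_count: int
    alt_count: int
    n: int

    @property
    def undecided(self) -> int:
        return self.n - (self.ref_count + self.alt_count)

    def __str__(self) -> str:
        return f"{self.ref_count}:{self.alt_count} (undecided {self.undecided} of {self.n})"


def bayes_factor(fit_ref: PosteriorFit, fit_alt: PosteriorFit) -> ComparisonOutcome:
    """Evidence ratio of two fits of the same subject and target variable.

    Evidences are compared on the observation scale: logit-target rows carry
    a change-of-variables Jacobian so that sigmoid and linear use models are
    measured against the same observed variable.
    """
    if fit_ref.subject_id != fit_alt.subject_id:
        raise ValueError("fits are for different subjects")
    t_ref = CANDIDATES[fit_ref.candidate_id].target
    t_alt = CANDIDATES[fit_alt.candidate_id].target
    if t_ref != t_alt:
        raise ValueError("fits target different variables")
    log_bf = fit_ref.log_evidence_obs - fit_alt.log_evidence_obs
    if not math.isfinite(log_bf):
        return ComparisonOutcome(
            fit_ref.subject_id, fit_ref.candidate_id, fit_alt.candidate_id,
            log_bf=float("nan"), bf=float("nan"), verdict="inconclusive", flagged=True,
        )
    bf = math.exp(log_bf)
    if bf >= BF_POSITIVE:
        verdict = "ref_positive"
    elif bf <= 1.0 / BF_POSITIVE:
        verdict = "alt_positive"
    else:
        verdict = "inconclusive"
    return ComparisonOutcome(
        fit_ref.subject_id, fit_ref.candidate_id, fit_alt.candidate_id,
        log_bf=log_bf, bf=bf, verdict=verdict,
    )


def positive_evidence_ratio(outcomes: list[ComparisonOutcome]) -> GroupPER:
    """Count per-subject verdicts into an x:y positive evidence ratio."""
    ids = [o.subject_id for o in outcomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subjects in comparison outcomes")
    x = sum(o.verdict == "ref_positive" for o in outcomes)
    y = sum(o.verdict == "alt_positive" for o in outcomes)
    return GroupPER(ref_count=x, alt_count=y, n=len(outcomes))


def convergence_filter(
    fits: list[PosteriorFit], cutoffs="auto"
) -> tuple[list[PosteriorFit], np.ndarray]:
    """Keep fits whose posterior sds are below per-parameter cut-offs.

    Under ``"auto"`` the cut-off for each parameter is the standard deviation
    across subjects of the posterior means — a fit is retained only if its
    own posterior is sharper than the between-subject spread. Explicit
    cut-offs (array-like, one per parameter) override the rule.
    """
    if not fits:
        return [], np.array([])
    cids = {f.candidate_id for f in fits}
    if len(cids) != 1:
        raise ValueError("convergence_filter expects fits of a single candidate")
    m = fits[0].mN.shape[0]
    if isinstance(cutoffs, str) and cutoffs == "auto":
        if len(fits) < 2:
            raise ValueError("auto cut-offs need at least 2 fits")
        means = np.vstack([f.mN for f in fits])
        cut = means.std(axis=0, ddof=1)
    else:
        cut = np.atleast_1d(np.asarray(cutoffs, dtype=float))
        if cut.shape != (m,):
            raise ValueError(f"need {m} cut-offs, got {cut.shape}")
    kept = [f for f in fits if np.all(f.posterior_sd < cut)]
    return kept, cut


def sensitivity_scan(
    cohort: list[SubjectSeries],
    candidate_ids,
    ref_id: str,
    noise_precision0_grid,
    prior_precision0: float = DEFAULT_ALPHA0,
    logit_eps: float = DEFAULT_LOGIT_EPS,
) -> pd.DataFrame:
    """Group-median log Bayes factor of the reference vs each competitor over
    a grid of initial noise precisions.

    Everything is refit at each grid point. Medians (not means) aggregate
    over subjects, and non-finite per-subject values are dropped, since a
    handful of non-converged fits would otherwise dominate.
    """
    grid = np.atleast_1d(np.asarray(noise_precision0_grid, dtype=float))
    if np.any(grid <= 0):
        raise ValueError("noise precisions must be positive")
    alts = [c for c in candidate_ids if c != ref_id]
    rows = []
    for beta0 in grid:
        priors = {
            cid: pooled_prior_means(
                cohort, cid, logit_eps,
                prior_precision0=prior_precision0, noise_precision0=beta0,
            )
            for cid in [ref_id, *alts]
        }
        log_ev = {cid: [] for cid in [ref_id, *alts]}
        for s in cohort:
            for cid in [ref_id, *alts]:
                problem = build_regression(cid, s, logit_eps)
                fit = evidence_fit(problem, priors[cid])
                log_ev[cid].append(fit.log_evidence_obs)
        ref_ev = np.asarray(log_ev[ref_id])
        for cid in alts:
            diff = ref_ev - np.asarray(log_ev[cid])
            diff = diff[np.isfinite(diff)]
            rows.append(
                {
                    "noise_precision0": beta0,
                    "ref_id": ref_id,
                    "alt_id": cid,
                    "median_log_bf": float(np.median(diff)) if diff.size else float("nan"),
                    "n_subjects": int(diff.size),
                }
            )
    return pd.DataFrame(rows)
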