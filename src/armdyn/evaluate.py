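"""Model evaluation: leave-one-out trajectory prediction with a randomized
baseline, before/after-therapy parameter comparison, and use-trend
classification.

Leave-one-out protocol: for a 7-point post-therapy series, each interior
point (indices 2-6, 1-based) is held out in turn; both the function and use
models are refitted on the remaining points (regression rows that consume
the held-out point are dropped), the coupled fitted model is forward
simulated from the first point, and the absolute prediction error at the
held-out index is recorded for F and U separately. The first and last points
are never held out — they anchor the trajectory as initial and final values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import (
    DEFAULT_LOGIT_EPS,
    PosteriorFit,
    PriorSpec,
    build_regression,
    evidence_fit,
    pooled_prior_means,
)
from .models import (
    REFERENCE_FUNCTION_ID,
    REFERENCE_USE_ID,
    SubjectSeries,
    simulate_pair,
)

__all__ = [
    "LooResult",
    "TherapyEffect",
    "loo_evaluate",
    "loo_cohort",
    "randomized_baseline",
    "therapy_effect",
    "classify_use_trend",
    "filter_low_function",
]

#: 1-based indices of the points eligible for holding out on a 7-point series
LOO_INDICES = (2, 3, 4, 5, 6)


@dataclass
class LooResult:
    subject_id: str
    left_out_index: int  # 1-based over the 7-point series
    abs_error_F: float
    abs_error_U: float
    failed: bool = False


@dataclass
class TherapyEffect:
    parameter: str  # {"a", "b", "c"}
    n_pairs: int
    mean_before: float
    se_before: float
    mean_after: float
    se_after: float
    t_stat: float
    p_two_tailed: float


def _fit_without_point(
    series: SubjectSeries,
    candidate_id: str,
    prior: PriorSpec,
    holdout: int,
    logit_eps: float,
) -> PosteriorFit:
    problem = build_regression(candidate_id, series, logit_eps)
    mask = [holdout in rp for rp in problem.row_points]
    reduced = problem.drop_rows(mask)
    return evidence_fit(reduced, prior)


def loo_evaluate(
    series: SubjectSeries,
    function_candidate: str = REFERENCE_FUNCTION_ID,
    use_candidate: str = REFERENCE_USE_ID,
    function_prior: PriorSpec | None = None,
    use_prior: PriorSpec | None = None,
    logit_eps: float = DEFAULT_LOGIT_EPS,
    mode: str = "simulate",
) -> list[LooResult]:
    """Leave-one-out prediction errors for one 7-point series.

    ``mode="simulate"`` (default) forward-simulates the coupled fitted model
    from the first observed point; ``mode="one_step"`` instead predicts the
    held-out point one step ahead from its observed predecessor.
    """
    if len(series) != 7:
        raise ValueError("leave-one-out evaluation requires a 7-point series")
    if mode not in ("simulate", "one_step"):
        raise ValueError("mode must be 'simulate' or 'one_step'")
    if function_prior is None:
        function_prior = pooled_prior_means([series], function_candidate, logit_eps)
    if use_prior is None:
        use_prior = pooled_prior_means([series], use_candidate, logit_eps)
    results: list[LooResult] = []
    for k in LOO_INDICES:
        h = k - 1  # 0-based
        try:
            f_fit = _fit_without_point(series, function_candidate, function_prior, h, logit_eps)
            u_fit = _fit_without_point(series, use_candidate, use_prior, h, logit_eps)
            if mode == "simulate":
                F_sim, U_sim = simulate_pair(
                    function_candidate, f_fit.mN, use_candidate, u_fit.mN,
                    series.F[0], series.U[0], len(series) - 1,
                )
                pred_F, pred_U = F_sim[h], U_sim[h]
            else:
                F_sim, U_sim = simulate_pair(
                    function_candidate, f_fit.mN, use_candidate, u_fit.mN,
                    series.F[h - 1], series.U[h - 1], 1,
                )
                pred_F, pred_U = F_sim[1], U_sim[1]
            results.append(
                LooResult(
                    subject_id=series.subject_id,
                    left_out_index=k,
                    abs_error_F=abs(pred_F - series.F[h]),
                    abs_error_U=abs(pred_U - series.U[h]),
                )
            )
        except (ValueError, np.linalg.LinAlgError):
            results.append(
                LooResult(series.subject_id, k, float("nan"), float("nan"), failed=True)
            )
    return results


def loo_cohort(
    cohort: list[SubjectSeries],
    function_candidate: str = REFERENCE_FUNCTION_ID,
    use_candidate: str = REFERENCE_USE_ID,
    logit_eps: float = DEFAULT_LOGIT_EPS,
    mode: str = "simulate",
) -> pd.DataFrame:
    """Leave-one-out errors for a whole cohort, with cohort-pooled priors.

    Prior means are pooled once over the full cohort (not re-pooled per
    reduced series) and reused for every refit.
    """
    f_prior = pooled_prior_means(cohort, function_candidate, logit_eps)
    u_prior = pooled_prior_means(cohort, use_candidate, logit_eps)
    rows = []
    for s in cohort:
        for r in loo_evaluate(
            s, function_candidate, use_candidate, f_prior, u_prior, logit_eps, mode
        ):
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "left_out_index": r.left_out_index,
                    "months": (r.left_out_index - 1) * 4,
                    "abs_error_F": r.abs_error_F,
                    "abs_error_U": r.abs_error_U,
                    "failed": r.failed,
                }
            )
    return pd.DataFrame(rows)


def randomized_baseline(cohort: list[SubjectSeries], rng_seed: int) -> pd.DataFrame:
    """Baseline prediction errors from randomly exchanged subjects.

    For every subject and every interior index, the prediction is the value
    of a uniformly drawn *other* subject at that index; seeded and
    reproducible.
    """
    if len(cohort) < 2:
        raise ValueError("randomized baseline needs at least 2 subjects")
    n7 = [s for s in cohort if len(s) == 7]
    if len(n7) != len(cohort):
        raise ValueError("all series must have 7 points")
    rng = np.random.default_rng(rng_seed)
    rows = []
    for i, s in enumerate(cohort):
        for k in LOO_INDICES:
            h = k - 1
            j = int(rng.integers(0, len(cohort) - 1))
            if j >= i:
                j += 1
            other = cohort[j]
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "left_out_index": k,
                    "months": h * 4,
                    "abs_error_F": abs(other.F[h] - s.F[h]),
                    "abs_error_U": abs(other.U[h] - s.U[h]),
                }
            )
    return pd.DataFrame(rows)


def therapy_effect(
    pre_fits: list[PosteriorFit], post_fits: list[PosteriorFit]
) -> list[TherapyEffect]:
    """Paired before/after comparison of the reference-model parameters.

    Input fits should already have passed the convergence filter in both
    phases; pairing is by subject id, separately per parameter source
    (function fits carry a; use fits carry b and c). Returns the classical
    two-tailed paired t-test per parameter.
    """

    def collect(fits: list[PosteriorFit]) -> dict[str, dict[str, float]]:
        vals: dict[str, dict[str, float]] = {"a": {}, "b": {}, "c": {}}
        for f in fits:
            if f.candidate_id == REFERENCE_FUNCTION_ID:
                vals["a"][f.subject_id] = float(f.mN[0])
            elif f.candidate_id == REFERENCE_USE_ID:
                vals["b"][f.subject_id] = float(f.mN[0])
                vals["c"][f.subject_id] = float(f.mN[1])
        return vals

    pre, post = collect(pre_fits), collect(post_fits)
    effects: list[TherapyEffect] = []
    for p in ("a", "b", "c"):
        subjects = sorted(set(pre[p]) & set(post[p]))
        if len(subjects) < 2:
            raise ValueError(f"fewer than 2 paired subjects for parameter {p}")
        x = np.array([pre[p][s] for s in subjects])
        y = np.array([post[p][s] for s in subjects])
        if np.allclose(x, y):
            t, pv = 0.0, 1.0
        else:
            t, pv = stats.ttest_rel(x, y)
        n = len(subjects)
        effects.append(
            TherapyEffect(
                parameter=p,
                n_pairs=n,
                mean_before=float(x.mean()),
                se_before=float(x.std(ddof=1) / np.sqrt(n)),
                mean_after=float(y.mean()),
                se_after=float(y.std(ddof=1) / np.sqrt(n)),
                t_stat=float(t),
                p_two_tailed=float(pv),
            )
        )
    return effects


def classify_use_trend(U, times, p_threshold: float = 0.25) -> str:
    """Classify a use trajectory as increase / decrease / no_change.

    Ordinary least-squares slope of use against time with its t-test; the
    lenient default threshold p < 0.25 mirrors a descriptive (not
    confirmatory) categorization. Invariant to affine rescaling of time.
    """
    U = np.asarray(U, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(U) < 3 or len(U) != len(times):
        raise ValueError("need at least 3 matched points")
    if np.ptp(times) == 0:
        raise ValueError("time values have no variance")
    if np.ptp(U) == 0:
        return "no_change"
    res = stats.linregress(times, U)
    if res.pvalue < p_threshold:
        return "increase" if res.slope > 0 else "decrease"
    return "no_change"


def filter_low_function(cohort: list[SubjectSeries], threshold: float = 0.5) -> list[SubjectSeries]:
    """Subgroup filter: keep subjects whose initial normalized function is
    below ``threshold`` (medium-to-low function subgroup)."""
    return [s for s in cohort if s.F[0] < threshold]
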