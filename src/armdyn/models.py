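"""Recovery model family: score transforms, state updates, forward simulation.

The core model couples two scalar states on a 4-month grid:

* arm function ``F(t) = (1 - a) F(t-1) + a U(t-1)`` — a weighted average of
  previous function and previous spontaneous use, with a single "use-effect"
  rate ``a``; ``1 - a`` acts as a per-step decay of function, so with zero
  use function decays geometrically (continuous-time constant ``D / a``
  months, ``D = 4``).
* arm use ``U(t) = sigma(b F(t-1) - c)`` — a logistic decision rule in which
  the slope ``b`` is the sensitivity of arm choice to function ("confidence")
  and ``c`` is a constant competition bias absorbing the unaffected arm's
  function and handedness.

Alongside the reference pair, the module enumerates the full candidate
family used for model comparison: seven function models (linear in
``F(t-1)``, ``U(t-1)``, both, with or without a constant) and four use
models (linear or sigmoidal in current or previous function).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "VISIT_LABELS",
    "STEP_MONTHS",
    "RawVisit",
    "SubjectSeries",
    "ModelParams",
    "CandidateModel",
    "FUNCTION_CANDIDATES",
    "USE_CANDIDATES",
    "CANDIDATES",
    "REFERENCE_FUNCTION_ID",
    "REFERENCE_USE_ID",
    "wmft_to_function",
    "function_to_wmft",
    "aou_to_use",
    "use_to_aou_items",
    "assemble_series",
    "function_step",
    "use_step",
    "simulate_trajectory",
    "simulate_pair",
]

#: Trial visit schedule (Pre1 at randomization; therapy spans Pre->Post).
VISIT_LABELS = ("Pre1", "Post1", "M4", "M8", "Pre2", "Post2", "M16", "M20", "M24")

#: Analysis grid step in months.
STEP_MONTHS = 4

_WMFT_TASKS = 15
_WMFT_CAP_S = 120.0
_AOU_ITEMS = 30


@dataclass(frozen=True)
class RawVisit:
    """One clinic visit: timed-task total and 30 amount-of-use item ratings."""

    subject_id: str
    visit_label: str
    wmft_time_affected: float
    wmft_time_unaffected: float
    aou_items: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.visit_label not in VISIT_LABELS:
            raise ValueError(f"unknown visit label {self.visit_label!r}")
        for t in (self.wmft_time_affected, self.wmft_time_unaffected):
            if not (0.0 < t <= _WMFT_TASKS * _WMFT_CAP_S):
                raise ValueError(f"WMFT time {t} s outside (0, {_WMFT_TASKS * _WMFT_CAP_S}]")
        if len(self.aou_items) != _AOU_ITEMS:
            raise ValueError(f"expected {_AOU_ITEMS} AOU items, got {len(self.aou_items)}")
        for r in self.aou_items:
            if not (0.0 <= r <= 5.0) or (2 * r) != int(round(2 * r)):
                raise ValueError(f"AOU rating {r} not on the 0.5 grid in [0, 5]")


@dataclass
class SubjectSeries:
    """A subject's normalized function F and use U on the 4-month grid."""

    subject_id: str
    group: str  # {"immediate", "delayed"}
    phase: str  # {"post_therapy", "pre_therapy"}
    times: np.ndarray  # months since first retained point, step 4
    F: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        n = len(self.times)
        if len(self.F) != n or len(self.U) != n:
            raise ValueError("times, F and U must have equal length")
        if n >= 2 and not np.allclose(np.diff(self.times), STEP_MONTHS):
            raise ValueError(f"times must increase in steps of {STEP_MONTHS} months")
        if np.any(self.F < 0) or np.any(self.F > 1) or np.any(self.U < 0) or np.any(self.U > 1):
            raise ValueError("normalized F and U must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class ModelParams:
    """Reference-model parameters (a, b, c).

    ``a`` is interpretable on [0, 1]; fits outside are retained but flagged
    via :meth:`a_interpretable`.
    """

    a: float
    b: float
    c: float

    @property
    def a_interpretable(self) -> bool:
        return 0.0 <= self.a <= 1.0


@dataclass(frozen=True)
class CandidateModel:
    """One row of the comparison family: target, regressors, link, lag."""

    id: str
    target: str  # {"function", "use"}
    regressors: tuple[str, ...]
    link: str  # {"linear", "sigmoid"}
    lag: int  # 1 = previous-step regressor, 0 = same-step
    n_params: int
    reference: bool = False
    param_names: tuple[str, ...] = field(default=())


REFERENCE_FUNCTION_ID = "F1_weighted"
REFERENCE_USE_ID = "U_sig_lag"

FUNCTION_CANDIDATES: dict[str, CandidateModel] = {
    m.id: m
    for m in (
        CandidateModel("F1_fw", "function", ("F(t-1)",), "linear", 1, 1, param_names=("w",)),
        CandidateModel("F2_fw_const", "function", ("F(t-1)", "const"), "linear", 1, 2, param_names=("w", "k")),
        CandidateModel("F1_uw", "function", ("U(t-1)",), "linear", 1, 1, param_names=("w",)),
        CandidateModel("F2_uw_const", "function", ("U(t-1)", "const"), "linear", 1, 2, param_names=("w", "k")),
        CandidateModel(
            "F1_weighted", "function", ("F(t-1)", "U(t-1)"), "linear", 1, 1,
            reference=True, param_names=("a",),
        ),
        CandidateModel("F2_fw_uw", "function", ("F(t-1)", "U(t-1)"), "linear", 1, 2, param_names=("w1", "w2")),
        CandidateModel(
            "F3_fw_uw_const", "function", ("F(t-1)", "U(t-1)", "const"), "linear", 1, 3,
            param_names=("w1", "w2", "k"),
        ),
    )
}

USE_CANDIDATES: dict[str, CandidateModel] = {
    m.id: m
    for m in (
        CandidateModel("U_lin_t", "use", ("F(t)", "const"), "linear", 0, 2, param_names=("s", "k")),
        CandidateModel("U_lin_lag", "use", ("F(t-1)", "const"), "linear", 1, 2, param_names=("s", "k")),
        CandidateModel("U_sig_t", "use", ("F(t)",), "sigmoid", 0, 2, param_names=("b", "c")),
        CandidateModel(
            "U_sig_lag", "use", ("F(t-1)",), "sigmoid", 1, 2,
            reference=True, param_names=("b", "c"),
        ),
    )
}

CANDIDATES: dict[str, CandidateModel] = {**FUNCTION_CANDIDATES, **USE_CANDIDATES}


# ---------------------------------------------------------------------------
# Score transforms


def wmft_to_function(
    wmft_seconds: float,
    ref_neglog_min: float,
    ref_neglog_max: float,
    clamp: bool = False,
) -> float:
    """Map a WMFT total time (s) to normalized function in [0, 1].

    The raw time score is long-tailed, so it is log-transformed, negated
    (high = good) and min-max normalized against the dataset-wide reference
    range of ``-ln(time)``:  ``(-ln t - lo) / (hi - lo)``.
    """
    if not ref_neglog_min < ref_neglog_max:
        raise ValueError("reference range must satisfy min < max")
    w = float(wmft_seconds)
    if w <= 0:
        raise ValueError(f"WMFT time must be positive, got {w}")
    score = -math.log(w)
    f = (score - ref_neglog_min) / (ref_neglog_max - ref_neglog_min)
    if not 0.0 <= f <= 1.0:
        if clamp:
            f = min(1.0, max(0.0, f))
        else:
            raise ValueError(
                f"WMFT {w} s maps to {f:.4f}, outside the reference range; "
                "pass clamp=True to clip"
            )
    return f


def function_to_wmft(f: float, ref_neglog_min: float, ref_neglog_max: float) -> float:
    """Inverse of :func:`wmft_to_function` (exact on the reference range)."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("normalized function must lie in [0, 1]")
    return math.exp(-(f * (ref_neglog_max - ref_neglog_min) + ref_neglog_min))


def aou_to_use(items) -> float:
    """Mean of 30 amount-of-use ratings (0-5, 0.5 steps), scaled to [0, 1]."""
    items = np.asarray(items, dtype=float)
    if items.shape != (_AOU_ITEMS,):
        raise ValueError(f"expected {_AOU_ITEMS} AOU items, got shape {items.shape}")
    if np.any(items < 0) or np.any(items > 5) or not np.allclose(2 * items, np.round(2 * items)):
        raise ValueError("AOU items must be on the 0.5 grid in [0, 5]")
    return float(items.mean() / 5.0)


def use_to_aou_items(u: float) -> tuple[float, ...]:
    """Synthesize 30 on-grid item ratings whose mean/5 is within 1/60 of ``u``.

    The target sum ``150 u`` is rounded to the 0.5 grid and distributed as
    evenly as possible; the residual half-steps are spread over the leading
    items.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("normalized use must lie in [0, 1]")
    half_steps = int(round(u * _AOU_ITEMS * 5 * 2))  # total sum in units of 0.5
    base, extra = divmod(half_steps, _AOU_ITEMS)
    items = np.full(_AOU_ITEMS, base * 0.5)
    items[:extra] += 0.5
    return tuple(float(x) for x in np.clip(items, 0.0, 5.0))


# ---------------------------------------------------------------------------
# Series assembly from the visit schedule

_IMMEDIATE_SCHEDULE = ("Post1", "M4", "M8", ("Pre2", "Post2"), "M16", "M20", "M24")
_DELAYED_PRE = (("Pre1", "Post1"), "M4", "M8", "Pre2")
_DELAYED_POST = ("Post2", "M16", "M20", "M24")


class IncompleteSubjectError(ValueError):
    """Subject lacks the full visit complement and is excluded."""


def _pick(values: dict[str, tuple[float, float]], spec) -> tuple[float, float]:
    if isinstance(spec, tuple):  # averaged visit pair, post-normalization
        pairs = [values[lbl] for lbl in spec]
        return (
            float(np.mean([p[0] for p in pairs])),
            float(np.mean([p[1] for p in pairs])),
        )
    return values[spec]


def assemble_series(
    visits: list[RawVisit],
    group: str,
    ref_neglog_min: float,
    ref_neglog_max: float,
    clamp: bool = False,
) -> list[SubjectSeries]:
    """Build analysis series from a subject's raw visits.

    Immediate group: Pre1 is dropped (pre-therapy), Pre2/Post2 are averaged,
    giving 7 points on the 4-month grid. Delayed group: Pre1/Post1 are
    averaged, giving a 4-point pre-therapy series [mean(Pre1,Post1), M4, M8,
    Pre2] and a 4-point post-therapy series [Post2, M16, M20, M24].
    Averaging happens on the normalized values. A missing visit excludes the
    subject (raises :class:`IncompleteSubjectError`).
    """
    if group not in ("immediate", "delayed"):
        raise ValueError(f"unknown group {group!r}")
    by_label: dict[str, tuple[float, float]] = {}
    subject_id = None
    for v in visits:
        subject_id = v.subject_id if subject_id is None else subject_id
        if v.subject_id != subject_id:
            raise ValueError("visits from more than one subject")
        f = wmft_to_function(v.wmft_time_affected, ref_neglog_min, ref_neglog_max, clamp=clamp)
        u = aou_to_use(v.aou_items)
        by_label[v.visit_label] = (f, u)
    missing = set(VISIT_LABELS) - set(by_label)
    if missing:
        raise IncompleteSubjectError(
            f"subject {subject_id}: missing visits {sorted(missing)}"
        )

    def series(schedule, phase: str) -> SubjectSeries:
        pts = [_pick(by_label, s) for s in schedule]
        n = len(pts)
        return SubjectSeries(
            subject_id=subject_id,
            group=group,
            phase=phase,
            times=np.arange(n) * STEP_MONTHS,
            F=np.array([p[0] for p in pts]),
            U=np.array([p[1] for p in pts]),
        )

    if group == "immediate":
        return [series(_IMMEDIATE_SCHEDULE, "post_therapy")]
    return [series(_DELAYED_PRE, "pre_therapy"), series(_DELAYED_POST, "post_therapy")]


# ---------------------------------------------------------------------------
# State updates


def _check_params(model: CandidateModel, params) -> np.ndarray:
    params = np.atleast_1d(np.asarray(params, dtype=float))
    if params.shape != (model.n_params,):
        raise ValueError(
            f"{model.id} expects {model.n_params} parameter(s), got {params.shape}"
        )
    return params


def function_step(model_id: str, params, F_prev: float, U_prev: float) -> float:
    """One step of a function-candidate update."""
    model = FUNCTION_CANDIDATES.get(model_id)
    if model is None:
        raise ValueError(f"{model_id!r} is not a function candidate")
    p = _check_params(model, params)
    if model_id == "F1_fw":
        return p[0] * F_prev
    if model_id == "F2_fw_const":
        return p[0] * F_prev + p[1]
    if model_id == "F1_uw":
        return p[0] * U_prev
    if model_id == "F2_uw_const":
        return p[0] * U_prev + p[1]
    if model_id == "F1_weighted":
        return (1.0 - p[0]) * F_prev + p[0] * U_prev
    if model_id == "F2_fw_uw":
        return p[0] * F_prev + p[1] * U_prev
    # F3_fw_uw_const
    return p[0] * F_prev + p[1] * U_prev + p[2]


def use_step(model_id: str, params, F_arg: float) -> float:
    """One step of a use-candidate update; ``F_arg`` is F at the row's lag."""
    model = USE_CANDIDATES.get(model_id)
    if model is None:
        raise ValueError(f"{model_id!r} is not a use candidate")
    p = _check_params(model, params)
    if model.link == "sigmoid":
        return float(expit(p[0] * F_arg - p[1]))
    return float(p[0] * F_arg + p[1])


def simulate_pair(
    function_id: str,
    function_params,
    use_id: str,
    use_params,
    F0: float,
    U0: float,
    n_steps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate an arbitrary (function, use) candidate pair for n_steps.

    Per step: the function update consumes the previous state, then the use
    update consumes F at its own lag (current F for lag-0 rows, previous F
    for lag-1 rows). Returns arrays of length ``n_steps + 1`` including the
    initial state. Values are not clipped; closure to [0, 1] holds for the
    reference pair with a in [0, 1].
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    use_model = USE_CANDIDATES[use_id]
    F = np.empty(n_steps + 1)
    U = np.empty(n_steps + 1)
    F[0], U[0] = float(F0), float(U0)
    for t in range(1, n_steps + 1):
        F[t] = function_step(function_id, function_params, F[t - 1], U[t - 1])
        f_arg = F[t] if use_model.lag == 0 else F[t - 1]
        U[t] = use_step(use_id, use_params, f_arg)
    return F, U


def simulate_trajectory(
    params: ModelParams, F0: float, U0: float, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate the coupled reference model from (F0, U0)."""
    return simulate_pair(
        REFERENCE_FUNCTION_ID, [params.a],
        REFERENCE_USE_ID, [params.b, params.c],
        F0, U0, n_steps,
    )


def decay_time_constant(a: float, step_months: float = STEP_MONTHS) -> float:
    """Forgetting time constant of function under zero use, in months.

    With U = 0 the function update is a geometric decay with per-step factor
    (1 - a); in continuous time that corresponds to a time constant of
    ``step / a`` months.
    """
    if a <= 0:
        raise ValueError("use-effect rate must be positive for a finite time constant")
    return step_months / a
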