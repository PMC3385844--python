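"""Empirical-Bayes linear regression (evidence maximization) for the model family.

Each candidate is linearized into a small regression problem ``y = Phi w + e``
with iid Gaussian noise of precision ``beta`` and an iid Gaussian prior
``w ~ N(m0, alpha^{-1} I)`` with a *nonzero* mean. The two hyperparameters
are tuned by maximizing the marginal likelihood (model evidence) with the
classic fixed-point iteration:

    mN    = (alpha I + beta Phi' Phi)^{-1} (beta Phi' y + alpha m0)
    gamma = sum_i lambda_i / (alpha + lambda_i),  lambda_i eig of beta Phi'Phi
    alpha = gamma / ||mN - m0||^2
    beta  = (L - gamma) / ||y - Phi mN||^2

repeated to convergence, after which the log evidence

    log p(y) = M/2 log alpha + L/2 log beta - E(mN)
               - 1/2 log|A| - L/2 log 2 pi,
    E(mN)    = beta/2 ||y - Phi mN||^2 + alpha/2 ||mN - m0||^2,
    A        = alpha I + beta Phi' Phi

is reported together with its additive breakdown. Because the model is
linear-Gaussian, this expression is *exact* and equals the closed-form
Gaussian marginal log density of ``y`` under
``N(Phi m0, beta^{-1} I + alpha^{-1} Phi Phi')`` — exposed here as
:func:`log_evidence_oracle` for independent verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit
from scipy.stats import multivariate_normal

from .models import CANDIDATES, REFERENCE_FUNCTION_ID, CandidateModel, SubjectSeries

__all__ = [
    "RegressionProblem",
    "PriorSpec",
    "PosteriorFit",
    "DEFAULT_LOGIT_EPS",
    "build_regression",
    "ml_fit",
    "evidence_fit",
    "log_evidence_oracle",
    "pooled_prior_means",
    "fit_cohort",
    "fits_to_frame",
    "frame_to_fits",
]

#: Clipping margin applied to U before the logit for sigmoid rows; the
#: amount-of-use scale produces exact 0s and 1s which the logit cannot take.
DEFAULT_LOGIT_EPS = 1e-4

#: Near-flat default hyperparameter initialization: prior precision 1e-11
#: with prior/noise precision ratio 1e-3.
DEFAULT_ALPHA0 = 1e-11
DEFAULT_BETA0 = 1e-8


@dataclass
class RegressionProblem:
    """Linearized candidate: target vector y (length L), design Phi (L x M)."""

    y: np.ndarray
    Phi: np.ndarray
    candidate_id: str
    #: time indices of the series each row consumes (used to drop rows that
    #: span a held-out point in leave-one-out evaluation)
    row_points: list[tuple[int, ...]] = field(default_factory=list)
    #: per-row log |dy/dU| for candidates whose regression target is a
    #: nonlinear transform of the observed variable (the logit rows); makes
    #: evidences comparable across links on the observation scale
    row_log_jacobian: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.Phi = np.asarray(self.Phi, dtype=float)
        if self.Phi.ndim != 2 or self.Phi.shape[0] != self.y.shape[0]:
            raise ValueError("Phi must be L x M with L = len(y)")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.Phi))):
            raise ValueError("non-finite entries in regression problem")

    @property
    def L(self) -> int:
        return self.y.shape[0]

    @property
    def M(self) -> int:
        return self.Phi.shape[1]

    @property
    def log_jacobian(self) -> float:
        if self.row_log_jacobian is None:
            return 0.0
        return float(np.sum(self.row_log_jacobian))

    def drop_rows(self, mask) -> "RegressionProblem":
        mask = np.asarray(mask, dtype=bool)
        keep = ~mask
        return RegressionProblem(
            y=self.y[keep],
            Phi=self.Phi[keep],
            candidate_id=self.candidate_id,
            row_points=[rp for rp, k in zip(self.row_points, keep) if k],
            row_log_jacobian=(
                None if self.row_log_jacobian is None else self.row_log_jacobian[keep]
            ),
        )


@dataclass
class PriorSpec:
    """Gaussian prior mean and initial hyperparameters (precisions)."""

    m0: np.ndarray
    prior_precision0: float = DEFAULT_ALPHA0
    noise_precision0: float = DEFAULT_BETA0

    def __post_init__(self) -> None:
        self.m0 = np.atleast_1d(np.asarray(self.m0, dtype=float))
        if self.prior_precision0 <= 0 or self.noise_precision0 <= 0:
            raise ValueError("precisions must be positive")


@dataclass
class PosteriorFit:
    """Converged posterior and evidence for one subject x candidate."""

    candidate_id: str
    mN: np.ndarray
    SN_precision: np.ndarray
    prior_precision: float
    noise_precision: float
    log_evidence: float
    evidence_terms: dict
    effective_dof: float
    n_iter: int
    converged: bool
    posterior_sd: np.ndarray
    m0: np.ndarray
    subject_id: str = ""
    phase: str = ""
    L: int = 0
    #: change-of-variables correction (0 for linear-target rows); add to
    #: log_evidence to compare candidates across links on the U scale
    log_jacobian: float = 0.0

    @property
    def log_evidence_obs(self) -> float:
        """Log evidence on the observation scale (Jacobian-corrected)."""
        return self.log_evidence + self.log_jacobian


def build_regression(
    candidate_id: str, series: SubjectSeries, logit_eps: float = DEFAULT_LOGIT_EPS
) -> RegressionProblem:
    """Linearize one candidate against a subject's series.

    All candidates use the L = n-1 transitions from the second point onward.
    The reference function model is rearranged so its single parameter is the
    regression weight: ``F(t) - F(t-1) = a (U(t-1) - F(t-1))``. Sigmoid use
    rows take ``logit(U(t))`` as target (U clipped away from {0, 1}) with
    design columns ``[F(lag), -1]``, so the fitted vector is ``(b, c)``.
    """
    model = CANDIDATES.get(candidate_id)
    if model is None:
        raise ValueError(f"unknown candidate {candidate_id!r}")
    n = len(series)
    if n < 2:
        raise ValueError("series must have at least 2 points")
    if not (0.0 < logit_eps < 0.5):
        raise ValueError("logit_eps must lie in (0, 0.5)")
    F, U = series.F, series.U
    t = np.arange(1, n)

    if model.target == "function":
        if candidate_id == REFERENCE_FUNCTION_ID:
            y = F[t] - F[t - 1]
            Phi = (U[t - 1] - F[t - 1])[:, None]
        else:
            y = F[t]
            cols = []
            for reg in model.regressors:
                if reg == "F(t-1)":
                    cols.append(F[t - 1])
                elif reg == "U(t-1)":
                    cols.append(U[t - 1])
                elif reg == "const":
                    cols.append(np.ones_like(y))
            Phi = np.column_stack(cols)
        row_points = [(int(i - 1), int(i)) for i in t]
    else:
        if np.any(U < 0) or np.any(U > 1):
            raise ValueError("U must lie in [0, 1]")
        f_arg = F[t] if model.lag == 0 else F[t - 1]
        row_log_jacobian = None
        if model.link == "sigmoid":
            u_clip = np.clip(U[t], logit_eps, 1.0 - logit_eps)
            y = logit(u_clip)
            Phi = np.column_stack([f_arg, -np.ones_like(y)])
            # d logit(U)/dU = 1/(U(1-U)): puts the logit-target evidence on
            # the observation (U) scale for comparison with linear rows
            row_log_jacobian = -np.log(u_clip * (1.0 - u_clip))
        else:
            y = U[t]
            Phi = np.column_stack([f_arg, np.ones_like(y)])
        if model.lag == 0:
            row_points = [(int(i),) for i in t]
        else:
            row_points = [(int(i - 1), int(i)) for i in t]
        return RegressionProblem(
            y=y, Phi=Phi, candidate_id=candidate_id,
            row_points=row_points, row_log_jacobian=row_log_jacobian,
        )

    return RegressionProblem(y=y, Phi=Phi, candidate_id=candidate_id, row_points=row_points)


def ml_fit(problem: RegressionProblem) -> np.ndarray:
    """Ordinary least squares solution (minimum-norm if rank-deficient)."""
    w, _, rank, _ = np.linalg.lstsq(problem.Phi, problem.y, rcond=None)
    if rank < problem.M:
        import warnings

        warnings.warn(
            f"rank-deficient design for {problem.candidate_id}; "
            "minimum-norm solution returned",
            stacklevel=2,
        )
    return w


def _posterior(problem, alpha, beta, m0):
    A = alpha * np.eye(problem.M) + beta * (problem.Phi.T @ problem.Phi)
    rhs = beta * (problem.Phi.T @ problem.y) + alpha * m0
    mN = np.linalg.solve(A, rhs)
    return A, mN


def _log_evidence(problem, alpha, beta, m0, A, mN):
    resid = problem.y - problem.Phi @ mN
    data_term = 0.5 * beta * float(resid @ resid)
    reg_term = 0.5 * alpha * float((mN - m0) @ (mN - m0))
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior precision not positive definite")
    le = (
        0.5 * problem.M * np.log(alpha)
        + 0.5 * problem.L * np.log(beta)
        - data_term
        - reg_term
        - 0.5 * logdet
        - 0.5 * problem.L * np.log(2.0 * np.pi)
    )
    terms = {
        "data_misfit": data_term,
        "regularization": reg_term,
        "log_det": 0.5 * logdet,
    }
    return float(le), terms


def evidence_fit(
    problem: RegressionProblem,
    prior: PriorSpec,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> PosteriorFit:
    """Fit by iterative evidence maximization over (alpha, beta).

    Stops when the relative change of both hyperparameters falls below
    ``tol``. Degenerate updates (zero residual or posterior mean exactly at
    the prior mean) leave the last finite state with ``converged=False`` —
    the regime in which the data cannot pin the parameter distribution down.
    """
    m0 = prior.m0
    if m0.shape != (problem.M,):
        raise ValueError(f"prior mean has shape {m0.shape}, expected ({problem.M},)")
    alpha = float(prior.prior_precision0)
    beta = float(prior.noise_precision0)
    gram = problem.Phi.T @ problem.Phi
    base_eigs = np.linalg.eigvalsh(gram)
    base_eigs = np.clip(base_eigs, 0.0, None)

    A, mN = _posterior(problem, alpha, beta, m0)
    gamma = float(np.sum(beta * base_eigs / (alpha + beta * base_eigs)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = beta * base_eigs
        gamma = float(np.sum(lam / (alpha + lam)))
        dm2 = float((mN - m0) @ (mN - m0))
        resid = problem.y - problem.Phi @ mN
        r2 = float(resid @ resid)
        # degenerate updates: zero residual (interpolation) or posterior mean
        # at the prior mean make a hyperparameter unbounded; stop at the last
        # finite state instead of chasing the singularity
        y2 = float(problem.y @ problem.y)
        if (
            dm2 <= 1e-12 * max(1.0, float(m0 @ m0))
            or r2 <= 1e-12 * max(1.0, y2)
            or gamma <= 1e-12
            or gamma >= problem.L - 1e-8
        ):
            break
        alpha_new = gamma / dm2
        beta_new = (problem.L - gamma) / r2
        rel = max(
            abs(alpha_new - alpha) / alpha,
            abs(beta_new - beta) / beta,
        )
        alpha, beta = alpha_new, beta_new
        A, mN = _posterior(problem, alpha, beta, m0)
        if rel < tol:
            converged = True
            break

    log_ev, terms = _log_evidence(problem, alpha, beta, m0, A, mN)
    posterior_sd = np.sqrt(np.diag(np.linalg.inv(A)))
    return PosteriorFit(
        candidate_id=problem.candidate_id,
        mN=mN,
        SN_precision=A,
        prior_precision=alpha,
        noise_precision=beta,
        log_evidence=log_ev,
        evidence_terms=terms,
        effective_dof=gamma,
        n_iter=it,
        converged=converged,
        posterior_sd=posterior_sd,
        m0=m0.copy(),
        L=problem.L,
        log_jacobian=problem.log_jacobian,
    )


def log_evidence_oracle(
    problem: RegressionProblem,
    prior_precision: float,
    noise_precision: float,
    m0,
) -> float:
    """Closed-form marginal log likelihood: ``y ~ N(Phi m0, B + a^-1 Phi Phi')``.

    Independent of the evidence-iteration bookkeeping; used as a cross-check
    of the additive evidence expression.
    """
    if prior_precision <= 0 or noise_precision <= 0:
        raise ValueError("precisions must be positive")
    m0 = np.atleast_1d(np.asarray(m0, dtype=float))
    mean = problem.Phi @ m0
    cov = (
        np.eye(problem.L) / noise_precision
        + (problem.Phi @ problem.Phi.T) / prior_precision
    )
    return float(multivariate_normal(mean=mean, cov=cov).logpdf(problem.y))


def pooled_prior_means(
    cohort: list[SubjectSeries],
    candidate_id: str,
    logit_eps: float = DEFAULT_LOGIT_EPS,
    prior_precision0: float = DEFAULT_ALPHA0,
    noise_precision0: float = DEFAULT_BETA0,
) -> PriorSpec:
    """Prior means pooled over the cohort by stacked maximum likelihood.

    All subjects' transitions are stacked into one regression and solved by
    least squares. The reference weighted-average function model instead gets
    the fixed prior mean 1 (full carry-over of use into function).
    """
    if not cohort:
        raise ValueError("empty cohort")
    model: CandidateModel = CANDIDATES[candidate_id]
    if candidate_id == REFERENCE_FUNCTION_ID:
        m0 = np.array([1.0])
    else:
        problems = [build_regression(candidate_id, s, logit_eps) for s in cohort]
        stacked = RegressionProblem(
            y=np.concatenate([p.y for p in problems]),
            Phi=np.vstack([p.Phi for p in problems]),
            candidate_id=candidate_id,
        )
        m0 = ml_fit(stacked)
    assert m0.shape == (model.n_params,)
    return PriorSpec(m0=m0, prior_precision0=prior_precision0, noise_precision0=noise_precision0)


_MAX_PARAMS = 3


def fits_to_frame(fits: list[PosteriorFit]):
    """Flatten fits to one row per subject x candidate x phase."""
    import pandas as pd

    rows = []
    for f in fits:
        model = CANDIDATES[f.candidate_id]
        row = {
            "subject_id": f.subject_id,
            "phase": f.phase,
            "candidate_id": f.candidate_id,
            "target": model.target,
            "L": f.L,
            "prior_precision": f.prior_precision,
            "noise_precision": f.noise_precision,
            "log_evidence": f.log_evidence,
            "log_jacobian": f.log_jacobian,
            "effective_dof": f.effective_dof,
            "converged": f.converged,
            "n_iter": f.n_iter,
        }
        for i in range(_MAX_PARAMS):
            row[f"m{i + 1}"] = f.mN[i] if i < len(f.mN) else np.nan
            row[f"m0_{i + 1}"] = f.m0[i] if i < len(f.m0) else np.nan
            row[f"sd{i + 1}"] = f.posterior_sd[i] if i < len(f.posterior_sd) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_fits(frame) -> list[PosteriorFit]:
    """Rebuild lightweight fits from a flattened results frame.

    Posterior precision matrices are not stored in the CSV, so the
    reconstructed fits carry only the diagonal information needed by the
    comparison and therapy-effect stages.
    """
    fits: list[PosteriorFit] = []
    for _, row in frame.iterrows():
        model = CANDIDATES[row["candidate_id"]]
        m = model.n_params
        mN = np.array([row[f"m{i + 1}"] for i in range(m)], dtype=float)
        m0 = np.array([row[f"m0_{i + 1}"] for i in range(m)], dtype=float)
        sd = np.array([row[f"sd{i + 1}"] for i in range(m)], dtype=float)
        fits.append(
            PosteriorFit(
                candidate_id=row["candidate_id"],
                mN=mN,
                SN_precision=np.diag(1.0 / sd**2),
                prior_precision=float(row["prior_precision"]),
                noise_precision=float(row["noise_precision"]),
                log_evidence=float(row["log_evidence"]),
                evidence_terms={},
                effective_dof=float(row["effective_dof"]),
                n_iter=int(row["n_iter"]),
                converged=bool(row["converged"]),
                posterior_sd=sd,
                m0=m0,
                subject_id=str(row["subject_id"]),
                phase=str(row["phase"]),
                L=int(row["L"]),
                log_jacobian=float(row.get("log_jacobian", 0.0)),
            )
        )
    return fits


def fit_cohort(
    cohort: list[SubjectSeries],
    candidate_ids,
    logit_eps: float = DEFAULT_LOGIT_EPS,
    prior_precision0: float = DEFAULT_ALPHA0,
    noise_precision0: float = DEFAULT_BETA0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> list[PosteriorFit]:
    """Fit every candidate to every subject with cohort-pooled prior means."""
    fits: list[PosteriorFit] = []
    for cid in candidate_ids:
        prior = pooled_prior_means(
            cohort, cid, logit_eps,
            prior_precision0=prior_precision0,
            noise_precision0=noise_precision0,
        )
        for s in cohort:
            problem = build_regression(cid, s, logit_eps)
            fit = evidence_fit(problem, prior, tol=tol, max_iter=max_iter)
            fit.subject_id = s.subject_id
            fit.phase = s.phase
            fits.append(fit)
    return fits
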