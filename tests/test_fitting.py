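"""Linearization and empirical-Bayes evidence maximization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from armdyn.fitting import (
    PriorSpec,
    RegressionProblem,
    build_regression,
    evidence_fit,
    fit_cohort,
    fits_to_frame,
    frame_to_fits,
    log_evidence_oracle,
    ml_fit,
    pooled_prior_means,
)
from armdyn.synth import SynthConfig, generate_cohort, generate_cohort_with_params

from conftest import make_series


def random_problem(rng, L=None, M=None):
    L = L or int(rng.integers(3, 11))
    M = M or int(rng.integers(1, min(4, L)))
    return RegressionProblem(
        y=rng.normal(size=L), Phi=rng.normal(size=(L, M)), candidate_id="F1_fw"
    )


class TestBuildRegression:
    def test_reference_function_single_transition(self):
        s = make_series([0.2, 0.4], [0.6, 0.5])
        p = build_regression("F1_weighted", s)
        assert p.y == pytest.approx([0.2])
        assert p.Phi.ravel() == pytest.approx([0.4])
        assert p.row_points == [(0, 1)]

    def test_transition_count_is_length_minus_one(self, small_cohort):
        for cid in ("F1_weighted", "F3_fw_uw_const", "U_sig_lag", "U_lin_t"):
            p = build_regression(cid, small_cohort[0])
            assert p.L == len(small_cohort[0]) - 1

    def test_sigmoid_target_is_logit(self):
        s = make_series([0.3, 0.4, 0.5], [0.2, 0.5, 1.0])
        p = build_regression("U_sig_lag", s, logit_eps=1e-4)
        assert p.y[0] == pytest.approx(0.0)  # logit(0.5)
        assert p.y[1] == pytest.approx(logit(1 - 1e-4))  # boundary clipping
        # design columns are [F(t-1), -1] so the fitted vector is (b, c)
        assert p.Phi[:, 1] == pytest.approx([-1.0, -1.0])

    def test_lag_zero_rows_consume_single_point(self):
        s = make_series([0.3, 0.4, 0.5], [0.2, 0.5, 0.6])
        p = build_regression("U_sig_t", s)
        assert p.row_points == [(1,), (2,)]

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            build_regression("F1_fw", make_series([0.5], [0.5]))


class TestMlFit:
    def test_exact_recovery_on_noiseless_data(self, rng):
        Phi = rng.normal(size=(8, 2))
        w = np.array([0.7, -0.3])
        p = RegressionProblem(y=Phi @ w, Phi=Phi, candidate_id="U_lin_lag")
        assert ml_fit(p) == pytest.approx(w, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            p = random_problem(rng)
            w_oracle = np.linalg.solve(p.Phi.T @ p.Phi, p.Phi.T @ p.y)
            assert ml_fit(p) == pytest.approx(w_oracle, abs=1e-10)

    def test_scalar_normal_equation(self, rng):
        p = random_problem(rng, L=6, M=1)
        phi = p.Phi[:, 0]
        assert ml_fit(p)[0] == pytest.approx(np.sum(phi * p.y) / np.sum(phi**2))


class TestEvidenceFit:
    def test_matches_closed_form_oracle(self, rng):
        worst = 0.0
        for _ in range(200):
            p = random_problem(rng)
            m0 = rng.normal(size=p.M)
            fit = evidence_fit(p, PriorSpec(m0=m0))
            orc = log_evidence_oracle(p, fit.prior_precision, fit.noise_precision, m0)
            worst = max(worst, abs(fit.log_evidence - orc))
        assert worst < 1e-8

    def test_frequentist_limit(self, rng):
        # vanishing prior precision leaves the least-squares solution
        p = random_problem(rng, L=8, M=2)
        prior = PriorSpec(m0=np.zeros(2), prior_precision0=1e-15, noise_precision0=1.0)
        fit = evidence_fit(p, prior, max_iter=0)
        assert fit.mN == pytest.approx(ml_fit(p), abs=1e-8)

    def test_posterior_precision_identity(self, rng):
        p = random_problem(rng, L=7, M=2)
        fit = evidence_fit(p, PriorSpec(m0=np.zeros(2)))
        expected = fit.prior_precision * np.eye(2) + fit.noise_precision * (p.Phi.T @ p.Phi)
        assert fit.SN_precision == pytest.approx(expected)

    def test_monotone_shrinkage_toward_prior_mean(self, rng):
        from armdyn.fitting import _posterior

        p = random_problem(rng, L=8, M=2)
        m0 = np.array([0.3, -0.2])
        dists = []
        for alpha in (1e-6, 1e-2, 1.0, 1e2, 1e6):
            _, mN = _posterior(p, alpha, 1.0, m0)
            dists.append(np.linalg.norm(mN - m0))
        assert all(d1 >= d2 - 1e-12 for d1, d2 in zip(dists, dists[1:]))

    def test_degenerate_zero_residual_flagged(self):
        # perfectly interpolable data leaves the noise update undefined
        Phi = np.array([[1.0], [2.0]])
        p = RegressionProblem(y=Phi[:, 0] * 0.5, Phi=Phi, candidate_id="F1_fw")
        fit = evidence_fit(p, PriorSpec(m0=np.array([0.5])))
        assert not fit.converged
        assert np.all(np.isfinite(fit.mN))

    def test_parameter_recovery_within_three_sds(self):
        """On reference-model data (noise sd 0.02) the converged posterior
        traps the generating use-effect rate within 3 sds >= 95% of the time."""
        from armdyn.synth import TruncNormal

        cfg = SynthConfig(
            n_subjects=500, seed=202, noise_sd=0.02,
            a_dist=TruncNormal(0.6, 0.0, 0.0, 1.0),
        )
        cohort, truth = generate_cohort_with_params(cfg)
        prior = PriorSpec(m0=np.array([1.0]))
        hits = total = 0
        for s in cohort:
            fit = evidence_fit(build_regression("F1_weighted", s), prior)
            if not fit.converged:
                continue
            total += 1
            hits += abs(fit.mN[0] - 0.6) <= 3 * fit.posterior_sd[0]
        assert total > 300
        assert hits / total >= 0.95


class TestPooledPriors:
    def test_reference_function_prior_mean_is_one(self, small_cohort):
        assert pooled_prior_means(small_cohort, "F1_weighted").m0 == pytest.approx([1.0])

    def test_default_hyperparameters(self, small_cohort):
        prior = pooled_prior_means(small_cohort, "U_sig_lag")
        assert prior.prior_precision0 == pytest.approx(1e-11)
        assert prior.noise_precision0 == pytest.approx(1e-8)

    def test_noiseless_cohort_recovers_generating_sigmoid(self):
        from armdyn.synth import TruncNormal

        cfg = SynthConfig(
            n_subjects=10, seed=4, noise_sd=0.0,
            b_dist=TruncNormal(3.0, 0.0), c_dist=TruncNormal(2.0, 0.0),
        )
        cohort = generate_cohort(cfg)
        prior = pooled_prior_means(cohort, "U_sig_lag")
        assert prior.m0 == pytest.approx([3.0, 2.0], abs=1e-6)

    def test_single_subject_equals_own_ml(self, small_cohort):
        s = small_cohort[0]
        prior = pooled_prior_means([s], "U_lin_lag")
        assert prior.m0 == pytest.approx(ml_fit(build_regression("U_lin_lag", s)))

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            pooled_prior_means([], "F1_fw")


class TestResultsRoundTrip:
    def test_frame_round_trip_preserves_comparison_fields(self, small_cohort):
        fits = fit_cohort(small_cohort[:5], ["F1_weighted", "U_sig_lag"])
        back = frame_to_fits(fits_to_frame(fits))
        assert len(back) == len(fits)
        for a, b in zip(fits, back):
            assert a.candidate_id == b.candidate_id
            assert a.log_evidence == pytest.approx(b.log_evidence)
            assert a.log_jacobian == pytest.approx(b.log_jacobian)
            assert a.mN == pytest.approx(b.mN)
            assert a.posterior_sd == pytest.approx(b.posterior_sd)


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_evidence_oracle_equivalence_property(seed):
    """Eq-(10)-style additive evidence equals the Gaussian marginal density
    for arbitrary well-posed problems (L > M)."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(3, 11))
    M = int(rng.integers(1, min(4, L)))
    p = RegressionProblem(y=rng.normal(size=L), Phi=rng.normal(size=(L, M)), candidate_id="x")
    m0 = rng.normal(size=M)
    fit = evidence_fit(p, PriorSpec(m0=m0))
    orc = log_evidence_oracle(p, fit.prior_precision, fit.noise_precision, m0)
    assert fit.log_evidence == pytest.approx(orc, abs=1e-8)
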