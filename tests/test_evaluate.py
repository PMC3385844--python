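"""Leave-one-out prediction, randomized baseline, therapy effects, trends."""

import numpy as np
import pytest

from armdyn.evaluate import (
    LOO_INDICES,
    classify_use_trend,
    filter_low_function,
    loo_cohort,
    loo_evaluate,
    randomized_baseline,
    therapy_effect,
)
from armdyn.fitting import fit_cohort
from armdyn.models import REFERENCE_FUNCTION_ID, REFERENCE_USE_ID
from armdyn.synth import SynthConfig, generate_cohort

from conftest import make_series


class TestLeaveOneOut:
    def test_held_out_indices_are_interior(self, noiseless_cohort):
        results = loo_evaluate(noiseless_cohort[0])
        assert [r.left_out_index for r in results] == list(LOO_INDICES) == [2, 3, 4, 5, 6]

    def test_zero_error_on_noiseless_model_data(self, noiseless_cohort):
        # zero up to the hyperparameter convergence tolerance of the refits
        for s in noiseless_cohort:
            for r in loo_evaluate(s):
                assert r.abs_error_F < 1e-5
                assert r.abs_error_U < 1e-5

    def test_requires_seven_points(self):
        s = make_series([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            loo_evaluate(s)

    def test_error_near_noise_floor(self):
        """Cohort-mean absolute LOO error lies within [0.5x, 3x] of the
        observation-scale noise floor the generator actually injects
        (target noise sd 0.05; for use the floor is the logit-space noise
        mapped through the sigmoid, measured against a noise-free replay)."""
        from armdyn.models import simulate_pair
        from armdyn.synth import generate_cohort_with_params

        cfg = SynthConfig(n_subjects=200, seed=21, noise_sd=0.05)
        cohort, truth = generate_cohort_with_params(cfg)
        floor_F, floor_U = [], []
        for s in cohort:
            tp = truth[s.subject_id]
            # noise-free replay by an oracle knowing the true parameters,
            # simulated from the first point like the LOO predictor
            Fr, Ur = simulate_pair(
                "F1_weighted", tp["function"], "U_sig_lag", tp["use"],
                s.F[0], s.U[0], len(s) - 1,
            )
            for t in range(1, len(s) - 1):
                floor_F.append(abs(Fr[t] - s.F[t]))
                floor_U.append(abs(Ur[t] - s.U[t]))
        errs = loo_cohort(cohort)
        for col, floor in (("abs_error_F", np.mean(floor_F)), ("abs_error_U", np.mean(floor_U))):
            m = errs[col].mean()
            assert 0.5 * floor <= m <= 3 * floor, (col, m, floor)

    def test_one_step_mode_also_self_consistent(self, noiseless_cohort):
        for r in loo_evaluate(noiseless_cohort[0], mode="one_step"):
            assert r.abs_error_F < 1e-6 and r.abs_error_U < 1e-6


class TestRandomizedBaseline:
    def test_identical_subjects_zero_error(self, noiseless_cohort):
        clones = []
        for i in range(4):
            s = noiseless_cohort[0]
            clones.append(make_series(s.F, s.U, subject_id=f"c{i}"))
        table = randomized_baseline(clones, rng_seed=1)
        assert (table["abs_error_F"] == 0).all() and (table["abs_error_U"] == 0).all()

    def test_seeded_determinism(self, small_cohort):
        t1 = randomized_baseline(small_cohort, rng_seed=99)
        t2 = randomized_baseline(small_cohort, rng_seed=99)
        assert t1.equals(t2)

    def test_single_subject_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            randomized_baseline(small_cohort[:1], rng_seed=0)

    def test_model_beats_baseline_on_heterogeneous_cohort(self):
        cohort = generate_cohort(SynthConfig(n_subjects=48, seed=5))
        model = loo_cohort(cohort)
        base = randomized_baseline(cohort, rng_seed=5)
        assert model["abs_error_F"].mean() < base["abs_error_F"].mean()
        assert model["abs_error_U"].mean() < base["abs_error_U"].mean()


class TestTherapyEffect:
    @staticmethod
    def _fits(cohort, phase):
        sub = [s for s in cohort if s.phase == phase]
        return fit_cohort(sub, [REFERENCE_FUNCTION_ID, REFERENCE_USE_ID])

    def test_identical_phases_give_null_result(self):
        cohort = generate_cohort(SynthConfig(n_subjects=10, group="delayed", seed=3))
        pre = self._fits(cohort, "pre_therapy")
        effects = therapy_effect(pre, pre)
        for e in effects:
            assert e.t_stat == 0.0 and e.p_two_tailed == 1.0
            assert e.mean_before == e.mean_after

    def test_constant_shift_detected(self):
        from armdyn.fitting import PosteriorFit

        def fits(vals, cid):
            out = []
            for i, v in enumerate(vals):
                m = np.atleast_1d(v)
                out.append(
                    PosteriorFit(
                        candidate_id=cid, mN=m, SN_precision=np.eye(len(m)),
                        prior_precision=1, noise_precision=1, log_evidence=0.0,
                        evidence_terms={}, effective_dof=1, n_iter=1, converged=True,
                        posterior_sd=np.full(len(m), 0.1), m0=np.zeros(len(m)),
                        subject_id=f"s{i}",
                    )
                )
            return out

        rng = np.random.default_rng(0)
        a_pre = rng.uniform(0.3, 0.9, size=12)
        pre = fits(a_pre, REFERENCE_FUNCTION_ID) + fits(
            [(b, c) for b, c in zip(rng.normal(2, 1, 12), rng.normal(1, 1, 12))],
            REFERENCE_USE_ID,
        )
        post = fits(a_pre + 0.2, REFERENCE_FUNCTION_ID) + fits(
            [(b, c) for b, c in zip(rng.normal(2, 1, 12), rng.normal(1, 1, 12))],
            REFERENCE_USE_ID,
        )
        effects = {e.parameter: e for e in therapy_effect(pre, post)}
        assert effects["a"].p_two_tailed < 1e-10  # zero within-pair variance
        assert effects["a"].mean_after - effects["a"].mean_before == pytest.approx(0.2)

    def test_confidence_shift_power(self):
        """A +1.5 shift applied to the sigmoid slope after therapy is detected
        for b in >= 80% of replicates, while a and c reject less often."""
        rej = {"a": 0, "b": 0, "c": 0}
        n_rep = 15
        for rep in range(n_rep):
            cohort = generate_cohort(
                SynthConfig(n_subjects=30, group="delayed", seed=500 + rep, therapy_shift=1.5)
            )
            effects = therapy_effect(
                self._fits(cohort, "pre_therapy"), self._fits(cohort, "post_therapy")
            )
            for e in effects:
                rej[e.parameter] += e.p_two_tailed < 0.05
        assert rej["b"] / n_rep >= 0.8
        assert rej["a"] < rej["b"] and rej["c"] < rej["b"]

    def test_too_few_pairs_rejected(self):
        cohort = generate_cohort(SynthConfig(n_subjects=1, group="delayed", seed=3))
        pre = self._fits(cohort, "pre_therapy")
        post = self._fits(cohort, "post_therapy")
        with pytest.raises(ValueError):
            therapy_effect(pre, post)


class TestUseTrend:
    def test_linear_trends(self):
        t = np.arange(7) * 4.0
        assert classify_use_trend(0.1 + 0.02 * t, t) == "increase"
        assert classify_use_trend(0.9 - 0.02 * t, t) == "decrease"
        assert classify_use_trend(np.full(7, 0.4), t) == "no_change"

    def test_affine_time_invariance(self):
        rng = np.random.default_rng(2)
        t = np.arange(7) * 4.0
        for _ in range(20):
            u = np.clip(rng.uniform(0.2, 0.8) + rng.normal(0, 0.1, size=7), 0, 1)
            assert classify_use_trend(u, t) == classify_use_trend(u, 3.0 * t + 11.0)

    def test_requires_time_variance(self):
        with pytest.raises(ValueError):
            classify_use_trend([0.1, 0.2, 0.3], [1.0, 1.0, 1.0])

    def test_category_proportions_recovered(self):
        """Cohorts seeded at the three archetypes (rising, falling, flat use)
        land mostly in the matching category."""
        from armdyn.models import simulate_trajectory, ModelParams

        t = np.arange(7) * 4.0
        rng = np.random.default_rng(6)
        # rising: high confidence; falling: strong bias; flat: balanced
        archetypes = {
            "increase": ModelParams(0.6, 6.0, 2.5),
            "decrease": ModelParams(0.6, 3.36, 3.03),
            "no_change": ModelParams(0.3, 2.0, 1.0),
        }
        starts = {"increase": (0.55, 0.3), "decrease": (0.7, 0.75), "no_change": (0.5, 0.5)}
        for label, params in archetypes.items():
            hits = 0
            for _ in range(30):
                F0, U0 = starts[label]
                _, U = simulate_trajectory(params, F0, U0, 6)
                u = np.clip(U + rng.normal(0, 0.02, size=7), 0, 1)
                hits += classify_use_trend(u, t) == label
            assert hits >= 20, (label, hits)


def test_low_function_subgroup_filter(small_cohort):
    sub = filter_low_function(small_cohort, threshold=0.5)
    assert all(s.F[0] < 0.5 for s in sub)
    assert len(sub) < len(small_cohort)
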