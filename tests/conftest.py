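import numpy as np
import pytest

from armdyn.models import STEP_MONTHS, SubjectSeries
from armdyn.synth import SynthConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(F, U, subject_id="s0", group="immediate", phase="post_therapy"):
    F = np.asarray(F, dtype=float)
    return SubjectSeries(
        subject_id=subject_id,
        group=group,
        phase=phase,
        times=np.arange(len(F)) * STEP_MONTHS,
        F=F,
        U=np.asarray(U, dtype=float),
    )


@pytest.fixture
def noiseless_cohort():
    """Three subjects generated exactly by the reference model (no noise)."""
    return generate_cohort(SynthConfig(n_subjects=3, seed=77, noise_sd=0.0))


@pytest.fixture
def small_cohort():
    """Twenty noisy immediate-group subjects at the default study conditions."""
    return generate_cohort(SynthConfig(n_subjects=20, seed=31))
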