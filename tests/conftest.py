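import numpy as np
import pytest

from pbmnet import synthetic
from pbmnet.preprocess import OpticalSession
from pbmnet.synthetic import CohortSpec, NoiseSpec


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Small, fast cohort: 4+4 subjects, short sessions."""
    return CohortSpec(
        n_responders=4,
        n_nonresponders=4,
        n_sessions_per_subject=20,
        session_duration=120.0,
        artifact_rate=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return synthetic.generate_cohort(tiny_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture()
def clean_state() -> synthetic.SubjectState:
    nch = 15
    return synthetic.SubjectState(
        subject_id="S00",
        responder=False,
        true_delta_gcs=0.0,
        pair_jitter=np.zeros((nch, nch)),
        decline_per_session=0.0,
    )


def make_session(intensities: np.ndarray, fs: float = 8.138) -> OpticalSession:
    return OpticalSession(intensities=intensities, sampling_rate=fs)


@pytest.fixture()
def quiet_spec() -> CohortSpec:
    """Noise- and artifact-free spec for round-trip checks."""
    return CohortSpec(
        n_responders=1,
        n_nonresponders=1,
        session_duration=120.0,
        noise=NoiseSpec(structured=0.5, cardiac=0.0, respiratory=0.0,
                        mayer=0.0, one_over_f=0.0, battery_noise_sd=0.0),
        artifact_rate=0.0,
        seed=5,
    )
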