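import numpy as np
import pytest

from promai import (
    CohortSpec,
    LesionSpec,
    PhantomSpec,
    PipelineConfig,
    generate_phantom,
)
from promai.pipeline import train_cohort_model


@pytest.fixture(scope="session")
def lesion_spec() -> PhantomSpec:
    """One noiseless phantom with a Gleason-8 lesion."""
    return PhantomSpec(
        seed=7,
        lesions=[LesionSpec((28.0, 22.0, 18.0), (6.0, 6.0, 6.0), 8)],
        noise_sigma_t2w=0.0,
        noise_sigma_dwi=0.0,
        noise_sigma_dce=0.0,
    )


@pytest.fixture(scope="session")
def lesion_phantom(lesion_spec):
    return generate_phantom(lesion_spec, patient_id="fix")


@pytest.fixture(scope="session")
def trained_model():
    """A small seeded reference model trained on a synthetic cohort."""
    return train_cohort_model(PipelineConfig(seed=11))
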