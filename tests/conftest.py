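import numpy as np
import pytest

from bbbmri import preprocessing, synthetic


@pytest.fixture(scope="session")
def default_spec():
    return synthetic.PhantomSpec(seed=1)


@pytest.fixture(scope="session")
def patient_bundle(default_spec):
    """Default lesioned phantom: (study, truth)."""
    return synthetic.generate_patient_study(default_spec)


@pytest.fixture(scope="session")
def control_templates(default_spec, patient_bundle):
    """Healthy-control templates on the phantom grid (21 controls)."""
    study, _ = patient_bundle
    controls = synthetic.generate_control_cohort(default_spec, 21)
    return preprocessing.build_templates(controls, study.voi)


@pytest.fixture(scope="session")
def segmented(patient_bundle, control_templates):
    from bbbmri import segmentation

    study, _ = patient_bundle
    return segmentation.segment_study(study, control_templates)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
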