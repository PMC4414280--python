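import dataclasses

import numpy as np
import pytest

import wingquant as wq
from wingquant.pipeline import extract_features

COHORT_SEED = 1
N_PER_FORM = 10


@pytest.fixture(scope="session")
def library():
    return wq.make_wingform_library()


@pytest.fixture(scope="session")
def forms(library):
    return {f.name: f for f in library}


@pytest.fixture(scope="session")
def cohort(library):
    """Default study cohort: 7 wingforms x 10 specimens, fixed seed."""
    specimens, labels = wq.generate_cohort(library, N_PER_FORM, seed=COHORT_SEED)
    return specimens, labels


@pytest.fixture(scope="session")
def cohort_features(cohort):
    """Full imaging + feature extraction over the default cohort."""
    specimens, _ = cohort
    return extract_features(specimens)


@pytest.fixture(scope="session")
def noiseless_specimen(forms):
    """One victoriaM specimen rendered with zero jitter and zero color noise."""
    spec = dataclasses.replace(forms["victoriaM"], jitter_sd=0.0, color_noise_sd=0.0)
    return wq.render_specimen(spec, length_px=512, seed=7)


@pytest.fixture(scope="session")
def square(forms):
    """A composed 512-px square from one rendered specimen."""
    sp = wq.render_specimen(forms["auroraM"], length_px=512, seed=11)
    return wq.square_compose(
        sp.fore_image,
        wq.segment_wing(sp.fore_image),
        sp.hind_image,
        wq.segment_wing(sp.hind_image),
        specimen_id=sp.specimen_id,
    )


@pytest.fixture(scope="session")
def bank():
    return wq.build_bank()


@pytest.fixture(scope="session")
def outline():
    """A simple valid 14-point outline for collapse-protocol unit tests."""
    t = np.linspace(0, np.pi, 14)
    return np.column_stack((np.linspace(0, 100, 14), 10 * np.sin(t)))
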