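import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petgtv.phantoms import PhantomSpec, make_sphere_phantom, make_tumor_phantom
from petgtv.segmentation import segment_gradient
from petgtv.study import StudyConfig, run_study

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_phantom():
    """One noiseless 60 mm tubular phantom on the default grid."""
    spec = PhantomSpec()
    pet, ct_like, truth = make_tumor_phantom(spec)
    return spec, pet, ct_like, truth


@pytest.fixture(scope="session")
def sphere_case():
    """Blurred-sphere calibration phantom (R = 15 mm, PSF sigma = 4 mm,
    2 mm voxels, 6:1 contrast) with its gradient segmentation."""
    pet, center, truth = make_sphere_phantom()
    gtv = segment_gradient(pet, center)
    return pet, center, truth, gtv


@pytest.fixture(scope="session")
def full_study(tmp_path_factory):
    """The seeded 10-case default study (noiseless, 5 mm wall margin)."""
    out = tmp_path_factory.mktemp("study")
    return run_study(StudyConfig(), out_dir=out)
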