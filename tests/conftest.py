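import numpy as np
import pytest

from choroquant import PhantomSpec, make_cohort
from choroquant.acquisition import BScan, _display_compress
from choroquant.config import AcquisitionParams
from choroquant.phantom import render_radial_section


@pytest.fixture(scope="session")
def small_cohort():
    """Three default-population eyes, shared across tests."""
    return make_cohort(PhantomSpec(seed=101), 3)


@pytest.fixture(scope="session")
def eye(small_cohort):
    return small_cohort[0]


def noise_free_bscan(eye, angle=0, axial_um=12.6, lateral_um=40.0):
    """Display-compressed section with no speckle, read noise or jitter."""
    refl, gt = render_radial_section(eye, angle, axial_um, lateral_um)
    params = AcquisitionParams()
    return BScan(
        pixels=_display_compress(refl**2, params),
        axial_um=axial_um,
        lateral_um=lateral_um,
        angle_deg=angle,
        n_avg=1,
        ground_truth=gt,
    )
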