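import numpy as np
import pytest

from lvatlas import (
    AcquisitionSpec,
    DEFAULT_BASELINE_SHAPE,
    build_template,
    fit_mesh,
    render_volumes,
)

# Reduced acquisition used throughout the tests: same 0.1 mm slice spacing,
# coarser in-plane sampling and a tighter stack, enough to hold the
# default phantom with margin.
SMALL_ACQ = dict(n_slices=60, slice_spacing_mm=0.1, pixel_mm=0.075, image_size_px=64)


@pytest.fixture(scope="session")
def small_acq():
    return AcquisitionSpec(**SMALL_ACQ, speckle_sd=0.08)


@pytest.fixture(scope="session")
def noiseless_acq():
    return AcquisitionSpec(**SMALL_ACQ, speckle_sd=0.0)


@pytest.fixture(scope="session")
def baseline_volumes(noiseless_acq):
    """Noiseless rendering of the default baseline phantom."""
    return render_volumes(DEFAULT_BASELINE_SHAPE, noiseless_acq, rng=0)


@pytest.fixture(scope="session")
def template():
    return build_template()


@pytest.fixture(scope="session")
def baseline_fit(template, baseline_volumes):
    """Template fitted to the noiseless baseline phantom mask."""
    mask, _ = baseline_volumes
    return fit_mesh(template, mask, case_id="baseline")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
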