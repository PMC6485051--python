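import numpy as np
import pytest

from portalqa import (
    ImagingGeometry,
    default_ptw_phantom,
    make_toy_spectrum,
    render_beam_mode,
)


@pytest.fixture(scope="session")
def phantom():
    return default_ptw_phantom()


@pytest.fixture(scope="session")
def geom():
    return ImagingGeometry()


@pytest.fixture(scope="session")
def al_beam():
    return make_toy_spectrum("al_target")


@pytest.fixture(scope="session")
def mv_beam():
    return make_toy_spectrum("6mv")


@pytest.fixture(scope="session")
def clean_al_image(phantom, geom):
    """Noise-free, PSF-free aluminum-target render of the default phantom."""
    return render_beam_mode(phantom, geom, "al_target", seed=11,
                            noise=False, psf_sigma_mm=0.0)
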