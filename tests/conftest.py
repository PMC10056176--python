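import numpy as np
import pytest

from orientfilm import synthgen as sg


@pytest.fixture(scope="session")
def grating_45():
    """Pure 45-degree grating, 256x256, wavelength 16."""
    return sg.gen_oriented_texture((256, 256), 45.0, 1.0, 16.0, seed=11)


@pytest.fixture(scope="session")
def biofilm_065():
    """Default synthetic biofilm at coverage 0.65 plus its ground truth."""
    spec = sg.biofilm_study_spec(60.0, seed=1, image_size=(512, 512),
                                 coverage=0.65)
    return sg.gen_biofilm_image(spec)


def circular_mean_deg(theta_deg):
    """Circular mean of orientation angles (period 180), degrees."""
    t = np.deg2rad(np.asarray(theta_deg, float) * 2.0)
    t = t[~np.isnan(t)]
    return float(np.rad2deg(np.arctan2(np.sin(t).mean(), np.cos(t).mean())) / 2.0) % 180.0


def angdiff(a, b):
    """Smallest absolute difference between orientations (period 180)."""
    return abs((a - b + 90.0) % 180.0 - 90.0)
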