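import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nanodisc_sas import UNMODIFIED_DISC
from nanodisc_sas.contrast import disc_contrasts
from nanodisc_sas.disc_model import derive_geometry, intensity
from nanodisc_sas.sas_io import SASCurve


@pytest.fixture(scope="session")
def unmod_geometry():
    return derive_geometry(UNMODIFIED_DISC)


@pytest.fixture(scope="session")
def xray_contrasts(unmod_geometry):
    return disc_contrasts(probe="xray", d2o_fraction=0.0, belt_volume=unmod_geometry.v_belt)


@pytest.fixture(scope="session")
def neutron_contrasts(unmod_geometry):
    return disc_contrasts(probe="neutron", d2o_fraction=1.0, belt_volume=unmod_geometry.v_belt)


@pytest.fixture(scope="session")
def noise_free_saxs(xray_contrasts):
    """Noise-free unmodified-disc SAXS curve with nominal 1% uncertainties."""
    q = np.logspace(np.log10(0.01), np.log10(0.45), 100)
    model = intensity(q, UNMODIFIED_DISC, xray_contrasts)
    return SASCurve(q, model, 0.01 * np.abs(model) + 1e-9, "xray", 0.0, "noise-free saxs")


@pytest.fixture(scope="session")
def sphere_curve():
    """Noise-free solid-sphere curve (R = 50 Å) with nominal 1% uncertainties."""
    R = 50.0
    q = np.logspace(np.log10(0.005), np.log10(0.35), 120)
    qR = q * R
    I = (3.0 * (np.sin(qR) - qR * np.cos(qR)) / qR**3) ** 2
    return SASCurve(q, I, 0.01 * I + 1e-8, "xray", 0.0, "sphere R50"), R


def make_curve(q, intensity_, sigma=None, probe="xray"):
    sigma = 0.05 * np.abs(intensity_) if sigma is None else sigma
    return SASCurve(np.asarray(q, float), np.asarray(intensity_, float), sigma, probe)
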