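import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from uricolysis import (
    AbsorptionSpectrum,
    AssayConditions,
    EnzymeSpec,
    KineticParameters,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def flat_spectra(eps_urate=12.2, eps_hiu=6.1, eps_ohcu=0.3, eps_allantoin=0.0):
    """Wavelength-flat spectra over [220, 340] nm for arithmetic-level tests."""
    wl = np.array([220.0, 292.0, 340.0])
    return [
        AbsorptionSpectrum("urate", wl, np.full(3, eps_urate)),
        AbsorptionSpectrum("hiu", wl, np.full(3, eps_hiu)),
        AbsorptionSpectrum("ohcu", wl, np.full(3, eps_ohcu)),
        AbsorptionSpectrum("allantoin", wl, np.full(3, eps_allantoin)),
    ]


@pytest.fixture
def wt_params():
    return KineticParameters(K_M=11.0, k_cat=3.95, K_i=4.3)


@pytest.fixture
def assay_with_urah(wt_params):
    return AssayConditions(
        substrate_0=100.0,
        enzymes=(
            EnzymeSpec("Uox", 0.9, parameters=wt_params),
            EnzymeSpec("Urah", 0.9, first_order_efficiency=30.0),
        ),
    )
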