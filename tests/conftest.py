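import numpy as np
import pytest

from helixorder import synthetic as syn
from helixorder.spectra import Spectrum


@pytest.fixture
def lorentzian_spectrum():
    """Isolated unit-area Lorentzian (fwhm 20 cm^-1) on the amide window."""
    from helixorder.deconvolution import BandComponent

    s, truth = syn.gen_spectrum(
        [BandComponent(1680.0, 20.0, 1.0)], grid=(1580.0, 1780.0, 0.25)
    )
    return s, truth


@pytest.fixture
def solution_spectrum():
    """Noiseless five-component solution-phase amide I' spectrum."""
    return syn.gen_spectrum(syn.solution_phase_bands(), grid=(1580.0, 1780.0, 0.5))


@pytest.fixture
def planted_bilayer():
    """Toy bilayer: planted 4 nm leaflet separation, 0.55 nm^2 per lipid."""
    return syn.gen_bilayer(nx=18, ny=18, apl=0.55, leaflet_sep=4.0, seed=11)


def make_spectrum(nu, ab):
    return Spectrum(np.asarray(nu, float), np.asarray(ab, float))
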