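import math

import numpy as np
import pytest

from rodraman.preprocess import RamanSpectrum
from rodraman.synth import SimConfig, study_cohort


def gaussian_trace(axis, center, amplitude, fwhm):
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return amplitude * np.exp(-0.5 * ((axis - center) / sigma) ** 2)


@pytest.fixture
def grid():
    """The default acquisition grid: 377-1717 cm^-1 at 4 cm^-1 (336 points)."""
    return SimConfig().axis


@pytest.fixture
def make_spectrum(grid):
    """Factory for single-Gaussian-band test spectra on the default grid."""

    def _make(center=960.0, amplitude=1.0, fwhm=20.0, slope=0.0, intercept=0.0,
              reference=1.0):
        trace = intercept + slope * grid + gaussian_trace(grid, center,
                                                          amplitude, fwhm)
        return RamanSpectrum(grid, trace, reference)

    return _make


@pytest.fixture
def bone_trace(grid):
    """Noise-free seven-band bone spectrum on the default grid."""
    bands = [(430.0, 0.30, 35.0), (960.0, 1.00, 17.0), (1005.0, 0.10, 12.0),
             (1074.0, 0.30, 26.0), (1275.0, 0.35, 55.0), (1609.0, 0.06, 14.0),
             (1660.0, 0.55, 45.0)]
    trace = np.full(grid.size, 0.1)
    for center, amp, fwhm in bands:
        trace = trace + gaussian_trace(grid, center, amp, fwhm)
    return trace


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled-down default cohort: ~1,000 spectra per class, seed 11."""
    return study_cohort(spectra_per_class=1000, seed=11)
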