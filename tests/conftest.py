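import numpy as np
import pandas as pd
import pytest

from nirquant import SpectraSet, build_design, make_wavenumber_grid, simulate_spectra
from nirquant.simulate import default_endmembers


def make_set(absorbance, wavenumbers=None, fa=None, fb=None):
    """Wrap a plain matrix into a SpectraSet with consistent targets."""
    absorbance = np.atleast_2d(np.asarray(absorbance, float))
    n, p = absorbance.shape
    if wavenumbers is None:
        wavenumbers = np.linspace(10_000, 4_000, p)
    fa = np.zeros(n) if fa is None else np.asarray(fa, float)
    fb = np.zeros(n) if fb is None else np.asarray(fb, float)
    targets = pd.DataFrame({"fA": fa, "fB": fb, "fC": fa + fb})
    return SpectraSet(wavenumbers, absorbance, targets)


@pytest.fixture
def small_noisy_set():
    """A modest simulated study with default artifact levels (fast)."""
    design = build_design(replicates_per_level=4)
    return simulate_spectra(design, default_endmembers(),
                            make_wavenumber_grid(300), seed=7)


@pytest.fixture
def small_clean_set():
    """Same design, all artifact magnitudes zero (pure linear mixtures)."""
    design = build_design(replicates_per_level=4)
    return simulate_spectra(design, default_endmembers().noiseless(),
                            make_wavenumber_grid(300), seed=7)
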