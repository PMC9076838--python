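import numpy as np
import pytest

import flimaggr as fa

# coarse acquisition used throughout the tests: 50 ns window, 0.25 ns channels
REP = 50.0
BIN = 0.25


@pytest.fixture(scope="session")
def delta_irf():
    """Delta IRF at the window origin."""
    return fa.irf_histogram(0.0, 0.0, REP, BIN)


@pytest.fixture(scope="session")
def gaussian_irf():
    """Sampled Gaussian IRF (centre 2 ns, FWHM 0.2 ns), high photon count."""
    return fa.irf_histogram(2.0, 0.2, REP, BIN, n_photons=2_000_000, seed=424242)


@pytest.fixture(scope="session")
def high_snr_scene():
    """3-cell scene with 6 well-separated bright puncta at 6 ns on a 3.3 ns
    background; the regime in which threshold detection must be exact."""
    spec = fa.SceneSpec(
        image_size=(96, 96),
        cells=fa.default_cells((96, 96), 3),
        puncta_per_cell=2,
        puncta_tau_range=(6.0, 6.0),
        puncta_radius_range=(3.0, 5.0),
        photons_per_pixel=500.0,
        seed=11,
    )
    stack, truth = fa.simulate_flim_scene(spec, rep_period=REP, bin_width=BIN)
    return spec, stack, truth
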