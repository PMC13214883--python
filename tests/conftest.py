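import numpy as np
import pytest

import ramancast as rc
from ramancast.io import SpectraSeries, Spectrum


def make_series(times, intensity_fn, axis=None, batch_id="test"):
    """Small handcrafted series: intensity_fn(t, axis) -> vector."""
    if axis is None:
        axis = np.arange(100.0, 131.0)
    spectra = [
        Spectrum(axis, np.asarray(intensity_fn(t, axis), dtype=float), t)
        for t in times
    ]
    return SpectraSeries(batch_id=batch_id, spectra=spectra)


@pytest.fixture(scope="session")
def linear_exact_series():
    """One noiseless batch whose latent dynamics are linear in time."""
    cfg = rc.preset("linear-exact", seed=0, n_batches=1)
    series, truth = rc.simulate_batch(cfg, 0)
    return series, truth


@pytest.fixture(scope="session")
def yeast_series():
    """One realistic-yeast batch (logistic + bell latents, drift, noise)."""
    cfg = rc.preset("realistic-yeast", seed=0, n_batches=1)
    series, truth = rc.simulate_batch(cfg, 0)
    return series, truth
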