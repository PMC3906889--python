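import numpy as np
import pytest

from qhtcp.growth import TimeSeries


def make_logistic_series(
    K=100.0, r=0.4, L=24.0, baseline=0.0, times=None, noise_sd=0.0, seed=0,
    culture_id="culture",
):
    """Render a logistic time series, optionally with seeded Gaussian noise."""
    if times is None:
        times = np.arange(0.0, 49.0, 2.0)
    times = np.asarray(times, dtype=float)
    y = baseline + K / (1.0 + np.exp(-r * (times - L)))
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, times.size)
    return TimeSeries(culture_id, times, y)


@pytest.fixture
def clean_series():
    return make_logistic_series()


@pytest.fixture
def small_screen():
    """Tiny L-level synthetic screen shared across interaction tests."""
    from qhtcp.simulate import ScreenConfig, generate_dose_responses

    cfg = ScreenConfig(n_genes=40, n_reference_replicates=64, n_overlap_pairs=5, seed=3)
    return generate_dose_responses(cfg)
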