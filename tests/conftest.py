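import numpy as np
import pytest

from fcsflim.flim import LifetimeModel, decay_shape
from fcsflim.tcspc import MARKER_LINE, MARKER_PIXEL, DecayHistogram, PhotonStream


@pytest.fixture
def lifetime_model() -> LifetimeModel:
    return LifetimeModel(tau_d=2.4, tau_da=1.0, irf_fwhm=0.3, irf_t0=2.0)


def make_linescan_stream(marker_times, photon_times, clock_hz=2e7, micro=None):
    """Stream with line markers at ``marker_times`` and the given photons."""
    return PhotonStream(
        macro_times=np.asarray(photon_times, dtype=np.int64),
        micro_times=None if micro is None else np.asarray(micro, dtype=np.int32),
        marker_kinds=np.full(len(marker_times), MARKER_LINE, dtype=np.int8),
        marker_times=np.asarray(marker_times, dtype=np.int64),
        clock_hz=clock_hz,
    )


def make_raster_stream(nx, ny, photon_times, micro, pixel_period=100):
    """Single-frame raster: one pixel marker per pixel, row-major."""
    pt = np.arange(nx * ny, dtype=np.int64) * pixel_period
    return PhotonStream(
        macro_times=np.asarray(photon_times, dtype=np.int64),
        micro_times=np.asarray(micro, dtype=np.int32),
        marker_kinds=np.full(pt.size, MARKER_PIXEL, dtype=np.int8),
        marker_times=pt,
    )


def synthetic_decay(f, model: LifetimeModel, n_photons=1e5, n_bins=256,
                    t_range=12.5, bg_fraction=0.01, rng=None):
    """Poisson decay histogram with FRET fraction ``f`` (expected-value
    histogram when ``rng`` is None)."""
    t = (np.arange(n_bins) + 0.5) * (t_range / n_bins)
    s_da = decay_shape(t, model.tau_da, model.irf_sigma, model.irf_t0) if model.tau_da else 0.0
    s_d = decay_shape(t, model.tau_d, model.irf_sigma, model.irf_t0)
    shape = f * s_da + (1.0 - f) * s_d
    shape = shape / shape.sum()
    expected = n_photons * ((1 - bg_fraction) * shape + bg_fraction / n_bins)
    counts = expected if rng is None else rng.poisson(expected)
    return DecayHistogram(counts=counts, bin_width=t_range / n_bins)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
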