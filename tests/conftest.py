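import numpy as np
import pytest

from fibroquant import synthetic as syn


@pytest.fixture
def small_shape():
    return (16, 16, 8)


@pytest.fixture
def segments_m08(small_shape):
    return syn.random_segments(10, small_shape, maturity=0.8, seed=11)


def brute_force_channel_metrics(channel, threshold):
    """Independent triple-loop oracle for per-slice area/density/intensity."""
    ny, nx, nz = channel.shape
    areas, densities, intensities = [], [], []
    for k in range(nz):
        vals = []
        for i in range(ny):
            for j in range(nx):
                v = channel[i, j, k]
                if v > threshold:
                    vals.append(v)
        area = len(vals)
        density = sum(vals) / area if area else float("nan")
        areas.append(area)
        densities.append(density)
        intensities.append(area * density if area else 0.0)
    return areas, densities, intensities


def brute_force_threshold(channel):
    """Histogram-free accumulation oracle for mu, sigma, T."""
    vals = [float(v) for v in np.asarray(channel).ravel()]
    n = len(vals)
    mu = sum(vals) / n
    var = sum((v - mu) ** 2 for v in vals) / n
    return mu, var**0.5, mu + var**0.5
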