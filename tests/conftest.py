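import itertools

import numpy as np
import pytest

from mldcyto import (Centroid, CompositeImage, FrameStack, PipelineConfig,
                     SimConfig)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def id_counter():
    return itertools.count(0)


def make_composite(array):
    array = np.asarray(array, dtype=float)
    return CompositeImage(array, np.zeros_like(array, dtype=int))


def gaussian_spot(shape, cx, cy, amplitude, sigma=2.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))


@pytest.fixture
def small_sim_config():
    """A fast, well-separated two-cell movie configuration."""
    return SimConfig(field_um=(96, 96), pixel_size_um=0.5, n_planes=3,
                     n_frames=10, initial_cells=2, rng_seed=7,
                     min_initial_spacing_um=40, border_margin_um=25,
                     snr=2.5, vesicles_per_cell=(20, 30),
                     initial_age_uniform=False)
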