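import numpy as np
import pytest

from cardioep import syngen


@pytest.fixture(scope="session")
def sham_recording():
    """Noise-free sham-preset recording with its ground truth."""
    params = syngen.EcgSimParams(rr_jitter_frac=0.0, seed=7)
    return syngen.gen_ecg(params), params


@pytest.fixture(scope="session")
def sham_movie():
    """Noise-free sham-preset movie (102/14.6 cm/s) with ground truth."""
    params = syngen.MapSimParams(fiber_angle=30.0, seed=11)
    movie, truth = syngen.gen_map_movie(params)
    return movie, truth, params


@pytest.fixture(scope="session")
def small_movie():
    """20×20 isotropic movie used for brute-force oracle comparisons."""
    params = syngen.MapSimParams(n_rows=20, n_cols=20, pacing_site=(10, 10),
                                 cv_long=50.0, cv_trans=50.0, n_frames=120,
                                 noise_sd=0.0, seed=5)
    movie, truth = syngen.gen_map_movie(params)
    return movie, truth, params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
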