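import numpy as np
import pytest

from tsmdl import model, synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_task():
    """A small separable two-domain task used by several model tests."""
    cfg = synthdata.SynthConfig(
        input_dim=16,
        layer_sizes=(8, 4),
        n_classes=2,
        n_source=60,
        n_target=60,
        class_separation=3.0,
        domain_shift=0.1,
        noise_sd=0.1,
        seed=0,
    )
    return synthdata.generate_transfer_task(cfg)


@pytest.fixture(scope="session")
def fitted_model(small_task):
    cfg = model.TSMDLConfig(n_layers=2, dict_sizes=(8, 4), max_outer_iters=8, seed=0)
    return model.fit(small_task.X_s, small_task.y_s, small_task.X_t, small_task.y_t, cfg)


def random_labels(rng, n, max_classes=4):
    n_classes = int(rng.integers(1, max_classes + 1))
    return [f"c{int(rng.integers(n_classes))}" for _ in range(n)]
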