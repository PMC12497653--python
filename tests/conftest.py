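"""Shared fixtures.

The trained demixing network is expensive to build, so one compact network
is trained once per session and shared by every test that needs demixing.
"""

from __future__ import annotations

import numpy as np
import pytest

from holomap.nwd import NWDConfig, UNet1D, make_training_set, train


@pytest.fixture(scope="session")
def nwd_model():
    """A compact demixing network trained on a reduced synthetic set.

    Problem size (3,500 examples, 14 epochs) is scaled for a CPU test run;
    quality is well past the point where demixing beats the raw traces.
    """
    cfg = NWDConfig(epochs=14, n_train=3500, seed=11)
    rng = np.random.default_rng(cfg.seed)
    ts = make_training_set(cfg, cfg.n_train, rng)
    model = UNet1D(cfg, rng)
    train(model, ts.inputs, ts.targets, cfg, rng)
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
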