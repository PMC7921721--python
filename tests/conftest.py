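"""Shared fixtures: trained networks are expensive, so they are built once
per session and shared by every test that needs them."""

import numpy as np
import pytest

from spikeseq.architecture import build_network
from spikeseq.config import ExperimentConfig
from spikeseq.protocol import train


def _train_rule(rule: str, seed: int = 3):
    cfg = ExperimentConfig()
    rng = np.random.default_rng(seed)
    net = build_network(cfg, rng)
    net, curve = train(net, rule, cfg.training.n_trials, cfg, rng)
    return net, curve, cfg, rng


@pytest.fixture(scope="session")
def trained_repeat():
    return _train_rule("repeat")


@pytest.fixture(scope="session")
def trained_mirror():
    return _train_rule("mirror")
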