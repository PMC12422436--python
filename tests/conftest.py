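"""Shared fixtures: small synthetic datasets and a briefly trained tiny network.

Session scope amortizes the (seconds-scale) training cost across the
tests that need a trained model; determinism of the underlying seeds
makes the fixtures reproducible run to run.
"""

from __future__ import annotations

import numpy as np
import pytest

from spermvision.network import (BackboneConfig, TrainConfig, build_network,
                                 stratified_split, train_two_stage)
from spermvision.preprocess import PreprocessConfig, to_network_input
from spermvision.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def smids_small():
    """30-image, 3-class synthetic set (deterministic, seed 7)."""
    return generate_dataset(SyntheticSpec(scheme="smids3", n_per_class=10,
                                          image_size=96, noise_sd=0.05,
                                          deform_strength=0.8, seed=7))


@pytest.fixture(scope="session")
def hushem_small():
    return generate_dataset(SyntheticSpec(scheme="hushem4", n_per_class=8,
                                          image_size=96, noise_sd=0.05,
                                          deform_strength=0.8, seed=7))


@pytest.fixture(scope="session")
def trained_tiny(smids_small):
    """Tiny network trained for 1+1 epochs on the small set, plus its inputs."""
    data = smids_small
    x = to_network_input(data.images, PreprocessConfig(), 64)
    y = data.labels
    cfg = TrainConfig(stage1_epochs=1, stage2_epochs=1, seed=3)
    tr, val, _ = stratified_split(y, cfg.split, 3)
    net = build_network(BackboneConfig(variant="tiny", input_size=64),
                        n_classes=3, seed=3)
    trained = train_two_stage(net, x[tr], y[tr], data.class_names, cfg,
                              x_val=x[val], y_val=y[val])
    return trained, x, y
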