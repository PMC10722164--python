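"""Shared fixtures: tiny datasets and networks sized for fast unit tests."""

import numpy as np
import pytest

import neuroplast as npl


@pytest.fixture(scope="session")
def tiny_spec():
    """4-class 16x16 stimulus spec used across unit tests."""
    return npl.StimulusSpec(
        n_classes=4, image_size=16, samples_per_class_train=40,
        samples_per_class_test=20, noise_sd=0.05, seed=3,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    return npl.generate_dataset(tiny_spec)


@pytest.fixture(scope="session")
def tiny_net_spec():
    return npl.NetworkSpec(
        blocks=(npl.ConvBlock(8, pool=True), npl.ConvBlock(16, pool=True)),
        hidden=(32,), n_classes=4, input_shape=(3, 16, 16),
    )


@pytest.fixture(scope="session")
def trained_tiny_net(tiny_net_spec, tiny_dataset):
    """A tiny network trained for a handful of epochs (session-shared; copy
    before mutating)."""
    net = npl.build_network(tiny_net_spec, seed=0)
    npl.train(net, tiny_dataset.train, npl.TrainingConfig(epochs=6, seed=0))
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
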