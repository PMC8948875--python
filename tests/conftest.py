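"""Shared fixtures: small synthetic datasets and a once-trained smoke model."""

import dataclasses

import numpy as np
import pytest

import nucstyle as ns
from nucstyle.synthetic import DEFAULT_RECIPES


@pytest.fixture(scope="session")
def two_domain_recipes():
    """Dark fluorescent (0) and light-gray bright-field (1) recipes."""
    return [
        DEFAULT_RECIPES[0],
        dataclasses.replace(DEFAULT_RECIPES[3], domain_id=1),
    ]


@pytest.fixture(scope="session")
def small_dataset(two_domain_recipes):
    """Balanced 2-domain 64x64 set, 10 images per domain."""
    return ns.make_dataset([10, 10], recipes=two_domain_recipes, side=64, seed=7)


@pytest.fixture(scope="session")
def five_domain_dataset():
    """50 images per default domain, for clustering checks."""
    return ns.make_dataset([50] * 5, side=64, seed=11)


@pytest.fixture(scope="session")
def smoke_model(two_domain_recipes):
    """The 2-domain style model smoke-trained for 500 iterations.

    Session-scoped because training takes minutes on one CPU; every test
    that needs a trained model shares this instance (read-only).
    """
    imgs = ns.make_dataset([20, 20], recipes=two_domain_recipes, side=64, seed=42)
    model = ns.StyleModel(ns.StyleConfig.test_profile(n_domains=2, seed=0))
    history = model.train(imgs, iterations=500)
    model._smoke_history = history  # stashed for the training-curve checks
    model._smoke_train_set = imgs
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
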