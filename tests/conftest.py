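"""Shared fixtures: synthetic datasets and one trained reference model.

The ``strong_model`` fixture trains the desk-scale capsule classifier once
per session on strong-signal synthetic data (200 windows per class,
validation on a cross-validation fold, untouched stratified test split)
and is reused by the end-to-end, interpretation and acceptance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pytest

import capm7g as c

STRONG_SEED = 7
STRONG_EPOCHS = 25


@dataclass
class TrainedFixture:
    trained: c.TrainedModel
    split: c.DatasetSplit
    manifest: list
    spec: c.SyntheticSpec
    test_report: c.EvaluationReport


@pytest.fixture(scope="session")
def strong_dataset():
    spec = c.SyntheticSpec(n_per_class=200, seed=STRONG_SEED, signal_strength="strong")
    windows, manifest = c.generate(spec)
    split = c.split_dataset(windows, seed=STRONG_SEED)
    return spec, windows, manifest, split


@pytest.fixture(scope="session")
def strong_model(strong_dataset) -> TrainedFixture:
    spec, windows, manifest, split = strong_dataset
    tr_idx, va_idx = split.folds[0]
    train_w = [split.train[i] for i in tr_idx]
    val_w = [split.train[i] for i in va_idx]
    config = c.CapsuleNetConfig.scaled(seed=STRONG_SEED)
    settings = c.TrainSettings(epochs=STRONG_EPOCHS, seed=STRONG_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # transient undefined-MCC epochs
        result = c.train(train_w, val_w, config, settings)
        report = c.evaluate(c.predict(result.trained, split.test))
    return TrainedFixture(
        trained=result.trained,
        split=split,
        manifest=manifest,
        spec=spec,
        test_report=report,
    )


@pytest.fixture()
def small_windows():
    """60 labeled 101-nt windows for fast plumbing tests."""
    spec = c.SyntheticSpec(
        n_per_class=30, window_length=101, seed=3, signal_strength="strong",
        motif_set=[("GGG", 4, (-40, 40)), ("CU", 2, (-40, 40)), ("UC", 2, (-40, 40))],
    )
    windows, _ = c.generate(spec)
    return windows
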