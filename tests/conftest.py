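"""Shared fixtures: small synthetic datasets and trained models.

Training is the expensive step, so fitted models are session-scoped and
shared; tests must not mutate them.
"""

from __future__ import annotations

import pytest

import cagecollapse as cc
from cagecollapse.train_eval import split_all_vs_all, split_all_vs_one


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small labelled dataset: 6 x 10 cores, all six reactions (360 cages)."""
    records, truth, library = cc.generate_dataset(
        n_tritopic=6, n_ditopic=10, seed=3
    )
    return records, truth, library


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """Quickly trained classifier + its train/test split."""
    records, _, _ = tiny_dataset
    train_recs, test_recs = split_all_vs_all(records, 0.8, seed=1)
    model = cc.train(train_recs, seed=5, n_epochs=15)
    return model, train_recs, test_recs


@pytest.fixture(scope="session")
def biased_head_model(tiny_dataset):
    """Variant with a fully biased MLP head (approximate completeness)."""
    records, _, _ = tiny_dataset
    train_recs, test_recs = split_all_vs_all(records, 0.8, seed=1)
    model = cc.train(
        train_recs, seed=5, n_epochs=15, classifier_hidden_biases=True
    )
    return model, test_recs


@pytest.fixture(scope="session")
def study_scale_model():
    """Study-conditions model: ~2000-cage dataset, All-vs-One protocol.

    Dataset of 12 x 28 cores over six reactions (2016 cages) with the
    default planted rule at seed 7; the aldehyde3amine2 family is held
    out and the default classifier is trained on the rest.
    """
    records, truth, library = cc.generate_dataset(
        n_tritopic=12, n_ditopic=28, seed=7
    )
    train_recs, test_recs = split_all_vs_one(records, "aldehyde3amine2")
    model = cc.train(train_recs, seed=8)
    return model, records, truth, library, train_recs, test_recs
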