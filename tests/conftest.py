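"""Shared fixtures: synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from coo_id.features import extract_features, features_from_recordings
from coo_id.synth import (
    REFERENCE_CALL_COUNTS,
    IndividualProfile,
    make_population,
    iter_population_calls,
    synthesize_call,
)


@pytest.fixture(scope="session")
def flat_call():
    """A noiseless flat-contour call at 300 Hz with known formants."""
    profile = IndividualProfile(
        individual_id="flat300", mean_f0=300.0, f0_within_sd=0.0,
        f0_contour_shape="flat", vocal_tract_length=9.6,
        mean_duration=0.5, duration_within_cv=0.0, noise_gain=0.0,
    )
    return synthesize_call(profile, call_seed=11, rate=44100)


@pytest.fixture(scope="session")
def tiny_features():
    """Feature table of a small well-separated population (3 × 6 calls)."""
    from coo_id.pipeline import make_fixture

    table, excluded = features_from_recordings(
        iter_population_calls(make_fixture("tiny", seed=7)), on_error="exclude"
    )
    assert not excluded
    return table


@pytest.fixture(scope="session")
def paper_like_dataset():
    """The reference-scale dataset: 7 callers, 162 calls, with ground truth.

    Returns (features DataFrame, truth DataFrame) sharing the call_id index.
    """
    pop = make_population(k=7, separation=1.0, within_scale=1.0, seed=1,
                          n_calls=REFERENCE_CALL_COUNTS)
    feat_rows, truth_rows = [], []
    for rec in iter_population_calls(pop):
        feats = extract_features(rec)
        feat_rows.append({"call_id": rec.call_id,
                          "individual_id": rec.individual_id,
                          **feats.as_dict()})
        truth_rows.append({"call_id": rec.call_id, **rec.true_params})
    return pd.DataFrame(feat_rows), pd.DataFrame(truth_rows)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
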