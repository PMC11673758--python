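"""Shared fixtures: small synthetic clip datasets and sampled feature arrays.

The expensive fixtures (rendering + optical-flow sampling) are session-scoped
so the classifier tests and the scaled-down learning check share one dataset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from groomkit.feature_sampling import SamplerParams, sample_clip
from groomkit.synthetic import make_classification_dataset


def sample_records(records, params: SamplerParams):
    samples = [sample_clip(r["seq"], r["clip"], params) for r in records]
    labels = np.array([r["label"] for r in records], dtype=np.int64)
    return samples, labels


def records_manifest(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "clip_id": [r["clip_id"] for r in records],
            "dataset": [r["dataset"] for r in records],
            "label": [r["label"] for r in records],
        }
    )


@pytest.fixture(scope="session")
def small_records():
    """16 balanced grooming/drastic clips across 4 synthetic datasets."""
    return make_classification_dataset(16, seed=11, n_datasets=4)


@pytest.fixture(scope="session")
def small_sampled(small_records):
    """Feature samples for the 16-clip dataset at the 32x32 network size."""
    params = SamplerParams(output_size=(32, 32), seed=11)
    return sample_records(small_records, params)


@pytest.fixture(scope="session")
def learning_dataset():
    """200 separable clips (the scaled-down training condition) plus features."""
    records = make_classification_dataset(200, seed=7)
    params = SamplerParams(output_size=(32, 32), seed=7)
    samples, labels = sample_records(records, params)
    return records, samples, labels


def random_batch(rng, b=2, ns=3, nf=10, h=32, w=32):
    """Random, shape-correct MSRC inputs for pure contract tests."""
    return (
        rng.uniform(0, 1, (b, ns, 3, h, w)),
        rng.uniform(-1, 1, (b, ns, nf, h, w)),
        rng.uniform(-1, 1, (b, ns, nf, h, w)),
    )
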