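"""Shared fixtures: small synthetic datasets, cached per session."""

import numpy as np
import pytest

from cypscreen.curation import curate
from cypscreen.records import CompoundRecord, Label, Source
from cypscreen.synthetic import SyntheticConfig, generate_labeled_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """200 molecules, ~1.2:1 classes, 10% label noise, seed 7."""
    cfg = SyntheticConfig.balanced(200, label_noise=0.1, seed=7)
    records, truth = generate_labeled_dataset(cfg)
    return records, truth


@pytest.fixture(scope="session")
def small_curated(small_dataset):
    records, _ = small_dataset
    kept, report = curate([CompoundRecord(**{
        "compound_id": r.compound_id, "smiles_raw": r.smiles_raw,
        "source": r.source, "activity_value": r.activity_value,
    }) for r in records])
    return kept, report


@pytest.fixture(scope="session")
def clean_dataset():
    """120 molecules, noise-free labels, seed 11 (planted rule == label)."""
    cfg = SyntheticConfig.balanced(120, label_noise=0.0, seed=11)
    return generate_labeled_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.RandomState(1234)


def make_record(cid, smiles, source=Source.POTENCY, value=None, label=Label.UNLABELED, std=None):
    return CompoundRecord(
        compound_id=cid, smiles_raw=smiles, source=source,
        activity_value=value, smiles_std=std, label=label,
    )
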