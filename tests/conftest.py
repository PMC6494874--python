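"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# property tests must behave identically on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ssmeta.dataio import records_to_frame
from ssmeta.effect_sizes import g_for_record
from ssmeta.pipeline import AnalysisConfig, run_all
from ssmeta.synthetic import SimConfig, generate, generate_paperlike

PAPERLIKE_SEED = 2026


@pytest.fixture(scope="session")
def paperlike():
    """The synthesis-shaped synthetic dataset (459 effects, 65 studies)."""
    return generate_paperlike(PAPERLIKE_SEED)


@pytest.fixture(scope="session")
def paperlike_bundle(paperlike):
    """Full pipeline report bundle on the paperlike dataset."""
    return run_all(AnalysisConfig(seed=PAPERLIKE_SEED), paperlike.records)


@pytest.fixture(scope="session")
def small_dataset():
    """A small generic synthetic dataset with g values attached."""
    cfg = SimConfig(n_studies=25, effects_per_study=(2, 5), beta=(0.2,),
                    sigma2_study=0.05, sigma2_trait=0.01, sigma2_taxon=0.01,
                    seed=42)
    ds = generate(cfg)
    frame = records_to_frame(ds.records)
    es = [g_for_record(r) for r in ds.records]
    frame["value"] = [e.value for e in es]
    frame["variance"] = [e.variance for e in es]
    return ds, frame


def attach_g(records) -> pd.DataFrame:
    """Analysis frame with Hedges' g value/variance columns."""
    frame = records_to_frame(records)
    es = [g_for_record(r) for r in records]
    frame["value"] = [e.value for e in es]
    frame["variance"] = [e.variance for e in es]
    return frame
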