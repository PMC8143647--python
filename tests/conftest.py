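"""Shared fixtures: small synthetic inputs and one pre-trained classifier."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import glandscreen as gs

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def strong_spec() -> gs.SimulationSpec:
    """A strongly separable training condition (high charge/amphipathy bias)."""
    return gs.SimulationSpec(
        n_amp=100, n_background=100,
        amp_charge_bias=0.5, amp_hydropathy_bias=0.7,
        seed=11,
    )


@pytest.fixture(scope="session")
def strong_corpus(strong_spec) -> gs.Corpus:
    return gs.curate_corpus(gs.simulate_amp_corpus(strong_spec))


@pytest.fixture(scope="session")
def trained_classifier(strong_corpus) -> gs.TrainedClassifier:
    """One grid-searched SVM shared by the scanning/serialisation tests."""
    return gs.train_classifiers(strong_corpus, seed=11)


@pytest.fixture
def tiny_matrix() -> gs.IntensityMatrix:
    """Hand-built 5-protein intensity matrix covering the filter edge cases.

    Columns: one FG sample, one SF, one serum, two tissues.
    p1: FG + 2 tissues (passes the valid filter)
    p2: FG + 1 tissue (fails: only one other value)
    p3: no FG, 2 tissues + SF (fails: no FG value)
    p4: FG only (unique to FG)
    p5: complete row (passes)
    """
    data = pd.DataFrame(
        {
            "FG": [100.0, 50.0, np.nan, 80.0, 10.0],
            "SF": [np.nan, np.nan, 30.0, np.nan, 20.0],
            "serum": [5.0, np.nan, np.nan, np.nan, 30.0],
            "brain": [200.0, 60.0, 40.0, np.nan, 40.0],
            "heart": [300.0, np.nan, 50.0, np.nan, 50.0],
        },
        index=["p1", "p2", "p3", "p4", "p5"],
    )
    roles = {"FG": "FG", "SF": "SF", "serum": "serum",
             "brain": "tissue", "heart": "tissue"}
    return gs.IntensityMatrix(data=data, roles=roles)


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if (a | b) else 0.0
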