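"""Shared fixtures: synthetic cohorts and small hand-built matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

import nanomir as nm
from nanomir.qc import dual_normalize, lane_lods


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized cohort (6/8/7 lanes, 827 probes) at seed 1."""
    return nm.generate_cohort(nm.SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    lanes, truth = default_cohort
    return nm.cohort_matrix(lanes, truth)


@pytest.fixture(scope="session")
def default_normalized(default_matrix):
    norm, pos, content = dual_normalize(default_matrix)
    lods = lane_lods(default_matrix)
    return norm, pos, content, lods


@pytest.fixture(scope="session")
def zero_noise_cohort():
    return nm.generate_cohort(nm.SyntheticConfig(seed=1, zero_noise=True))


def make_matrix(counts: dict, classes: dict, design: dict) -> nm.CountMatrix:
    """Hand-built CountMatrix: counts maps probe -> per-lane list."""
    lanes = list(design)
    probes = pd.DataFrame(
        {
            "code_class": [classes[p] for p in counts],
            "accession": [f"ACC_{p}" for p in counts],
        },
        index=pd.Index(list(counts), name="name"),
    )
    table = pd.DataFrame(
        {lane: [counts[p][i] for p in counts] for i, lane in enumerate(lanes)},
        index=probes.index,
    )
    return nm.CountMatrix(probes=probes, counts=table, design=dict(design))


@pytest.fixture()
def toy_matrix():
    """Two positive, two negative, five reference and three endogenous probes
    over three identical lanes."""
    counts = {
        "POS_A": [3200, 3200, 3200],
        "POS_E": [125, 125, 125],
        "NEG_A": [10, 10, 10],
        "NEG_B": [14, 14, 14],
        "ACTB": [800, 800, 800],
        "B2M": [1200, 1200, 1200],
        "GAPDH": [1000, 1000, 1000],
        "RPL19": [500, 500, 500],
        "RPLP0": [600, 600, 600],
        "miR-1": [50, 50, 50],
        "miR-2": [200, 200, 200],
        "miR-3": [5, 5, 5],
    }
    classes = {
        "POS_A": "Positive",
        "POS_E": "Positive",
        "NEG_A": "Negative",
        "NEG_B": "Negative",
        "ACTB": "Housekeeping",
        "B2M": "Housekeeping",
        "GAPDH": "Housekeeping",
        "RPL19": "Housekeeping",
        "RPLP0": "Housekeeping",
        "miR-1": "Endogenous",
        "miR-2": "Endogenous",
        "miR-3": "Endogenous",
    }
    design = {"L1": "case", "L2": "case", "L3": "control"}
    return make_matrix(counts, classes, design)
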