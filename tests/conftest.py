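"""Shared fixtures: a small code universe, its ontology, and toy cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import unidiag as u

# codes spread over several chapters, including V/E codes and all leaf levels
FIXTURE_CODES = [
    "001.1",
    "008.45",
    "038.9",
    "038.42",
    "041.04",
    "112.0",
    "250.00",
    "250.13",
    "276.2",
    "276.51",
    "285.9",
    "285.21",
    "311",
    "305.1",
    "331.0",
    "401.9",
    "410.71",
    "427.31",
    "428.0",
    "430",
    "486",
    "491.21",
    "507.0",
    "518.81",
    "530.81",
    "541",
    "550.12",
    "550.13",
    "550.9",
    "571.2",
    "584.9",
    "585.9",
    "599.0",
    "682.6",
    "715.90",
    "780.60",
    "785.52",
    "790.92",
    "995.91",
    "995.92",
    "998.59",
    "V09.0",
    "V45.81",
    "V58.61",
    "E878.8",
    "E950.0",
]

# Table of the printed cluster-2 co-occurrence pattern: code, occurrence
# probability, average order, published re-order rank.
TDCCOP2 = [
    ("518.81", 0.526, 7.665, 3),
    ("38.9", 0.608, 7.545, 2),
    ("785.52", 0.729, 7.813, 8),
    ("584.9", 0.554, 7.377, 1),
    ("427.31", 0.593, 8.038, 11),
    ("995.92", 0.941, 8.031, 10),
    ("428.0", 0.729, 7.703, 5),
    ("486.0", 0.334, 7.805, 6),
    ("599.0", 0.389, 7.701, 4),
    ("401.9", 0.343, 7.807, 7),
    ("276.2", 0.360, 7.875, 9),
    ("250.0", 0.383, 8.062, 12),
]


@pytest.fixture(scope="session")
def tree() -> u.OntologyTree:
    return u.build_ontology(FIXTURE_CODES)


@pytest.fixture(scope="session")
def tdccop2() -> u.TDCCoP:
    return u.TDCCoP.from_summaries(
        codes=[r[0] for r in TDCCOP2],
        average_orders=[r[2] for r in TDCCOP2],
        probabilities=[r[1] for r in TDCCOP2],
        cluster=1,
    )


def make_patients(spec: dict[str, list[tuple[str, int]]]) -> list[u.PatientDiagnosis]:
    return [u.PatientDiagnosis.from_raw(pid, entries) for pid, entries in spec.items()]


@pytest.fixture()
def five_patients(tree) -> list[u.PatientDiagnosis]:
    """Two hernia-like patients, two sepsis-like, one mixed."""
    return make_patients(
        {
            "a": [("550.12", 1), ("550.13", 2)],
            "b": [("550.13", 1), ("541", 2)],
            "c": [("038.9", 1), ("995.92", 2), ("785.52", 3)],
            "d": [("038.9", 1), ("995.91", 2)],
            "e": [("550.12", 1), ("038.9", 2)],
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 60-patient synthetic cohort with its config and true labels."""
    config = u.default_config(n_patients=60, seed=7)
    patients, labels = u.generate_diagnoses(config)
    return config, patients, labels


def block_similarity(sizes: list[int], within: float = 1.0, between: float = 0.0):
    """Block-diagonal similarity matrix over groups of the given sizes."""
    n = sum(sizes)
    values = np.full((n, n), between)
    start = 0
    for size in sizes:
        values[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(values, 1.0)
    ids = [f"p{i}" for i in range(n)]
    return u.SimilarityMatrix(ids=ids, values=values)
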