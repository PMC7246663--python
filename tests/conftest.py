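import random

import networkx as nx
import pytest

from comorbnet import Cohort, PatientRecord


def make_cohort(diagnosis_sets, index_code="C220", ages=None, sexes=None):
    """Build a small cohort from per-patient comorbidity sets; the index
    code is prepended to every patient automatically."""
    n = len(diagnosis_sets)
    ages = ages or [55] * n
    sexes = sexes or ["male"] * n
    records = tuple(
        PatientRecord(
            patient_id=f"p{i}",
            age=ages[i],
            sex=sexes[i],
            diagnoses=(index_code, *diagnosis_sets[i]),
        )
        for i in range(n)
    )
    return Cohort(records, index_codes=frozenset({index_code}))


@pytest.fixture
def two_cliques_bridge():
    """Two unit-weight 3-cliques joined by one bridge edge (m = 7)."""
    g = nx.Graph()
    g.add_edges_from([(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5), (2, 3)])
    return g


@pytest.fixture
def random_cohort():
    """100 patients, 8 diseases, independent random carriage."""
    rng = random.Random(42)
    diseases = [f"D{i:02d}" for i in range(8)]
    sets = []
    for _ in range(100):
        sets.append(tuple(d for d in diseases if rng.random() < 0.3))
    return make_cohort(sets)
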