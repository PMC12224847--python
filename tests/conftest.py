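import numpy as np
import pytest

from cmmnet.cohort import (
    RawMeasurements,
    default_config,
    generate_cohort,
    planted_config,
)
from cmmnet.network import SimilarityGraph


def make_raw(**overrides) -> RawMeasurements:
    """A subject strictly inside every normal range; override to cross cutoffs."""
    base = dict(
        sex="male",
        systolic_bp=118.0,
        diastolic_bp=75.0,
        dx_hypertension=False,
        total_cholesterol=4.5,
        triglycerides=1.1,
        ldl_c=2.5,
        hdl_c=1.4,
        fasting_glucose=5.2,
        ogtt_2h_glucose=6.5,
        dx_diabetes=False,
        acr=8.0,
        egfr=95.0,
        kidney_damage_over_3mo=False,
        serum_uric_acid=300.0,
    )
    base.update(overrides)
    return RawMeasurements(**base)


@pytest.fixture(scope="session")
def bridge_graph() -> SimilarityGraph:
    """Two triangles joined by a single bridge edge (m = 7)."""
    edges = {
        (0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0,
        (3, 4): 1.0, (3, 5): 1.0, (4, 5): 1.0,
        (2, 3): 1.0,
    }
    return SimilarityGraph([f"n{i}" for i in range(6)], edges, threshold=0.0)


@pytest.fixture(scope="session")
def two_cliques() -> SimilarityGraph:
    edges = {}
    for off in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                edges[(off + i, off + j)] = 1.0
    return SimilarityGraph([f"n{i}" for i in range(8)], edges, threshold=0.0)


@pytest.fixture(scope="session")
def small_planted_cohort():
    return generate_cohort(planted_config(200, n_groups=4, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(default_config(n_patients=600, seed=11))


def random_similarity_graph(n: int, p: float, rng: np.random.Generator) -> SimilarityGraph:
    edges = {
        (i, j): 1.0
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    }
    return SimilarityGraph([str(i) for i in range(n)], edges, threshold=0.0)
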