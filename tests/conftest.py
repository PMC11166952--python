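import math

import numpy as np
import pandas as pd
import pytest

import mima
from mima.containers import ExpressionMatrix, MicrobeAbundanceMatrix


def hypergeom_tail_enum(overlap: int, universe: int, size_a: int, size_b: int) -> float:
    """Brute-force hypergeometric upper tail P(X >= overlap) via binomial coefficients."""
    total = math.comb(universe, size_b)
    acc = 0
    for k in range(overlap, min(size_a, size_b) + 1):
        acc += math.comb(size_a, k) * math.comb(universe - size_a, size_b - k)
    return acc / total


@pytest.fixture(scope="session")
def planted_cohort():
    """Small two-cell-type cohort with strong planted effects in CD14 monocytes."""
    cfg = mima.CohortConfig(
        n_crew=4,
        n_genes=20,
        n_planted=6,
        effect_size=1.5,
        noise_sd=0.3,
        cell_types=("CD14_Mono", "NK"),
        planted_cell_type="CD14_Mono",
        n_microbes_per_rank={("bacteria", "genus"): 15, ("virus", "genus"): 8},
        seed=11,
    )
    return cfg, mima.generate_cohort(cfg)


@pytest.fixture()
def tiny_expression():
    data = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4) + 1.0,
        index=["g1", "g2", "g3"],
        columns=["crew1_T1", "crew1_T2", "crew2_T1", "crew2_T2"],
    )
    return ExpressionMatrix(data, cell_type="PBMC")


@pytest.fixture()
def tiny_microbes():
    data = pd.DataFrame(
        [[0.0, 1.0, 2.0, 4.0], [3.0, 0.0, 5.0, 1.0]],
        index=["m1", "m2"],
        columns=["crew1_T1", "crew1_T2", "crew2_T1", "crew2_T2"],
    )
    return MicrobeAbundanceMatrix(data, domain="bacteria", rank="genus")
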