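from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cnotscreen.expression import ExpressionMatrix
from cnotscreen.motifs import default_motifs
from cnotscreen.simulate import SimulationConfig


@pytest.fixture(scope="session")
def motifs():
    return default_motifs()


@pytest.fixture
def small_config():
    return SimulationConfig(
        seed=7, n_genes=300, n_planted_anticorr=30, n_per_group=4,
        utr_length_mean=250.0, utr_length_sd=60.0,
    )


def make_matrix(
    n_genes: int, n_per_group: int, deltas: dict[str, np.ndarray] | None, noise_sd: float,
    seed: int = 0,
) -> ExpressionMatrix:
    """Hand-rolled three-group matrix for unit tests (no planted truth)."""
    rng = np.random.default_rng(seed)
    ids = [f"g{i}" for i in range(n_genes)]
    cols, blocks, group_of = [], [], {}
    for group in ("control", "knockdown", "overexpression"):
        shift = deltas.get(group, np.zeros(n_genes)) if deltas else np.zeros(n_genes)
        block = shift[:, None] + rng.normal(0, noise_sd, (n_genes, n_per_group)) + 8.0
        blocks.append(block)
        for j in range(n_per_group):
            name = f"{group}_{j}"
            cols.append(name)
            group_of[name] = group
    values = pd.DataFrame(np.hstack(blocks), index=ids, columns=cols)
    return ExpressionMatrix(values, pd.Series(group_of))
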