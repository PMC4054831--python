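import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from salivamix import (
    BetaMatrix,
    ReferencePanel,
    TwinDesign,
    simulate_cohort,
    simulate_reference_panel,
)


@pytest.fixture
def tiny_matrix() -> BetaMatrix:
    """5 CpGs × 4 samples with annotation and detection P-values."""
    beta = pd.DataFrame(
        np.array(
            [
                [0.10, 0.20, 0.30, 0.40],
                [0.90, 0.80, 0.70, 0.60],
                [0.50, 0.50, 0.50, 0.50],
                [0.05, 0.95, 0.25, 0.75],
                [0.33, 0.66, 0.11, 0.99],
            ]
        ),
        index=[f"cg{i}" for i in range(1, 6)],
        columns=["s1", "s2", "s3", "s4"],
    )
    detp = pd.DataFrame(1e-5, index=beta.index, columns=beta.columns)
    ann = pd.DataFrame(
        {"chrom": ["1", "2", "Y", "X", "Y"], "pos": [100, 200, 300, 400, 500]},
        index=beta.index,
    )
    return BetaMatrix(beta=beta, detection_p=detp, annotation=ann)


@pytest.fixture
def small_panel():
    """Reference panel with a planted near-binary marker (0.82/0.05)."""
    panel, truth = simulate_reference_panel(
        n_cpgs=200, n_discriminative=20, separation=0.5, seed=11
    )
    return panel, truth


@pytest.fixture
def cohort(small_panel):
    panel, ptruth = small_panel
    matrix, design, truth = simulate_cohort(
        panel, n_pairs=8, noise_sd=0.02, seed=12
    )
    return panel, ptruth, matrix, design, truth


@pytest.fixture
def design4() -> TwinDesign:
    return TwinDesign(
        pd.DataFrame(
            {
                "pair_id": ["p1", "p2", "p3", "p4"],
                "heavy_sample": ["a_H", "b_H", "c_H", "d_H"],
                "light_sample": ["a_L", "b_L", "c_L", "d_L"],
            }
        )
    )


def brute_force_wilcoxon(diffs) -> float:
    """Independent oracle: enumerate all sign assignments explicitly."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [
            ranks[np.array(signs, dtype=bool)].sum()
            for signs in itertools.product([0, 1], repeat=d.size)
        ]
    )
    cdf = np.mean(ws <= w_obs + 1e-9)
    sf = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(cdf, sf))
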