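"""Shared fixtures: synthetic datasets and a null count matrix.

Everything is generated programmatically at test time; session scope keeps
the expensive fixtures to a single build.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cernakit import quantde, syndata
from cernakit.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def ds7():
    """Default-sized synthetic dataset, seed 7 (3 planted triplets)."""
    return syndata.generate_dataset(syndata.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_ds():
    """The small generator configuration used in worked examples."""
    return syndata.generate_dataset(syndata.SyntheticConfig(
        seed=7, n_mrna=50, n_lncrna=20, n_mirna=5, n_triplets=3,
        n_cis_pairs=3, dispersion=0.02))


def make_null_matrix(n_features: int = 2000, mu: float = 100.0,
                     phi: float = 0.1, seed: int = 0) -> ExpressionMatrix:
    """3 vs 3 NB count matrix with no group effect (global null)."""
    rng = np.random.default_rng(seed)
    vals = np.array([syndata.simulate_counts(mu, phi, 6, rng)
                     for _ in range(n_features)])
    meta = pd.DataFrame(
        {"stage": ["A"] * 3 + ["B"] * 3, "replicate": [1, 2, 3, 1, 2, 3]},
        index=pd.Index([f"S{i}" for i in range(6)], name="sample_id"))
    return ExpressionMatrix(
        values=pd.DataFrame(vals, index=[f"f{i}" for i in range(n_features)],
                            columns=meta.index),
        unit="counts", sample_meta=meta)


@pytest.fixture(scope="session")
def null_de():
    """DE results on the 2000-feature global-null matrix (seed 0)."""
    matrix = make_null_matrix()
    table = quantde.de_test(matrix, ["S0", "S1", "S2"], ["S3", "S4", "S5"])
    return matrix, table
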