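"""Shared fixtures: small synthetic maps, references and datasets."""

import numpy as np
import pandas as pd
import pytest

import dmrperm as dp


@pytest.fixture(scope="session")
def small_map():
    return dp.generate_map(2, 30, 300.0, seed=11)


@pytest.fixture(scope="session")
def dense_map():
    """Single chromosome, 12 probes, 100 bp spacing (no gap breaks)."""
    return dp.CpGMap.from_arrays(
        probe_id=[f"p{i:02d}" for i in range(12)],
        chrom=["chr1"] * 12,
        pos=[1000 + 100 * i for i in range(12)],
    )


@pytest.fixture(scope="session")
def reference(small_map):
    return dp.make_cell_reference(small_map, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_assoc(cpg_map, z, delta_beta=None):
    """Association table from explicit z scores (p and direction derived)."""
    from scipy import stats

    z = np.asarray(z, dtype=float)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if delta_beta is None:
        delta_beta = 0.01 * z
    return pd.DataFrame(
        {"effect": 0.1 * z, "delta_beta": delta_beta,
         "z": z, "p": np.clip(p, 1e-300, 1.0),
         "direction": np.where(np.asarray(delta_beta) < 0, "hypo", "hyper")},
        index=pd.Index(cpg_map.probe_ids, name="probe_id"))


@pytest.fixture(scope="session")
def cohort_small(small_map, reference):
    model = dp.CohortModel(cell_reference=reference, n_exposed=10, n_control=14,
                           seed=21)
    return dp.generate_cohort(small_map, model)
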