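"""Shared fixtures: all inputs are generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

import metacomp as mc
from metacomp.containers import LogExpressionMatrix
from metacomp.simulate import prepare_cohorts


@pytest.fixture(scope="session")
def small_truth():
    """A compact planted-program ground truth: 5 identity + 1 activity
    programs of 20 genes in a 300-gene universe."""
    return mc.make_truth(
        n_genes=300, n_identity=5, n_activity=1, genes_per_program=20, seed=0
    )


@pytest.fixture(scope="session")
def small_cohorts(small_truth):
    return mc.simulate_cohorts(
        small_truth, n_datasets=6, cells_per_dataset=150, seed=0
    )


@pytest.fixture(scope="session")
def small_logs(small_cohorts):
    return prepare_cohorts(small_cohorts)


@pytest.fixture(scope="session")
def small_run(small_logs):
    """One end-to-end discovery on the compact fixture."""
    return mc.discover_mecs(small_logs, k=8, seed=0, resolution="auto")


def make_log_matrix(values, dataset_id="toy", gene_ids=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return LogExpressionMatrix(
        values=values,
        cell_ids=cell_ids or [f"c{i}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j}" for j in range(g)],
        dataset_id=dataset_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
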