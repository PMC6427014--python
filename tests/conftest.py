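import dataclasses

import numpy as np
import pandas as pd
import pytest

from bacaba import datasets, synthetic
from bacaba.datatypes import TraitTable


@pytest.fixture(scope="session")
def ref_d2():
    """Published 15-genotype Mahalanobis D² matrix."""
    return datasets.reference_d2()


@pytest.fixture(scope="session")
def ref_params():
    """Published per-trait genetic-parameter table (printed precision)."""
    return datasets.reference_genetic_parameters()


@pytest.fixture(scope="session")
def study_table():
    """One synthetic trial at the study design (15 x 14 x 8, PY derived)."""
    cfg = synthetic.study_design_config(seed=11, derive_py=True)
    table, truth = synthetic.simulate_population(cfg)
    return table, truth, cfg


def make_table(values: dict[str, list[list[float]]]) -> TraitTable:
    """Build a TraitTable from {trait: [[rep values] per genotype]} blocks."""
    traits = list(values)
    n_geno = len(values[traits[0]])
    rows = []
    for i in range(n_geno):
        reps = len(values[traits[0]][i])
        for k in range(reps):
            row = {"genotype": str(i + 1), "replicate": str(k + 1)}
            for t in traits:
                row[t] = values[t][i][k]
            rows.append(row)
    return TraitTable(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clustered_config():
    """Study-design config with three equidistant planted clusters."""
    cfg = synthetic.study_design_config(seed=0)
    return dataclasses.replace(cfg, clusters=synthetic.planted_cluster_shifts(cfg))
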