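import numpy as np
import pandas as pd
import pytest

from faimepath.dep import dep_table
from faimepath.faime import score_matrix
from faimepath.io import CountMatrix
from faimepath.preprocess import preprocess
from faimepath.simulate import SyntheticSpec, generate_cohort, generate_gene_sets


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down cohort: same sample design, smaller gene universe."""
    return SyntheticSpec(
        n_genes=1200,
        n_pathways=60,
        n_affected_pathways=8,
        n_progression_pathways=6,
        pathway_size_range=(8, 20),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    sets = generate_gene_sets(small_spec)
    cm, truth = generate_cohort(small_spec, sets)
    return small_spec, sets, cm, truth


@pytest.fixture(scope="session")
def small_scores(small_cohort):
    _, sets, cm, truth = small_cohort
    expr = preprocess(cm)
    psm = score_matrix(expr, sets)
    baseline = cm.metadata.loc[list(cm.counts.columns)]
    baseline = baseline.index[baseline["timepoint"] == "baseline"]
    return psm, cm, truth, list(baseline)


@pytest.fixture(scope="session")
def small_dep(small_scores):
    psm, cm, truth, baseline = small_scores
    labels = cm.metadata.loc[baseline, "group"]
    return dep_table(psm.scores[baseline], labels), truth


@pytest.fixture()
def toy_counts():
    """A tiny valid count matrix with paired patient samples."""
    counts = pd.DataFrame(
        {
            "HC1": [5, 10, 0, 3],
            "HC2": [6, 9, 1, 2],
            "S1_T0": [7, 11, 0, 4],
            "S1_T1": [8, 12, 2, 3],
        },
        index=["GA", "GB", "GC", "GD"],
    )
    md = pd.DataFrame(
        {
            "sample_id": ["HC1", "HC2", "S1_T0", "S1_T1"],
            "subject_id": ["HC1", "HC2", "S1", "S1"],
            "group": ["HC", "HC", "PreSSc", "PreSSc"],
            "outcome": ["none", "none", "evolving", "evolving"],
            "timepoint": ["baseline", "baseline", "baseline", "followup"],
        }
    ).set_index("sample_id")
    return CountMatrix(counts=counts, metadata=md)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
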