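import numpy as np
import pandas as pd
import pytest

from imply import BulkExperiment, SignatureMatrix, SimulationConfig, simulate


def make_bulk(n_genes=5, subjects=("A", "A", "B", "B"), groups=None, seed=0):
    """Small valid BulkExperiment with one sample per (subject, repeat)."""
    rng = np.random.default_rng(seed)
    samples = []
    counts = {}
    meta = []
    for subj in dict.fromkeys(subjects):
        counts[subj] = 0
    for subj in subjects:
        counts[subj] += 1
        samples.append(f"{subj}{counts[subj]}")
        meta.append((samples[-1], subj, counts[subj]))
    expr = pd.DataFrame(
        rng.uniform(1, 100, size=(n_genes, len(samples))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=samples,
    )
    group_map = groups or {s: 0 for s in dict.fromkeys(subjects)}
    metadata = pd.DataFrame(
        [(s, subj, rep, group_map[subj]) for s, subj, rep in meta],
        columns=["sample_id", "subject_id", "repeat_index", "group"],
    ).set_index("sample_id")
    return BulkExperiment(expr, metadata)


@pytest.fixture
def tiny_bulk():
    return make_bulk()


@pytest.fixture
def random_signature():
    rng = np.random.default_rng(7)
    vals = pd.DataFrame(
        rng.uniform(5, 200, size=(40, 3)),
        index=[f"g{i}" for i in range(40)],
        columns=["T", "B", "NK"],
    )
    return SignatureMatrix(vals)


@pytest.fixture(scope="session")
def small_truth():
    """One small but non-trivial simulated dataset shared across tests."""
    cfg = SimulationConfig(
        n_genes=300,
        n_subjects_per_group=8,
        n_markers=120,
        seed=42,
    )
    return simulate(cfg)
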