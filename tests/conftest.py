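from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from t6sscope.detection import DetectionThresholds
from t6sscope.synthetic_data import SimulationConfig, simulate_replicons


def make_gene_table(replicon_id: str, n_genes: int, t6ss_hits, mge_hits=()):
    """Build an annotation table with T6SS hits at given (ordinal, label)
    positions and optional MGE hits at (ordinal, family)."""
    labels = ["gene"] * n_genes
    categories = ["other"] * n_genes
    for ordinal, label in t6ss_hits:
        labels[ordinal] = label
        categories[ordinal] = "T6SS"
    for ordinal, family in mge_hits:
        labels[ordinal] = family
        categories[ordinal] = "MGE"
    return pd.DataFrame({
        "replicon_id": replicon_id,
        "ordinal": range(n_genes),
        "strand": "+",
        "label": labels,
        "category": categories,
    })


def random_gene_table(rng: np.random.Generator, max_genes: int = 500):
    """Random replicon with 0-14 T6SS hits for oracle-equivalence checks."""
    from t6sscope.vocabulary import CANONICAL_COMPONENTS

    n_genes = int(rng.integers(30, max_genes + 1))
    n_hits = int(rng.integers(0, 15))
    ordinals = sorted(rng.choice(n_genes, size=min(n_hits, n_genes), replace=False))
    hits = [(int(o), str(rng.choice(CANONICAL_COMPONENTS))) for o in ordinals]
    return make_gene_table("R0", n_genes, hits), hits


@pytest.fixture(scope="session")
def thresholds():
    return DetectionThresholds()


@pytest.fixture(scope="session")
def large_cohort():
    """Noise-free 1000-replicon cohort with planted ground truth (shared by
    the recovery and distributional checks)."""
    config = SimulationConfig(n_plasmids=700, n_chromosomes=300, seed=20260923)
    gene_table, metadata, truth = simulate_replicons(config)
    return config, gene_table, metadata, truth
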