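import numpy as np
import pandas as pd
import pytest

import hallnet as hn


def connectome(mat, sid="sub"):
    """Build a SubjectConnectome from any square array-like."""
    return hn.SubjectConnectome(subject_id=sid, weights=np.asarray(mat, float))


def partition_of(assignment):
    return hn.ModularPartition(assignment=np.asarray(assignment, int),
                               gamma=1.0, quality=float("nan"))


@pytest.fixture(scope="session")
def small_cohort():
    """29-subject, 90-node synthetic cohort with a planted severity effect."""
    cfg = hn.SimulationConfig(seed=42)
    return cfg, *hn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no severity-connectivity association (effect_beta=0)."""
    cfg = hn.SimulationConfig(n_subjects=20, n_nodes=30, n_modules=3,
                              effect_beta=0.0, seed=7)
    return cfg, *hn.generate_cohort(cfg)


@pytest.fixture()
def two_cliques():
    """Two disconnected 4-cliques: an unambiguous 2-module graph."""
    w = np.zeros((8, 8))
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                w[base + i, base + j] = w[base + j, base + i] = 1.0
    return w


@pytest.fixture()
def clique_ring():
    """Ring of four 5-cliques joined by weak bridges."""
    k, m = 5, 4
    n = k * m
    w = np.zeros((n, n))
    for b in range(m):
        idx = range(b * k, (b + 1) * k)
        for i in idx:
            for j in idx:
                if i < j:
                    w[i, j] = w[j, i] = 1.0
    for b in range(m):
        i = b * k          # one weak bridge between consecutive cliques
        j = ((b + 1) % m) * k
        w[i, j] = w[j, i] = 0.05
    return w
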