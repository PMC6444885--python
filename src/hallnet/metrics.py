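"""Node-level topology metrics on a partitioned weighted network.

Module degree z-score W_i standardizes a node's within-module strength
against its own module's distribution; the participation coefficient
B_i = 1 - sum_s (kappa_is / kappa_i)^2 measures how uniformly a node's
strength is spread across modules (0 = fully within-module). The diverse
club is the set of highest-participation nodes filtered against a
permutation null of the participation vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import ModularPartition
from .severity import DegenerateInputError


def module_strengths(weights: np.ndarray, partition: ModularPartition) -> np.ndarray:
    """kappa_is: strength of node i to each module s (n_nodes x n_modules)."""
    a = partition.assignment
    n_mod = partition.n_modules
    onehot = np.equal.outer(a, np.arange(n_mod)).astype(float)
    return np.asarray(weights, dtype=float) @ onehot


def module_degree_zscore(weights: np.ndarray, partition: ModularPartition) -> np.ndarray:
    """W_i = (kappa_i - mean_module) / sd_module, population (n) SD.

    kappa_i here is the node's strength to other nodes of its own module.
    Singleton modules and zero-variance modules give W_i = 0.
    """
    a = partition.assignment
    kis = module_strengths(weights, partition)
    own = kis[np.arange(a.size), a]
    w = np.zeros(a.size)
    for m in range(partition.n_modules):
        members = a == m
        vals = own[members]
        sd = vals.std(ddof=0)
        if members.sum() > 1 and sd > 0:
            w[members] = (vals - vals.mean()) / sd
    return w


def participation_coefficient(weights: np.ndarray, partition: ModularPartition) -> np.ndarray:
    """B_i = 1 - sum_s (kappa_is / kappa_i)^2; isolated nodes get B_i = 0."""
    kis = module_strengths(weights, partition)
    ki = kis.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(ki[:, None] > 0, kis / np.maximum(ki, 1e-300)[:, None], 0.0)
    b = 1.0 - (frac**2).sum(axis=1)
    b[ki == 0] = 0.0
    return b


def node_metrics_table(weights: np.ndarray, partition: ModularPartition) -> pd.DataFrame:
    """Per-node strength, within-module strength, W_i and B_i."""
    a = partition.assignment
    kis = module_strengths(weights, partition)
    df = pd.DataFrame({
        "node_id": np.arange(a.size),
        "module": a,
        "strength": np.asarray(weights, float).sum(axis=1),
        "within_module_strength": kis[np.arange(a.size), a],
        "W": module_degree_zscore(weights, partition),
        "B": participation_coefficient(weights, partition),
    })
    return df


@dataclass(frozen=True)
class DiverseClubResult:
    """Diverse-club membership with the null cutoff that defined it."""

    club_node_ids: np.ndarray
    candidate_node_ids: np.ndarray    # top 20% of B_i
    top_fraction: float
    bi_threshold_percentile: float
    null_cutoff: float
    n_iterations: int


def diverse_club(b: np.ndarray, top_fraction: float = 0.20,
                 percentile: float = 95.0, n_iterations: int = 5000,
                 seed: int = 0) -> DiverseClubResult:
    """Highest-participation nodes filtered against a shuffled-B null.

    The candidate set is the top ``top_fraction`` of nodes by B_i. Each
    iteration shuffles the B vector across nodes and records the
    candidate-selection cutoff of the shuffled vector (its ``n_cand``-th
    largest value); the club is every candidate whose B_i strictly exceeds
    the ``percentile`` percentile of those pooled cutoffs. With
    exchangeable (e.g., all-equal) B values the club is empty.
    """
    b = np.asarray(b, dtype=float)
    n = b.size
    if n < 10:
        raise DegenerateInputError("diverse club needs >= 10 nodes")
    n_cand = math.ceil(top_fraction * n)
    order = np.argsort(-b, kind="stable")
    candidates = np.sort(order[:n_cand])
    rng = np.random.default_rng(seed)
    null = np.empty(n_iterations)
    for it in range(n_iterations):
        shuffled = rng.permutation(b)
        null[it] = np.partition(shuffled, n - n_cand)[n - n_cand]
    cutoff = float(np.percentile(null, percentile))
    club = candidates[b[candidates] > cutoff]
    return DiverseClubResult(club_node_ids=club, candidate_node_ids=candidates,
                             top_fraction=top_fraction,
                             bi_threshold_percentile=percentile,
                             null_cutoff=cutoff, n_iterations=n_iterations)
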