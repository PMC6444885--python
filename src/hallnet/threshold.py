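"""Group edge masks: consistency thresholding, plain and distance-binned.

Consistency thresholding keeps an edge if it carries a positive weight in
at least a given fraction of subjects. The distance-binned variant ranks
edges by consistency within equal-count bins of inter-node Euclidean
distance, avoiding preferential retention of short connections, and fills
each bin's quota to hit a target overall density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import DimensionError, NodeTable, SubjectConnectome


class ParameterError(ValueError):
    """Out-of-range thresholding parameter."""


@dataclass(frozen=True)
class GroupMask:
    """Boolean symmetric matrix of retained edges plus provenance."""

    matrix: np.ndarray
    method: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool).copy()
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DimensionError(f"mask must be square, got {m.shape}")
        if not np.array_equal(m, m.T):
            raise ValueError("mask must be symmetric")
        np.fill_diagonal(m, False)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def density(self) -> float:
        n = self.n_nodes
        possible = n * (n - 1) / 2
        return float(np.triu(self.matrix, k=1).sum() / possible) if possible else 0.0


def _presence_counts(cohort: list[SubjectConnectome]) -> np.ndarray:
    ns = {c.n_nodes for c in cohort}
    if len(ns) != 1:
        raise DimensionError(f"cohort matrices differ in size: {sorted(ns)}")
    stack = np.stack([c.weights > 0 for c in cohort])
    return stack.sum(axis=0)


def consistency_mask(cohort: list[SubjectConnectome], fraction: float = 0.5) -> GroupMask:
    """Retain edges present (weight > 0) in >= ceil(fraction * n_subjects) subjects."""
    if len(cohort) < 2:
        raise ParameterError("need >= 2 subjects for consistency thresholding")
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    counts = _presence_counts(cohort)
    need = math.ceil(fraction * len(cohort))
    return GroupMask(matrix=counts >= max(need, 1), method="consistency")


def distance_binned_mask(cohort: list[SubjectConnectome], node_table: NodeTable,
                         target_density: float, n_bins: int = 10) -> GroupMask:
    """Consistency ranking within equal-count Euclidean-distance bins.

    Each bin contributes a proportional quota of its most consistent edges
    so that the overall mask density reaches ``target_density``; candidate
    edges are those present in at least one subject.
    """
    if not 0 < target_density <= 1:
        raise ParameterError(f"target_density must be in (0, 1], got {target_density}")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    counts = _presence_counts(cohort)
    n = counts.shape[0]
    if node_table.n_nodes != n:
        raise DimensionError("node table size does not match cohort matrices")
    cent = node_table.centroids
    iu, ju = np.triu_indices(n, k=1)
    candidate = counts[iu, ju] > 0
    n_possible = iu.size
    n_target = int(round(target_density * n_possible))
    if n_target > candidate.sum():
        raise ParameterError(
            f"target_density {target_density} exceeds available nonzero-edge density "
            f"{candidate.sum() / n_possible:.4f}")
    dist = np.linalg.norm(cent[iu] - cent[ju], axis=1)
    cand_idx = np.flatnonzero(candidate)
    order = cand_idx[np.argsort(dist[cand_idx], kind="stable")]
    bins = np.array_split(order, n_bins)  # equal-count distance bins
    kept = np.zeros(n_possible, dtype=bool)
    remaining = n_target
    for b, members in enumerate(bins):
        # proportional quota; last bins absorb rounding so the total is exact
        bins_left = len(bins) - b
        quota = min(len(members), int(round(remaining / bins_left)))
        if quota <= 0:
            continue
        # most consistent first; ties broken by stable order (shorter first)
        rank = np.argsort(-counts[iu[members], ju[members]], kind="stable")
        kept[members[rank[:quota]]] = True
        remaining -= quota
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[kept], ju[kept]] = True
    mask |= mask.T
    return GroupMask(matrix=mask, method="distance_binned")


def apply_mask(subject: SubjectConnectome, mask: GroupMask) -> SubjectConnectome:
    """Zero out every weight the group mask does not retain."""
    if subject.n_nodes != mask.n_nodes:
        raise DimensionError(
            f"subject n={subject.n_nodes} vs mask n={mask.n_nodes}")
    return SubjectConnectome(subject_id=subject.subject_id,
                             weights=subject.weights * mask.matrix)


def density(mask: GroupMask) -> float:
    return mask.density


def group_mean_matrix(cohort: list[SubjectConnectome], mask: GroupMask,
                      nonzero_only: bool = False) -> np.ndarray:
    """Mean weight over subjects on retained edges.

    By default averages over all subjects (zeros included), penalizing
    inconsistent edges; ``nonzero_only`` averages over edge-possessing
    subjects instead.
    """
    stack = np.stack([apply_mask(c, mask).weights for c in cohort])
    if nonzero_only:
        npos = (stack > 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(npos > 0, stack.sum(axis=0) / np.maximum(npos, 1), 0.0)
    else:
        mean = stack.mean(axis=0)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 0.0)
    return mean
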