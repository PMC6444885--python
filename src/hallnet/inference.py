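"""Permutation inference on the identified subnetwork and node metrics.

Covers: resting-state-network overlap of the subnetwork against a
label-permutation null, subnetwork-vs-rest contrasts of mean node metrics,
diverse-club enrichment inside the subnetwork, and the whole-connectome
nodewise Spearman screen with max-statistic familywise-error correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .severity import DegenerateInputError


def rsn_overlap_test(subnetwork_nodes: np.ndarray, rsn_labels: np.ndarray,
                     n_iterations: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Per-network percentage of nodes inside the subnetwork vs permuted labels.

    Each iteration permutes the network-identity vector across nodes and
    recomputes the per-label overlap, populating a null distribution. A
    label is 'targeted' if its observed overlap exceeds the null's 97.5th
    percentile and 'spared' if it falls below the 2.5th.
    """
    labels = np.asarray(rsn_labels)
    n = labels.size
    in_sub = np.zeros(n, dtype=bool)
    sub = np.asarray(subnetwork_nodes, dtype=int)
    if sub.size and (sub.min() < 0 or sub.max() >= n):
        raise ValueError("subnetwork node ids outside the node table")
    in_sub[sub] = True
    uniq = sorted(set(labels.tolist()))
    onehot = np.stack([(labels == u).astype(float) for u in uniq], axis=1)
    sizes = onehot.sum(axis=0)
    observed = 100.0 * (in_sub @ onehot) / sizes
    rng = np.random.default_rng(seed)
    null = np.empty((n_iterations, len(uniq)))
    for it in range(n_iterations):
        null[it] = 100.0 * (in_sub[rng.permutation(n)] @ onehot) / sizes
    lo = np.percentile(null, 2.5, axis=0)
    hi = np.percentile(null, 97.5, axis=0)
    verdict = np.where(observed > hi, "targeted",
                       np.where(observed < lo, "spared", "neither"))
    return pd.DataFrame({"rsn_label": uniq, "n_nodes": sizes.astype(int),
                         "percent_in_subnetwork": observed,
                         "null_p2_5": lo, "null_p97_5": hi, "verdict": verdict})


def group_metric_contrast(values: np.ndarray, in_subnetwork: np.ndarray,
                          n_iterations: int = 5000, seed: int = 0) -> dict:
    """Mean metric inside vs outside the subnetwork; label-shuffle permutation p.

    Statistic = difference of group means; two-sided p with the +1
    correction.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(in_subnetwork, dtype=bool)
    if lab.all() or not lab.any():
        raise DegenerateInputError("both groups must be nonempty")
    obs_in, obs_out = v[lab].mean(), v[~lab].mean()
    obs = obs_in - obs_out
    rng = np.random.default_rng(seed)
    null = np.empty(n_iterations)
    for it in range(n_iterations):
        p = lab[rng.permutation(lab.size)]
        null[it] = v[p].mean() - v[~p].mean()
    pval = (1 + int(np.sum(np.abs(null) >= abs(obs)))) / (n_iterations + 1)
    return {"mean_in": float(obs_in), "mean_out": float(obs_out),
            "difference": float(obs), "p": float(pval)}


def club_enrichment_test(club_node_ids: np.ndarray, subnetwork_nodes: np.ndarray,
                         n_nodes: int, n_iterations: int = 5000,
                         seed: int = 0) -> tuple[int, float]:
    """Is the diverse club over-represented inside the subnetwork?

    Observed = |club ∩ subnetwork|; the null re-draws the subnetwork's
    membership uniformly over nodes (one-sided, +1 correction). Converges
    to the hypergeometric upper tail.
    """
    club = np.asarray(club_node_ids, dtype=int)
    sub = np.asarray(subnetwork_nodes, dtype=int)
    if club.size == 0:
        raise DegenerateInputError("club is empty")
    in_sub = np.zeros(n_nodes, dtype=bool)
    in_sub[sub] = True
    observed = int(in_sub[club].sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_iterations, dtype=int)
    for it in range(n_iterations):
        null[it] = int(in_sub[rng.permutation(n_nodes)][club].sum())
    p = (1 + int(np.sum(null >= observed))) / (n_iterations + 1)
    return observed, float(p)


@dataclass(frozen=True)
class NodewiseScreenResult:
    """Observed nodewise Spearman rho with max-statistic corrected flags."""

    rho: np.ndarray
    flagged: np.ndarray
    critical_rho: float
    alpha: float
    n_iterations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": np.arange(self.rho.size),
                             "rho": self.rho, "flagged": self.flagged})


def _residualize_cols(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def nodewise_screen(metric_stack: np.ndarray, severity: np.ndarray,
                    covariate: Optional[np.ndarray] = None,
                    n_iterations: int = 5000, alpha: float = 0.05,
                    seed: int = 0) -> NodewiseScreenResult:
    """Spearman rho of each node's metric vs severity, FWE-corrected.

    ``metric_stack`` is subjects x nodes. Each permutation shuffles the
    severity ranks across subjects and records the maximum |rho| over
    nodes; a node is flagged iff its observed |rho| exceeds the (1-alpha)
    quantile of that maximum-statistic null (weak familywise control). The
    partial variant rank-transforms all three variables and residualizes
    metric and severity ranks on the covariate ranks first.
    """
    M = np.asarray(metric_stack, dtype=float)
    n_subj, n_nodes = M.shape
    if n_subj < 5:
        raise ValueError("need >= 5 subjects")
    R = rankdata(M, axis=0).astype(float)
    g = rankdata(np.asarray(severity, dtype=float)).astype(float)
    if covariate is not None:
        c = rankdata(np.asarray(covariate, dtype=float)).astype(float)
        R = _residualize_cols(R, c)
        g = _residualize_cols(g[:, None], c)[:, 0]
    R = R - R.mean(axis=0)
    g = g - g.mean()
    Rn = np.linalg.norm(R, axis=0)
    gn = np.linalg.norm(g)
    ok = (Rn > 0) & (gn > 0)

    def _rho(gv: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(ok, (gv @ R) / np.maximum(gn * Rn, 1e-300), 0.0)
        return np.clip(r, -1.0, 1.0)

    rho = _rho(g)
    rng = np.random.default_rng(seed)
    max_null = np.empty(n_iterations)
    for it in range(n_iterations):
        max_null[it] = np.abs(_rho(g[rng.permutation(n_subj)])).max()
    crit = float(np.quantile(max_null, 1.0 - alpha))
    flagged = np.abs(rho) > crit
    return NodewiseScreenResult(rho=rho, flagged=flagged, critical_rho=crit,
                                alpha=alpha, n_iterations=n_iterations)
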