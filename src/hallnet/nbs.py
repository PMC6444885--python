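"""Network-based statistic (NBS) for severity-connectivity association.

Each retained edge's weight across subjects is correlated with the severity
regressor (optionally as a partial correlation controlling a nuisance
covariate); the correlation is converted to a t statistic, edges above a
t threshold are kept, and inference is on the size (edge count) of the
connected components they form. Familywise error is controlled by
permuting the regressor and recording the maximal component size, giving a
component-level FWE p-value.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .io import EdgeList, SubjectConnectome
from .threshold import GroupMask

logger = logging.getLogger(__name__)

T_CAP = 1e6  # guard for |r| -> 1 degenerate edges


@dataclass(frozen=True)
class NBSConfig:
    """NBS parameters; defaults follow the severity-connectome design."""

    t_threshold: float = 1.7
    n_permutations: int = 5000
    direction: str = "negative"      # direction of association tested
    covariate_name: Optional[str] = None
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_threshold <= 0:
            raise ValueError("t_threshold must be > 0")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.direction not in ("negative", "positive"):
            raise ValueError("direction must be 'negative' or 'positive'")


@dataclass
class NBSComponent:
    """One suprathreshold connected subnetwork."""

    edges: EdgeList
    nodes: np.ndarray
    p_fwe: float = math.nan

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class NBSResult:
    edge_t: np.ndarray                 # symmetric signed-t matrix
    components: list[NBSComponent]
    max_component_size_null: np.ndarray
    significant_nodes: np.ndarray
    significant_edges: EdgeList
    config: NBSConfig
    exact: bool = False


def _residualize(y: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residuals of y (columns) on [1, covariate] by least squares."""
    X = np.column_stack([np.ones_like(covariate), covariate])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _corr_t(g: np.ndarray, E: np.ndarray, df: int, direction: str) -> np.ndarray:
    """Signed t per edge column of E vs regressor g (both zero-mean)."""
    gn = np.linalg.norm(g)
    en = np.linalg.norm(E, axis=0)
    ok = (gn > 0) & (en > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(ok, (g @ E) / np.maximum(gn * en, 1e-300), 0.0)
    r = np.clip(r, -1.0, 1.0)
    denom = np.maximum(1.0 - r**2, 1e-300)
    t = np.clip(r * np.sqrt(df / denom), -T_CAP, T_CAP)
    return -t if direction == "negative" else t


def _prepare(cohort: list[SubjectConnectome], mask: GroupMask,
             regressor: np.ndarray, covariate: Optional[np.ndarray]):
    n = mask.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    keep = mask.matrix[iu, ju]
    iu, ju = iu[keep], ju[keep]
    E = np.stack([c.weights[iu, ju] for c in cohort])     # subjects x edges
    g = np.asarray(regressor, dtype=float)
    if g.std() == 0:
        raise ValueError("regressor has zero variance")
    if covariate is not None:
        c = np.asarray(covariate, dtype=float)
        if c.std() == 0:
            raise ValueError("covariate is constant")
        E = _residualize(E, c)
        g = _residualize(g[:, None], c)[:, 0]
        df = len(cohort) - 3
    else:
        E = E - E.mean(axis=0)
        g = g - g.mean()
        df = len(cohort) - 2
    n_const = int(np.sum(np.linalg.norm(E, axis=0) == 0))
    if n_const:
        logger.info("%d constant edges across subjects; t set to 0", n_const)
    return iu, ju, E, g, df


def edge_statistics(cohort: list[SubjectConnectome], mask: GroupMask,
                    regressor: np.ndarray,
                    covariate: Optional[np.ndarray] = None,
                    direction: str = "negative") -> np.ndarray:
    """Symmetric matrix of signed per-edge t statistics on retained edges.

    Without a covariate: Pearson r across subjects, t = r sqrt((n-2)/(1-r^2)).
    With one: partial correlation after residualizing both edge weights and
    regressor on the covariate, df = n-3. Positive t means association in
    the requested direction.
    """
    if len(cohort) < 5:
        raise ValueError("need >= 5 subjects")
    iu, ju, E, g, df = _prepare(cohort, mask, regressor, covariate)
    t = _corr_t(g, E, df, direction)
    n = mask.n_nodes
    mat = np.zeros((n, n))
    mat[iu, ju] = t
    mat += mat.T
    return mat


def _component_sizes(iu: np.ndarray, ju: np.ndarray, above: np.ndarray,
                     n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Component label per suprathreshold edge and edge count per component."""
    si, sj = iu[above], ju[above]
    if si.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    adj = coo_matrix((np.ones(si.size), (si, sj)), shape=(n_nodes, n_nodes))
    _, labels = _cc(adj, directed=False)
    edge_labels = labels[si]
    counts = np.bincount(edge_labels)
    return edge_labels, counts


def _max_component(iu, ju, above, n_nodes) -> int:
    _, counts = _component_sizes(iu, ju, above, n_nodes)
    return int(counts.max()) if counts.size else 0


def suprathreshold_components(edge_t: np.ndarray, t_threshold: float,
                              ) -> list[NBSComponent]:
    """Connected components of edges with t > threshold, largest first."""
    n = edge_t.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    above = edge_t[iu, ju] > t_threshold
    edge_labels, counts = _component_sizes(iu, ju, above, n)
    comps: list[NBSComponent] = []
    if counts.size:
        si, sj, st = iu[above], ju[above], edge_t[iu, ju][above]
        for lab in np.argsort(-counts, kind="stable"):
            if counts[lab] == 0:
                continue
            sel = edge_labels == lab
            edges = EdgeList(pd.DataFrame({
                "node_i": si[sel], "node_j": sj[sel], "statistic": st[sel]}))
            nodes = np.unique(np.concatenate([si[sel], sj[sel]]))
            comps.append(NBSComponent(edges=edges, nodes=nodes))
    return comps


def nbs_test(cohort: list[SubjectConnectome], mask: GroupMask,
             regressor: np.ndarray, covariate: Optional[np.ndarray] = None,
             config: NBSConfig = NBSConfig()) -> NBSResult:
    """Full NBS: edge statistics, components, maximal-size permutation FWE.

    The regressor (its covariate-residualized form when a covariate is
    present, a Freedman-Lane-style residual permutation) is permuted across
    subjects; each permutation's maximal suprathreshold component size
    forms the null. When the sample is small enough that all orderings fit
    in the permutation budget, the null is enumerated exactly.
    """
    if len(cohort) < 5:
        raise ValueError("need >= 5 subjects")
    iu, ju, E, g, df = _prepare(cohort, mask, regressor, covariate)
    n = mask.n_nodes
    thr = config.t_threshold

    t_obs = _corr_t(g, E, df, config.direction)
    mat = np.zeros((n, n))
    mat[iu, ju] = t_obs
    mat += mat.T
    comps = suprathreshold_components(mat, thr)

    n_subj = len(cohort)
    exact = math.factorial(n_subj) <= config.n_permutations
    if exact:
        logger.info("n=%d: exact enumeration over %d orderings", n_subj,
                    math.factorial(n_subj))
        perms = np.array(list(itertools.permutations(range(n_subj))))
    else:
        rng = np.random.default_rng(config.seed)
        perms = np.stack([rng.permutation(n_subj)
                          for _ in range(config.n_permutations)])
    null = np.empty(len(perms), dtype=int)
    for k, p in enumerate(perms):
        t_p = _corr_t(g[p], E, df, config.direction)
        null[k] = _max_component(iu, ju, t_p > thr, n)

    for comp in comps:
        ge = int(np.sum(null >= comp.n_edges))
        comp.p_fwe = ge / len(perms) if exact else (1 + ge) / (len(perms) + 1)

    sig = [c for c in comps if c.p_fwe < config.alpha]
    if sig:
        sig_edges = EdgeList(pd.concat([c.edges.frame for c in sig],
                                       ignore_index=True))
        sig_nodes = np.unique(np.concatenate([c.nodes for c in sig]))
    else:
        sig_edges = EdgeList(pd.DataFrame({"node_i": [], "node_j": [],
                                           "statistic": []}))
        sig_nodes = np.empty(0, dtype=int)
    return NBSResult(edge_t=mat, components=comps,
                     max_component_size_null=null,
                     significant_nodes=sig_nodes, significant_edges=sig_edges,
                     config=config, exact=exact)
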