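"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a small clinical diffusion-imaging cohort: each
subject carries a weighted structural connectome whose group backbone is a
stochastic block model (modular, FA-like bounded weights), two positively
correlated hallucination-severity components (a misperception percentage on
a bistable-percept task and a questionnaire total), a disease-severity
nuisance covariate, and a planted subnetwork whose edge weights decrease
linearly with the standardized composite severity score.

All randomness flows from a single seed; identical config + seed yields a
byte-identical cohort.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import (
    RSN_LABELS,
    SUBCORTICAL_LABEL,
    CohortManifest,
    EdgeList,
    NodeTable,
    SubjectConnectome,
    write_manifest,
    write_node_table,
    write_subject_matrix,
)

WEIGHT_CLIP = (0.05, 0.95)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed derived by hashing the stage name with the master seed.

    Keeps stages statistically independent while fully reproducible; the
    result stays below 2**31 so downstream RNGs accept it.
    """
    h = hashlib.sha256(f"{stage}:{int(master_seed)}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class SimulationConfig:
    """Cohort-generation parameters; defaults are the study-like conditions."""

    n_subjects: int = 29
    n_nodes: int = 90          # 233 for full-scale runs
    n_modules: int = 6
    p_in: float = 0.8          # within-module edge probability
    p_out: float = 0.1         # between-module edge probability
    weight_mean_in: float = 0.55
    weight_mean_out: float = 0.35
    weight_concentration: float = 20.0   # Beta concentration (alpha+beta)
    subject_noise_sd: float = 0.03
    presence_jitter: float = 0.10        # P(group edge absent in a subject)
    severity_component_corr: float = 0.5
    covariate_corr: float = 0.3
    effect_beta: float = 0.08  # weight decrement per SD of severity on planted edges
    planted_edges: int = 20
    planted_within_rsn: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_in", "p_out", "presence_jitter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(self.severity_component_corr) > 1 or abs(self.covariate_corr) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.n_modules < 1 or self.n_nodes < self.n_modules:
            raise ValueError("need n_nodes >= n_modules >= 1")


@dataclass
class GroundTruth:
    """What the generator planted: partition, affected edges, true severity."""

    true_partition: np.ndarray
    planted_edge_set: EdgeList
    true_hss: np.ndarray


def _beta_weights(rng: np.random.Generator, mean: float, concentration: float,
                  size: int) -> np.ndarray:
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return np.clip(rng.beta(a, b, size=size), *WEIGHT_CLIP)


def _module_assignment(n_nodes: int, n_modules: int) -> np.ndarray:
    """Near-equal contiguous blocks, module ids 0..n_modules-1."""
    return np.sort(np.arange(n_nodes) % n_modules)


def generate_group_backbone(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Stochastic-block-model group matrix and its planted partition.

    Within-module edges appear with probability ``p_in`` and carry Beta
    weights around ``weight_mean_in``; between-module edges use ``p_out`` /
    ``weight_mean_out``. Symmetric, zero diagonal.
    """
    if config.p_in <= config.p_out:
        import warnings

        warnings.warn("p_in <= p_out: planted modularity is unrecoverable by design",
                      stacklevel=2)
    rng = np.random.default_rng(derive_seed(config.seed, "backbone"))
    n = config.n_nodes
    part = _module_assignment(n, config.n_modules)
    iu, ju = np.triu_indices(n, k=1)
    within = part[iu] == part[ju]
    p_edge = np.where(within, config.p_in, config.p_out)
    present = rng.random(iu.size) < p_edge
    w = np.zeros(iu.size)
    w[present & within] = _beta_weights(
        rng, config.weight_mean_in, config.weight_concentration,
        int(np.sum(present & within)))
    w[present & ~within] = _beta_weights(
        rng, config.weight_mean_out, config.weight_concentration,
        int(np.sum(present & ~within)))
    mat = np.zeros((n, n))
    mat[iu, ju] = w
    mat += mat.T
    return mat, part


def generate_severity_and_covariates(config: SimulationConfig) -> pd.DataFrame:
    """Per-subject (bpp_pct, psychq_a, updrs3) with the configured correlations.

    The two severity components are drawn from a bivariate normal at the
    target correlation; the misperception percentage is mapped to [0, 100]
    by a scaled logistic (keeping rank order, emulating a right-skewed task
    score with mean near 18%), the questionnaire total is an affine map
    clipped at zero. The motor covariate correlates with the latent
    severity at ``covariate_corr``.
    """
    rng = np.random.default_rng(derive_seed(config.seed, "severity"))
    n = config.n_subjects
    rho = config.severity_component_corr
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    bpp = 100.0 * expit(0.9 * z[:, 0] - 1.55)       # mean ~18.5%, range mostly 0-50
    psychq = np.clip(9.5 + 7.0 * z[:, 1], 0.0, 52.0)

    # the covariate tracks the composite severity (sum of standardized
    # components) at the configured correlation
    def _z(x: np.ndarray) -> np.ndarray:
        s = x.std(ddof=1)
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    hss = _z(bpp) + _z(psychq)
    z_hss = _z(hss)
    r = config.covariate_corr
    noise = rng.standard_normal(n)
    updrs_z = r * z_hss + np.sqrt(max(0.0, 1.0 - r**2)) * noise
    updrs3 = np.clip(40.0 + 12.0 * updrs_z, 0.0, 132.0)
    return pd.DataFrame({"bpp_pct": bpp, "psychq_a": psychq, "updrs3": updrs3})


def _pick_planted_edges(backbone: np.ndarray, rsn_labels: np.ndarray,
                        config: SimulationConfig,
                        rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Grow a connected planted subnetwork over the group backbone.

    Starting from a random backbone edge, edges touching the current node
    set are added one at a time, so the planted effect forms one connected
    subnetwork rather than scattered single edges.
    """
    iu, ju = np.triu_indices(backbone.shape[0], k=1)
    present = backbone[iu, ju] > 0
    if config.planted_within_rsn is not None:
        lab = rsn_labels
        present &= (lab[iu] == config.planted_within_rsn) & (lab[ju] == config.planted_within_rsn)
    idx = np.flatnonzero(present)
    if config.planted_edges > idx.size:
        raise ValueError(
            f"planted_edges={config.planted_edges} exceeds available edges ({idx.size})")
    chosen: list[int] = [int(rng.choice(idx))]
    nodes = {int(iu[chosen[0]]), int(ju[chosen[0]])}
    pool = set(idx.tolist()) - set(chosen)
    while len(chosen) < config.planted_edges:
        touching = [e for e in pool if iu[e] in nodes or ju[e] in nodes]
        if not touching:  # component exhausted; restart from a fresh edge
            touching = sorted(pool)
        e = int(rng.choice(touching))
        chosen.append(e)
        pool.discard(e)
        nodes.update((int(iu[e]), int(ju[e])))
    chosen_arr = np.sort(np.array(chosen))
    return iu[chosen_arr], ju[chosen_arr]


def _node_table(config: SimulationConfig, part: np.ndarray,
                rng: np.random.Generator) -> NodeTable:
    """Pseudo-parcellation: module-wise RSN labels, module-clustered centroids.

    The last module doubles as the subcortical compartment when there are at
    least two modules, mirroring a cortical parcellation with a separate
    subcortical block (~6% of nodes in the full-scale atlas).
    """
    n = config.n_nodes
    labels = np.empty(n, dtype=object)
    sub = np.zeros(n, dtype=bool)
    sub_module = config.n_modules - 1 if config.n_modules >= 2 else None
    for m in range(config.n_modules):
        members = np.flatnonzero(part == m)
        if m == sub_module:
            labels[members] = SUBCORTICAL_LABEL
            sub[members] = True
        else:
            labels[members] = RSN_LABELS[m % len(RSN_LABELS)]
    module_centers = rng.uniform(-60, 60, size=(config.n_modules, 3))
    cent = module_centers[part] + rng.normal(0, 8.0, size=(n, 3))
    hemi = np.where(cent[:, 0] < -2, "left", np.where(cent[:, 0] > 2, "right", "midline"))
    df = pd.DataFrame({
        "node_id": np.arange(n),
        "name": [f"region_{i:03d}" for i in range(n)],
        "hemisphere": hemi,
        "x": cent[:, 0], "y": cent[:, 1], "z": cent[:, 2],
        "rsn_label": labels,
        "is_subcortical": sub,
    })
    return NodeTable(df)


def generate_cohort(config: SimulationConfig) -> tuple[
        CohortManifest, list[SubjectConnectome], NodeTable, GroundTruth]:
    """Full cohort: manifest, subject matrices, node table and ground truth.

    Each subject's matrix is the group backbone plus Gaussian weight noise
    and Bernoulli presence jitter; on planted edges the weight is reduced by
    ``effect_beta`` per standard deviation of the composite severity score.
    """
    backbone, part = generate_group_backbone(config)
    sev = generate_severity_and_covariates(config)
    rng = np.random.default_rng(derive_seed(config.seed, "cohort"))
    node_table = _node_table(config, part, rng)
    pi, pj = _pick_planted_edges(backbone, node_table.rsn_labels, config, rng)

    # standardized composite of the two components (population convention is
    # irrelevant for the planted effect; analysis recomputes its own HSS)
    def _z(x: np.ndarray) -> np.ndarray:
        s = x.std(ddof=1)
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    true_hss = _z(sev["bpp_pct"].to_numpy()) + _z(sev["psychq_a"].to_numpy())
    z_hss = _z(true_hss) if true_hss.std(ddof=1) > 0 else true_hss

    n = config.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    base_upper = backbone[iu, ju]
    present = base_upper > 0
    cohort: list[SubjectConnectome] = []
    for s in range(config.n_subjects):
        w = base_upper.copy()
        if config.subject_noise_sd > 0:
            w[present] += rng.normal(0, config.subject_noise_sd, int(present.sum()))
        if config.presence_jitter > 0:
            drop = present & (rng.random(iu.size) < config.presence_jitter)
            w[drop] = 0.0
        mat = np.zeros((n, n))
        mat[iu, ju] = w
        mat += mat.T
        mat[pi, pj] = mat[pj, pi] = np.where(
            mat[pi, pj] > 0,
            np.clip(mat[pi, pj] - config.effect_beta * z_hss[s], *WEIGHT_CLIP),
            0.0)
        np.clip(mat, 0.0, WEIGHT_CLIP[1], out=mat)
        mat[mat > 0] = np.clip(mat[mat > 0], WEIGHT_CLIP[0], WEIGHT_CLIP[1])
        cohort.append(SubjectConnectome(subject_id=f"sub-{s+1:03d}", weights=mat))

    manifest = CohortManifest(pd.DataFrame({
        "subject_id": [c.subject_id for c in cohort],
        "matrix_path": [f"{c.subject_id}.tsv" for c in cohort],
        "bpp_pct": sev["bpp_pct"],
        "psychq_a": sev["psychq_a"],
        "updrs3": sev["updrs3"],
        "age": np.round(rng.normal(68, 8, config.n_subjects), 1),
        "duration": np.round(np.abs(rng.normal(6, 4, config.n_subjects)), 1),
    }))
    planted = EdgeList(pd.DataFrame({
        "node_i": pi, "node_j": pj, "statistic": backbone[pi, pj]}))
    truth = GroundTruth(true_partition=part, planted_edge_set=planted,
                        true_hss=true_hss)
    return manifest, cohort, node_table, truth


def write_cohort(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Generate a cohort and write every artifact under ``out_dir``."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest, cohort, node_table, truth = generate_cohort(config)
    for conn in cohort:
        write_subject_matrix(conn, out / f"{conn.subject_id}.tsv")
    write_manifest(manifest, out / "manifest.tsv")
    write_node_table(node_table, out / "nodes.tsv")
    gt = {
        "true_partition": truth.true_partition.tolist(),
        "planted_edges": [[int(i), int(j)] for i, j in
                          zip(truth.planted_edge_set.frame["node_i"],
                              truth.planted_edge_set.frame["node_j"])],
        "true_hss": truth.true_hss.tolist(),
        "config": {k: v for k, v in asdict(config).items()},
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return out / "manifest.tsv"
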