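"""End-to-end orchestration: severity -> mask -> modules -> metrics -> NBS -> inference.

A single master seed is hashed per stage so every stage is independently
reproducible; the run summary JSON records parameters, seeds and headline
outputs, and every intermediate artifact is written to the output
directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .community import consensus_partition, select_gamma
from .inference import (club_enrichment_test, group_metric_contrast,
                        nodewise_screen, rsn_overlap_test)
from .io import (load_cohort, load_node_table, write_edge_list,
                 write_metrics_table)
from .metrics import diverse_club, node_metrics_table
from .nbs import NBSConfig, nbs_test
from .severity import compute_hss, correlate_demographics
from .simulate import derive_seed
from .threshold import (apply_mask, consistency_mask, distance_binned_mask,
                        group_mean_matrix)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat key-value configuration for a full pipeline run."""

    manifest: str
    nodes: str
    out_dir: str
    threshold_method: str = "consistency"   # or "distance_binned"
    consistency_fraction: float = 0.5
    target_density: float = 0.15
    n_bins: int = 10
    gamma_min: float = 0.5
    gamma_max: float = 2.0
    gamma_step: float = 0.1
    gamma_runs: int = 100
    consensus_runs: int = 500
    t_threshold: float = 1.7
    n_permutations: int = 5000
    direction: str = "negative"
    covariate: Optional[str] = "updrs3"
    alpha: float = 0.05
    club_iterations: int = 5000
    infer_iterations: int = 5000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        for p in (self.manifest, self.nodes):
            if not Path(p).exists():
                raise FileNotFoundError(f"config references missing file: {p}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    def _stage(name: str):
        logger.info("stage: %s", name)
        return derive_seed(seed, name)

    # --- severity ---------------------------------------------------------
    _stage("severity")
    manifest, cohort = load_cohort(config.manifest)
    node_table = load_node_table(config.nodes)
    if node_table.n_nodes != cohort[0].n_nodes:
        raise ValueError("node table and matrices disagree on n_nodes")
    sev = compute_hss(manifest)
    sev.to_csv(out / "severity.tsv", sep="\t", index=False)
    demo = correlate_demographics(sev, manifest)
    demo.to_csv(out / "demographic_correlations.tsv", sep="\t", index=False)
    hss = sev["hss"].to_numpy()

    # --- group threshold --------------------------------------------------
    _stage("threshold")
    if config.threshold_method == "consistency":
        mask = consistency_mask(cohort, fraction=config.consistency_fraction)
    elif config.threshold_method == "distance_binned":
        mask = distance_binned_mask(cohort, node_table,
                                    target_density=config.target_density,
                                    n_bins=config.n_bins)
    else:
        raise ValueError(f"unknown threshold_method {config.threshold_method!r}")
    np.savetxt(out / "group_mask.tsv", mask.matrix.astype(int), fmt="%d",
               delimiter="\t")
    gmean = group_mean_matrix(cohort, mask)
    np.savetxt(out / "group_mean.tsv", gmean, fmt="%.10g", delimiter="\t")

    # --- resolution sweep + consensus modules -----------------------------
    s_gamma = _stage("gamma_sweep")
    gammas = np.round(np.arange(config.gamma_min, config.gamma_max + 1e-9,
                                config.gamma_step), 10)
    sweep = select_gamma(gmean, gammas=gammas, n_runs=config.gamma_runs,
                         seed=s_gamma)
    pd.DataFrame({"gamma": sweep.gammas, "similarity": sweep.similarity,
                  "mean_n_modules": sweep.mean_n_modules}).to_csv(
        out / "gamma_sweep.tsv", sep="\t", index=False)
    s_cons = _stage("consensus")
    partition = consensus_partition(gmean, gamma=sweep.selected_gamma,
                                    n_runs=config.consensus_runs, seed=s_cons)
    pd.DataFrame({"node_id": np.arange(partition.n_nodes),
                  "module": partition.assignment}).to_csv(
        out / "partition.tsv", sep="\t", index=False)

    # --- node metrics + diverse club --------------------------------------
    s_club = _stage("metrics")
    metrics = node_metrics_table(gmean, partition)
    club = diverse_club(metrics["B"].to_numpy(),
                        n_iterations=config.club_iterations, seed=s_club)
    metrics["is_diverse_club"] = np.isin(metrics["node_id"], club.club_node_ids)

    # per-subject metrics under the group partition, for the nodewise screen
    W_stack = np.stack([
        node_metrics_table(apply_mask(c, mask).weights, partition)["W"].to_numpy()
        for c in cohort])
    B_stack = np.stack([
        node_metrics_table(apply_mask(c, mask).weights, partition)["B"].to_numpy()
        for c in cohort])

    # --- NBS --------------------------------------------------------------
    s_nbs = _stage("nbs")
    cov = (manifest.frame[config.covariate].to_numpy(dtype=float)
           if config.covariate else None)
    nbs_cfg = NBSConfig(t_threshold=config.t_threshold,
                        n_permutations=config.n_permutations,
                        direction=config.direction,
                        covariate_name=config.covariate,
                        alpha=config.alpha, seed=s_nbs)
    result = nbs_test(cohort, mask, hss, covariate=cov, config=nbs_cfg)
    write_edge_list(result.significant_edges, out / "nbs_subnetwork_edges.tsv")
    np.savetxt(out / "nbs_null_max_component.tsv",
               result.max_component_size_null, fmt="%d")
    metrics["in_subnetwork"] = np.isin(metrics["node_id"],
                                       result.significant_nodes)
    write_metrics_table(metrics, out / "node_metrics.tsv")

    # --- inference on the subnetwork --------------------------------------
    summary_inf: dict = {}
    sub_nodes = result.significant_nodes
    if sub_nodes.size and sub_nodes.size < node_table.n_nodes:
        s = _stage("overlap")
        overlap = rsn_overlap_test(sub_nodes, node_table.rsn_labels,
                                   n_iterations=config.infer_iterations, seed=s)
        overlap.to_csv(out / "rsn_overlap.tsv", sep="\t", index=False)
        summary_inf["targeted_rsns"] = overlap.loc[
            overlap["verdict"] == "targeted", "rsn_label"].tolist()
        summary_inf["spared_rsns"] = overlap.loc[
            overlap["verdict"] == "spared", "rsn_label"].tolist()
        s = _stage("contrast")
        in_sub = metrics["in_subnetwork"].to_numpy()
        summary_inf["contrast_W"] = group_metric_contrast(
            metrics["W"].to_numpy(), in_sub,
            n_iterations=config.infer_iterations, seed=s)
        summary_inf["contrast_B"] = group_metric_contrast(
            metrics["B"].to_numpy(), in_sub,
            n_iterations=config.infer_iterations, seed=derive_seed(s, "B"))
        if club.club_node_ids.size:
            s = _stage("club_enrichment")
            count, p = club_enrichment_test(club.club_node_ids, sub_nodes,
                                            node_table.n_nodes,
                                            n_iterations=config.infer_iterations,
                                            seed=s)
            summary_inf["club_in_subnetwork"] = {"count": count, "p": p}

    s = _stage("screen")
    screen_w = nodewise_screen(W_stack, hss, covariate=cov,
                               n_iterations=config.infer_iterations,
                               alpha=config.alpha, seed=s)
    screen_b = nodewise_screen(B_stack, hss, covariate=cov,
                               n_iterations=config.infer_iterations,
                               alpha=config.alpha, seed=derive_seed(s, "B"))
    pd.DataFrame({"node_id": np.arange(node_table.n_nodes),
                  "rho_W": screen_w.rho, "flagged_W": screen_w.flagged,
                  "rho_B": screen_b.rho, "flagged_B": screen_b.flagged}).to_csv(
        out / "nodewise_screen.tsv", sep="\t", index=False)

    summary = {
        "version": __version__,
        "seed": seed,
        "parameters": asdict(config),
        "n_subjects": manifest.n_subjects,
        "n_nodes": node_table.n_nodes,
        "mask_density": mask.density,
        "selected_gamma": sweep.selected_gamma,
        "n_modules": partition.n_modules,
        "modularity_Q": partition.quality,
        "club_size": int(club.club_node_ids.size),
        "subnetwork_n_edges": int(len(result.significant_edges)),
        "subnetwork_n_nodes": int(sub_nodes.size),
        "component_p_fwe": [c.p_fwe for c in result.components[:10]],
        "n_flagged_W": int(screen_w.flagged.sum()),
        "n_flagged_B": int(screen_b.flagged.sum()),
        **summary_inf,
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1,
                                                     sort_keys=True))
    return summary
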