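"""Shared data model and on-disk I/O for the connectome pipeline.

All artifacts are plain delimited text (TSV/CSV auto-detected by extension,
``.gz`` accepted transparently): square weight matrices, node tables, cohort
manifests, per-node metric tables and edge lists. Node indexing is 0-based;
the on-disk ``node_id`` column is authoritative, not row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

#: Canonical cortical resting-state network labels (Yeo 7-network scheme)
#: plus the separate subcortical label.
RSN_LABELS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "DMN",
)
SUBCORTICAL_LABEL = "subcortical"

SYMMETRY_TOL = 1e-9

REQUIRED_MANIFEST_COLS = ("subject_id", "matrix_path", "bpp_pct", "psychq_a", "updrs3")
OPTIONAL_MANIFEST_COLS = ("age", "duration", "ledd", "hy", "mmse", "tmt")


class FormatError(ValueError):
    """Malformed on-disk artifact (non-square matrix, missing columns...)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a type invariant."""


class DimensionError(ValueError):
    """Size mismatch between artifacts that must agree on n."""


@dataclass(frozen=True)
class SubjectConnectome:
    """One subject's symmetric weighted connectivity matrix.

    Weights are unitless FA-like values in (0, 1); the diagonal is zero.
    """

    subject_id: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"{self.subject_id}: weights must be square, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValidationError(f"{self.subject_id}: non-finite weight")
        if np.any(w < 0):
            raise ValidationError(f"{self.subject_id}: negative weight")
        asym = np.max(np.abs(w - w.T)) if w.size else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(f"{self.subject_id}: asymmetry {asym:.3g} exceeds tolerance")
        w = (w + w.T) / 2.0  # exact symmetrization within tolerance
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class NodeTable:
    """Parcellation node metadata: names, hemispheres, centroids, RSN labels."""

    frame: pd.DataFrame

    REQUIRED = ("node_id", "name", "hemisphere", "x", "y", "z", "rsn_label", "is_subcortical")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"node table missing columns: {missing}")
        df["node_id"] = df["node_id"].astype(int)
        if df["node_id"].duplicated().any():
            raise ValidationError("duplicate node_id in node table")
        df = df.sort_values("node_id").reset_index(drop=True)
        n = len(df)
        if not np.array_equal(df["node_id"].to_numpy(), np.arange(n)):
            raise ValidationError("node_ids must be contiguous 0..n-1")
        bad_hemi = set(df["hemisphere"]) - {"left", "right", "midline"}
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere values: {sorted(bad_hemi)}")
        allowed = set(RSN_LABELS) | {SUBCORTICAL_LABEL}
        bad = set(df["rsn_label"]) - allowed
        if bad:
            raise ValidationError(f"unknown rsn_label values: {sorted(bad)}")
        df["is_subcortical"] = df["is_subcortical"].astype(bool)
        mism = df["is_subcortical"] != (df["rsn_label"] == SUBCORTICAL_LABEL)
        if mism.any():
            raise ValidationError("rsn_label must be 'subcortical' iff is_subcortical")
        object.__setattr__(self, "frame", df)

    @property
    def n_nodes(self) -> int:
        return len(self.frame)

    @property
    def centroids(self) -> np.ndarray:
        """n×3 array of MNI-style centroid coordinates in mm."""
        return self.frame[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def rsn_labels(self) -> np.ndarray:
        return self.frame["rsn_label"].to_numpy()


@dataclass(frozen=True)
class CohortManifest:
    """Per-subject severity components, covariates and matrix paths."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy().reset_index(drop=True)
        missing = [c for c in REQUIRED_MANIFEST_COLS if c not in df.columns]
        if missing:
            raise FormatError(f"manifest missing required columns: {missing}")
        if df["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject_id in manifest")
        for col in ("bpp_pct", "psychq_a", "updrs3"):
            if df[col].isna().any():
                raise ValidationError(f"missing values in required column {col!r}")
            df[col] = df[col].astype(float)
        if ((df["bpp_pct"] < 0) | (df["bpp_pct"] > 100)).any():
            raise ValidationError("bpp_pct outside [0, 100]")
        if (df["psychq_a"] < 0).any():
            raise ValidationError("psychq_a must be >= 0")
        object.__setattr__(self, "frame", df)

    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.frame["subject_id"]]

    @property
    def n_subjects(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class EdgeList:
    """Rows of (node_i, node_j, statistic) with node_i < node_j, no duplicates."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame.copy().reset_index(drop=True)
        for c in ("node_i", "node_j"):
            if c not in df.columns:
                raise FormatError(f"edge list missing column {c!r}")
            df[c] = df[c].astype(int)
        if "statistic" not in df.columns:
            df["statistic"] = np.nan
        if (df["node_i"] >= df["node_j"]).any():
            raise ValidationError("edge list requires node_i < node_j (no self-loops)")
        if df.duplicated(subset=["node_i", "node_j"]).any():
            raise ValidationError("duplicate edge in edge list")
        object.__setattr__(self, "frame", df)

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return set(zip(self.frame["node_i"], self.frame["node_j"]))

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    return "," if ".csv" in suffixes else "\t"


def load_subject_matrix(path: str | Path, expected_n: Optional[int] = None,
                        subject_id: Optional[str] = None) -> SubjectConnectome:
    """Read a whitespace- or comma-delimited square matrix as a connectome.

    Asymmetries below 1e-9 are averaged away; larger ones are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    try:
        raw = pd.read_csv(path, sep=None, engine="python", header=None,
                          comment="#").to_numpy(dtype=float)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"{path}: could not parse numeric matrix ({exc})") from None
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise DimensionError(f"{path}: expected square matrix, got {raw.shape}")
    if np.isnan(raw).any():
        raise ValidationError(f"{path}: NaN entry in matrix")
    if expected_n is not None and raw.shape[0] != expected_n:
        raise DimensionError(f"{path}: size {raw.shape[0]} != expected {expected_n}")
    sid = subject_id if subject_id is not None else path.stem.removesuffix(".tsv").removesuffix(".csv")
    return SubjectConnectome(subject_id=sid, weights=raw)


def write_subject_matrix(conn: SubjectConnectome, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, conn.weights, delimiter=_sep_for(path), fmt="%.10g")


def load_node_table(path: str | Path) -> NodeTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return NodeTable(df)


def write_node_table(table: NodeTable, path: str | Path) -> None:
    path = Path(path)
    table.frame.to_csv(path, sep=_sep_for(path), index=False)


def load_manifest(path: str | Path) -> CohortManifest:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return CohortManifest(df)


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    manifest.frame.to_csv(path, sep=_sep_for(path), index=False)


def load_cohort(manifest_path: str | Path) -> tuple[CohortManifest, list[SubjectConnectome]]:
    """Load a manifest and every subject matrix it references, in order.

    Relative matrix paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    manifest = load_manifest(manifest_path)
    base = manifest_path.parent
    cohort: list[SubjectConnectome] = []
    n_ref: Optional[int] = None
    for _, row in manifest.frame.iterrows():
        mpath = Path(row["matrix_path"])
        if not mpath.is_absolute():
            mpath = base / mpath
        if not mpath.exists():
            raise FileNotFoundError(
                f"matrix for subject {row['subject_id']!r} not found: {mpath}")
        conn = load_subject_matrix(mpath, expected_n=n_ref, subject_id=str(row["subject_id"]))
        n_ref = conn.n_nodes
        cohort.append(conn)
    return manifest, cohort


def write_metrics_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-node metrics table as delimited text with full precision."""
    Path(path)
    table.to_csv(path, sep=_sep_for(Path(path)), index=False, float_format="%.17g")


def load_metrics_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep=_sep_for(Path(path)))


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    edges.frame.to_csv(Path(path), sep=_sep_for(Path(path)), index=False,
                       float_format="%.17g")


def load_edge_list(path: str | Path) -> EdgeList:
    df = pd.read_csv(Path(path), sep=_sep_for(Path(path)))
    return EdgeList(df)


def edges_from_mask_matrix(matrix: np.ndarray, values: Optional[np.ndarray] = None) -> EdgeList:
    """Upper-triangle edges of a boolean/weight matrix as an EdgeList."""
    iu, ju = np.triu_indices(matrix.shape[0], k=1)
    keep = matrix[iu, ju] != 0
    stat = values[iu, ju][keep] if values is not None else matrix[iu, ju][keep]
    return EdgeList(pd.DataFrame({
        "node_i": iu[keep], "node_j": ju[keep], "statistic": stat}))
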