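"""Delimited-text I/O for vertex-wise surface features, parcellations, matrices and graphs.

All formats are plain UTF-8 text with a mandatory header row, ``.`` decimal
separator, and tab delimiting by default (comma accepted on read).  Binary
FreeSurfer formats (``.mgh``/``.annot``/``.surf``) are deliberately out of
scope: vertex tables are expected as simple exports with one row per vertex.

Formats
-------
Vertex table
    ``vertex_id  region_label  thickness  area  volume  sulc  metric_distortion  curvature``
Parcellation
    ``region_label  hemisphere  index  region_name``
Matrix
    first row and first column carry region labels.
Graph edge list
    ``region_a  region_b  weight  present``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: canonical feature column order for FreeSurfer-like exports
FEATURE_COLUMNS = (
    "thickness",
    "area",
    "volume",
    "sulc",
    "metric_distortion",
    "curvature",
)


class FormatError(ValueError):
    """A file does not conform to one of the toolkit's text formats."""


@dataclass(frozen=True)
class VertexTable:
    """Per-vertex feature rows for one subject.

    Attributes
    ----------
    vertex_id : (n,) int array, unique within the subject
    region_label : (n,) array of atlas labels
    features : (n, d) float array, columns ordered as ``feature_names``
    feature_names : names of the d selected feature columns
    """

    vertex_id: np.ndarray
    region_label: np.ndarray
    features: np.ndarray
    feature_names: tuple[str, ...]

    @property
    def n_vertices(self) -> int:
        return len(self.vertex_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"vertex_id": self.vertex_id, "region_label": self.region_label})
        for j, name in enumerate(self.feature_names):
            df[name] = self.features[:, j]
        return df


@dataclass(frozen=True)
class ParcellationMap:
    """Bijective map between atlas region labels and contiguous indices 0..V-1."""

    labels: tuple[str, ...]  # position = index
    hemispheres: tuple[str, ...]
    region_names: tuple[str, ...]
    label_to_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.label_to_index:
            object.__setattr__(
                self, "label_to_index", {lab: i for i, lab in enumerate(self.labels)}
            )

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.label_to_index[label]
        except KeyError:
            raise KeyError(f"region label not in parcellation: {label!r}") from None

    def hemisphere_of(self, label: str) -> str:
        return self.hemispheres[self.index_of(label)]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    if path.stat().st_size == 0:
        raise FormatError(f"empty file: {path}")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty:
        raise FormatError(f"no data rows in {path}")
    return df


def read_vertex_features(path, feature_names: Sequence[str]) -> VertexTable:
    """Read a delimited vertex-feature table, keeping only the requested features.

    Raises :class:`FormatError` naming the offending column or row on missing
    columns, duplicate vertex ids, or non-numeric feature cells.  Row order is
    preserved (downstream network construction is permutation-invariant).
    """
    feature_names = tuple(feature_names)
    if not feature_names:
        raise ValueError("at least one feature column must be requested")
    df = _read_table(path)
    for col in ("vertex_id", "region_label", *feature_names):
        if col not in df.columns:
            raise FormatError(f"column not found: {col}")
    vid = pd.to_numeric(df["vertex_id"], errors="coerce")
    if vid.isna().any():
        row = int(vid.isna().idxmax()) + 2  # +2: header + 1-based lines
        raise FormatError(f"non-numeric vertex_id at line {row}")
    raise_bad = None
    feats = np.empty((len(df), len(feature_names)), dtype=float)
    for j, name in enumerate(feature_names):
        col = pd.to_numeric(df[name], errors="coerce")
        if col.isna().any():
            bad = int(col.isna().idxmax()) + 2
            raise_bad = f"non-numeric or missing value in column {name!r} at line {bad}"
            break
        feats[:, j] = col.to_numpy(dtype=float)
    if raise_bad:
        raise FormatError(raise_bad)
    vid_arr = vid.to_numpy(dtype=int)
    if len(np.unique(vid_arr)) != len(vid_arr):
        raise FormatError("duplicate vertex_id values")
    return VertexTable(
        vertex_id=vid_arr,
        region_label=df["region_label"].to_numpy(dtype=object),
        features=feats,
        feature_names=feature_names,
    )


def write_vertex_features(table: VertexTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_parcellation(path) -> ParcellationMap:
    """Read a parcellation lookup; indices must be contiguous 0..V-1 and unique."""
    df = _read_table(path)
    for col in ("region_label", "hemisphere", "index"):
        if col not in df.columns:
            raise FormatError(f"column not found: {col}")
    idx = pd.to_numeric(df["index"], errors="coerce")
    if idx.isna().any():
        raise FormatError("non-numeric region index")
    idx = idx.to_numpy(dtype=int)
    labels = df["region_label"].to_numpy(dtype=object)
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate region_label in parcellation")
    if len(set(idx.tolist())) != len(idx):
        raise FormatError("duplicate region index in parcellation")
    if sorted(idx.tolist()) != list(range(len(idx))):
        raise FormatError("region indices not contiguous from 0")
    order = np.argsort(idx)
    names = (
        df["region_name"].to_numpy(dtype=object)
        if "region_name" in df.columns
        else labels.copy()
    )
    return ParcellationMap(
        labels=tuple(labels[order]),
        hemispheres=tuple(df["hemisphere"].to_numpy(dtype=object)[order]),
        region_names=tuple(names[order]),
    )


def default_parcellation() -> ParcellationMap:
    """The bundled 68-region Desikan-Killiany cortical atlas (34 per hemisphere)."""
    with resources.as_file(resources.files("morphnet.data") / "dk_atlas.tsv") as p:
        return read_parcellation(p)


def write_matrix(matrix: np.ndarray, labels: Sequence[str], path) -> None:
    """Write a square labelled matrix as TSV; round-trips to 1e-12."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    if len(labels) != matrix.shape[0]:
        raise ValueError(
            f"labels length {len(labels)} does not match matrix dimension {matrix.shape[0]}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["region", *labels]) + "\n")
        for lab, row in zip(labels, matrix):
            fh.write(lab + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = _read_table(path)
    labels = df.iloc[:, 0].tolist()
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(f"matrix in {path} is not square: {mat.shape}")
    header = list(df.columns[1:])
    if header != [str(l) for l in labels]:
        raise FormatError("row and column labels disagree")
    return mat, labels


def write_edge_list(adjacency: np.ndarray, weights: np.ndarray, labels: Sequence[str], path) -> None:
    """Write an undirected graph as ``region_a region_b weight present`` rows (i < j)."""
    V = len(labels)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("region_a\tregion_b\tweight\tpresent\n")
        for i in range(V):
            for j in range(i + 1, V):
                fh.write(
                    f"{labels[i]}\t{labels[j]}\t{weights[i, j]:.17g}\t{int(adjacency[i, j])}\n"
                )


def read_edge_list(path, labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    df = _read_table(path)
    V = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    adj = np.zeros((V, V), dtype=int)
    w = np.zeros((V, V), dtype=float)
    for _, row in df.iterrows():
        i, j = pos[row["region_a"]], pos[row["region_b"]]
        w[i, j] = w[j, i] = float(row["weight"])
        adj[i, j] = adj[j, i] = int(row["present"])
    return adj, w


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_json_default)


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
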