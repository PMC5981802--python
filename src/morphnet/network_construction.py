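"""Individual morphological brain-network construction.

A subject's network has one node per cortical atlas region.  The edge between
regions A and B is derived from the *combined Euclidean distance* — a scaled
two-sample energy distance between the multisets of per-vertex morphological
feature vectors of the two regions:

.. math::

    e(A, B) = \\frac{n_1 n_2}{n_1 + n_2}\\Bigl(
        \\frac{2}{n_1 n_2}\\sum_{i,j}\\lVert a_i - b_j\\rVert_2
        - \\frac{1}{n_1^2}\\sum_{i,j}\\lVert a_i - a_j\\rVert_2
        - \\frac{1}{n_2^2}\\sum_{i,j}\\lVert b_i - b_j\\rVert_2\\Bigr)

which is zero iff the two empirical feature distributions coincide and
non-negative otherwise.  The subject's region-pair distances are then mapped
to a similarity matrix in two steps: min–max normalization over the
off-diagonal entries (so every subject occupies the same [0, 1] range) and
the exponential map :math:`c = \\exp(-e_n)`, giving off-diagonal similarities
in :math:`[e^{-1}, 1]` and a unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .surface_io import ParcellationMap, VertexTable

_NEG_TOL = 1e-10  # energy distances below -tol are an error, above are clipped


@dataclass(frozen=True)
class RegionFeatureSet:
    """The multiset of per-vertex feature vectors for one atlas region."""

    region_index: int
    vectors: np.ndarray  # (n_vertices, d)

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError("region must hold an (n >= 1, d) feature matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite feature values in region {self.region_index}")
        object.__setattr__(self, "vectors", v)

    @property
    def n_vertices(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]


@dataclass(frozen=True)
class SimilarityMatrix:
    """V x V symmetric edge-similarity matrix for one subject, with provenance."""

    values: np.ndarray
    labels: tuple[str, ...]
    feature_names: tuple[str, ...] = ()
    standardized: bool = True
    method: str = "energy"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def standardize_features(regions: Sequence[RegionFeatureSet]) -> list[RegionFeatureSet]:
    """Z-score each feature column using mean/SD pooled over all of the
    subject's vertices, so that features on disparate physical scales (mm,
    mm^2, mm^3, dimensionless) contribute comparably to the 2-norm.

    Raises ``ValueError`` naming the feature if a pooled column has zero
    variance.
    """
    if not regions:
        raise ValueError("no regions given")
    pooled = np.vstack([r.vectors for r in regions])
    mu = pooled.mean(axis=0)
    sd = pooled.std(axis=0, ddof=0)
    zero = np.nonzero(sd <= 0)[0]
    if zero.size:
        raise ValueError(f"zero-variance feature column(s): {zero.tolist()}")
    return [
        RegionFeatureSet(r.region_index, (r.vectors - mu) / sd) for r in regions
    ]


def combined_euclidean_distance(A: RegionFeatureSet, B: RegionFeatureSet) -> float:
    """Two-sample energy distance between the vertex feature multisets of two
    regions (scaled by :math:`n_1 n_2 / (n_1 + n_2)`).

    Symmetric, translation-invariant, homogeneous of degree one under uniform
    feature scaling, and zero iff A and B carry the same empirical feature
    distribution.  Tiny negative rounding (within 1e-10) is clipped to 0.
    """
    if A.n_features != B.n_features:
        raise ValueError(
            f"feature dimension mismatch: {A.n_features} vs {B.n_features}"
        )
    a, b = A.vectors, B.vectors
    n1, n2 = A.n_vertices, B.n_vertices
    between = cdist(a, b).sum()
    within_a = 2.0 * pdist(a).sum() if n1 > 1 else 0.0
    within_b = 2.0 * pdist(b).sum() if n2 > 1 else 0.0
    e = (n1 * n2 / (n1 + n2)) * (
        2.0 / (n1 * n2) * between - within_a / n1**2 - within_b / n2**2
    )
    if e < -_NEG_TOL:
        raise ValueError(f"energy distance unexpectedly negative: {e}")
    return max(e, 0.0)


def pairwise_dissimilarity(regions: Sequence[RegionFeatureSet]) -> np.ndarray:
    """All-pairs combined Euclidean distance matrix (V x V, symmetric, zero
    diagonal).  Invariant to vertex order within regions and to region
    processing order."""
    V = len(regions)
    if V < 2:
        raise ValueError("need at least two regions")
    d = regions[0].n_features
    for r in regions:
        if r.n_features != d:
            raise ValueError("all regions must share the feature dimension")
    D = np.zeros((V, V))
    for i in range(V):
        for j in range(i + 1, V):
            D[i, j] = D[j, i] = combined_euclidean_distance(regions[i], regions[j])
    return D


def minmax_normalize(D: np.ndarray, include_diagonal: bool = False) -> np.ndarray:
    """Affinely rescale region-pair dissimilarities to [0, 1].

    By default the min and max are taken over the off-diagonal upper triangle
    only; including the structurally zero diagonal (``include_diagonal=True``)
    forces the minimum to 0 and degenerates the map to pure max-scaling.
    """
    D = np.asarray(D, dtype=float)
    iu = np.triu_indices(D.shape[0], k=1)
    vals = D[iu]
    lo = 0.0 if include_diagonal else float(vals.min())
    hi = float(vals.max())
    if hi <= lo:
        raise ValueError("degenerate dissimilarity matrix: all off-diagonal values equal")
    Dn = np.zeros_like(D)
    Dn[iu] = (vals - lo) / (hi - lo)
    return Dn + Dn.T


def to_similarity(Dn: np.ndarray) -> np.ndarray:
    """Exponential similarity map ``c = exp(-e_n)`` with the diagonal pinned
    to 1; off-diagonal entries land in [exp(-1), 1]."""
    Dn = np.asarray(Dn, dtype=float)
    iu = np.triu_indices(Dn.shape[0], k=1)
    if Dn[iu].min() < -1e-12 or Dn[iu].max() > 1 + 1e-12:
        raise ValueError("normalized dissimilarities must lie in [0, 1]")
    C = np.exp(-Dn)
    np.fill_diagonal(C, 1.0)
    return C


def regions_from_table(
    table: VertexTable, parcellation: ParcellationMap
) -> list[RegionFeatureSet]:
    """Group a vertex table into per-region feature sets ordered by atlas index.

    Every atlas region must be represented by at least one vertex, and every
    row's label must be in the parcellation.
    """
    labels = np.asarray(table.region_label)
    unknown = sorted(set(labels) - set(parcellation.labels))
    if unknown:
        raise ValueError(f"labels not in parcellation: {unknown}")
    present = set(labels)
    missing = [lab for lab in parcellation.labels if lab not in present]
    if missing:
        raise ValueError(f"regions with no vertices: {missing}")
    out = []
    for idx, lab in enumerate(parcellation.labels):
        rows = np.nonzero(labels == lab)[0]
        out.append(RegionFeatureSet(idx, table.features[rows]))
    return out


def build_individual_network(
    table: VertexTable,
    parcellation: ParcellationMap,
    feature_names: Sequence[str] | None = None,
    standardize: bool | None = None,
    include_diagonal_in_minmax: bool = False,
) -> SimilarityMatrix:
    """Full construction for one subject: group vertices by region, optionally
    z-score features, compute all-pairs energy distances, min–max normalize,
    and map to similarities.

    ``standardize`` defaults to on when more than one feature is used (mixed
    physical units) and off for a single feature; the flag actually applied is
    recorded in the result's provenance.
    """
    if feature_names is None:
        feature_names = table.feature_names
    else:
        feature_names = tuple(feature_names)
        missing = [f for f in feature_names if f not in table.feature_names]
        if missing:
            raise ValueError(f"features not in table: {missing}")
        cols = [table.feature_names.index(f) for f in feature_names]
        table = VertexTable(
            table.vertex_id, table.region_label, table.features[:, cols], feature_names
        )
    if standardize is None:
        standardize = len(feature_names) > 1
    regions = regions_from_table(table, parcellation)
    if standardize:
        regions = standardize_features(regions)
    D = pairwise_dissimilarity(regions)
    Dn = minmax_normalize(D, include_diagonal=include_diagonal_in_minmax)
    C = to_similarity(Dn)
    return SimilarityMatrix(
        values=C,
        labels=tuple(parcellation.labels),
        feature_names=feature_names,
        standardized=bool(standardize),
        method="energy",
        params={"include_diagonal_in_minmax": include_diagonal_in_minmax},
    )
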