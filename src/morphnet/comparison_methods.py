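"""Competitor single-feature (cortical thickness) edge-similarity formulas.

Five published alternatives for turning two regions' thickness statistics
into an edge value, implemented as printed so that alternative individual
networks can be built and fed through the same thresholding / classification
machinery as the energy-distance networks:

- **kong** — symmetric Kullback–Leibler divergence between kernel-density
  estimates of the two regions' thickness distributions, mapped through
  ``c = exp(−KL)``.
- **kim** — mean-thickness difference z-scored by the other region's SD,
  symmetrized by averaging the two directions (may be negative).
- **wee** — squared mean difference through a Gaussian with width
  sigma_i + sigma_j.
- **dai** — squared mean difference through ``exp(−d/eta)`` with a free
  bandwidth eta.
- **zheng** — a ratio of the two regions' mean absolute deviations
  (c_precision) alongside the squared mean difference (c_rough).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .network_construction import (
    SimilarityMatrix,
    build_individual_network,
    minmax_normalize,
    to_similarity,
)
from .surface_io import ParcellationMap, VertexTable

METHOD_IDS = ("proposed", "kong", "kim", "wee", "dai", "zheng")

_DENSITY_FLOOR = 1e-12


@dataclass(frozen=True)
class RegionSummary:
    """Per-region thickness sample with its summary statistics."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size < 1 or not np.all(np.isfinite(v)):
            raise ValueError("region needs >= 1 finite thickness value")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def T(self) -> float:
        """Mean thickness."""
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std(ddof=0))

    @property
    def mad(self) -> float:
        """Mean absolute deviation from the regional mean."""
        return float(np.abs(self.values - self.values.mean()).mean())


def kong_similarity(
    i: RegionSummary, j: RegionSummary, bandwidth: str | float = "silverman", grid_size: int = 512
) -> float:
    """exp(−KL_sym) between Gaussian-KDE estimates of the two regions'
    thickness densities, integrated on a shared grid spanning the pooled
    range ± 3 bandwidths.  Densities are floored at 1e-12 before the logs."""
    if i.sd == 0 or j.sd == 0:
        raise ValueError("kernel density estimate undefined for zero-variance region")
    kde_i = gaussian_kde(i.values, bw_method=bandwidth)
    kde_j = gaussian_kde(j.values, bw_method=bandwidth)
    bw = max(
        float(np.sqrt(kde_i.covariance[0, 0])), float(np.sqrt(kde_j.covariance[0, 0]))
    )
    lo = min(i.values.min(), j.values.min()) - 3 * bw
    hi = max(i.values.max(), j.values.max()) + 3 * bw
    x = np.linspace(lo, hi, grid_size)
    pi = np.maximum(kde_i(x), _DENSITY_FLOOR)
    pj = np.maximum(kde_j(x), _DENSITY_FLOOR)
    integrand = pi * np.log(pi / pj) + pj * np.log(pj / pi)
    kl = float(np.trapezoid(integrand, x))
    return float(np.exp(-max(kl, 0.0)))


def kim_similarity(i: RegionSummary, j: RegionSummary) -> float:
    """c = (Z(i,j) + Z(j,i)) / 2 with Z(i,j) = (T(i) − T(j)) / sigma_j.

    Both orderings average the same two Z terms, so the value is symmetric in
    (i, j), but it can be negative; the magnitude is what downstream sparsity
    ranking uses.
    """
    if i.sd == 0 or j.sd == 0:
        raise ValueError("kim similarity undefined with a zero-SD region")
    z_ij = (i.T - j.T) / j.sd
    z_ji = (j.T - i.T) / i.sd
    return float((z_ij + z_ji) / 2.0)


def wee_similarity(i: RegionSummary, j: RegionSummary) -> float:
    """c = exp(−(T(i)−T(j))² / 2(sigma_i + sigma_j)²)."""
    sigma = i.sd + j.sd
    if sigma == 0:
        raise ValueError("wee similarity undefined with both SDs zero")
    d = (i.T - j.T) ** 2
    return float(np.exp(-d / (2.0 * sigma**2)))


def dai_similarity(i: RegionSummary, j: RegionSummary, eta: float) -> float:
    """c = exp(−(T(i)−T(j))² / eta) with a free bandwidth eta > 0."""
    if eta <= 0:
        raise ValueError("eta must be > 0")
    d = (i.T - j.T) ** 2
    return float(np.exp(-d / eta))


def zheng_similarity(i: RegionSummary, j: RegionSummary) -> tuple[float, float]:
    """(c_precision, c_rough): the ratio of the two regions' mean absolute
    deviations, and the squared difference of mean thicknesses.

    c_precision(j,i) = 1/c_precision(i,j); it is NaN-flagged when region j's
    deviation is zero.  c_rough is symmetric.
    """
    c_rough = float((i.T - j.T) ** 2)
    if j.mad == 0:
        return float("nan"), c_rough
    return float(i.mad / j.mad), c_rough


def _thickness_summaries(
    table: VertexTable, parcellation: ParcellationMap
) -> list[RegionSummary]:
    if "thickness" not in table.feature_names:
        raise ValueError("thickness column required for comparison methods")
    col = table.feature_names.index("thickness")
    labels = np.asarray(table.region_label)
    out = []
    for lab in parcellation.labels:
        rows = np.nonzero(labels == lab)[0]
        if rows.size == 0:
            raise ValueError(f"region with no vertices: {lab}")
        out.append(RegionSummary(table.features[rows, col]))
    return out


def build_network_with_method(
    table: VertexTable,
    parcellation: ParcellationMap,
    method: str,
    eta: float | None = None,
    kong_grid_size: int = 512,
) -> SimilarityMatrix:
    """Build a subject's V × V edge matrix with the chosen similarity formula.

    ``proposed`` delegates to the energy-distance construction restricted to
    thickness.  ``dai``'s eta defaults to the median of the subject's squared
    mean-difference matrix (self-tuning).  ``zheng``'s network uses c_rough
    (a distance) min–max normalized and passed through the exponential map,
    with the c_precision matrix attached as an auxiliary in ``params``.
    ``kim`` stores the signed values; rank-based thresholding should use the
    magnitude.
    """
    if method not in METHOD_IDS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHOD_IDS}")
    if method == "proposed":
        return build_individual_network(table, parcellation, feature_names=("thickness",))
    summaries = _thickness_summaries(table, parcellation)
    V = len(summaries)
    C = np.zeros((V, V))
    params: dict = {}
    if method == "dai" and eta is None:
        T = np.array([s.T for s in summaries])
        d2 = (T[:, None] - T[None, :]) ** 2
        eta = float(np.median(d2[np.triu_indices(V, k=1)]))
        if eta <= 0:
            raise ValueError("self-tuned eta degenerate: all regional means equal")
        params["eta"] = eta
    elif method == "dai":
        params["eta"] = float(eta)
    if method == "zheng":
        precision = np.ones((V, V))
        rough = np.zeros((V, V))
        for a in range(V):
            for b in range(V):
                if a == b:
                    continue
                cp, cr = zheng_similarity(summaries[a], summaries[b])
                precision[a, b] = cp
                rough[a, b] = cr
        rough_n = minmax_normalize(rough)
        C = to_similarity(rough_n)
        params["c_precision"] = precision
        params["note"] = "edge weight = exp(-minmax(c_rough)); c_precision auxiliary"
    else:
        fns = {
            "kong": lambda a, b: kong_similarity(a, b, grid_size=kong_grid_size),
            "kim": kim_similarity,
            "wee": wee_similarity,
            "dai": lambda a, b: dai_similarity(a, b, eta),
        }
        fn = fns[method]
        for a in range(V):
            for b in range(a + 1, V):
                C[a, b] = C[b, a] = fn(summaries[a], summaries[b])
        np.fill_diagonal(C, 1.0 if method != "kim" else 0.0)
    if method == "zheng":
        np.fill_diagonal(C, 1.0)
    return SimilarityMatrix(
        values=C,
        labels=tuple(parcellation.labels),
        feature_names=("thickness",),
        standardized=False,
        method=method,
        params=params,
    )
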