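"""Test–retest reliability of graph properties via the intraclass
correlation coefficient.

The estimator is ICC(1,1): a one-way random-effects ANOVA over a
subjects × sessions table, where

    ICC = sigma2_between / (sigma2_between + sigma2_within)

with the variance components taken from the mean squares, sigma2_within = MSW
and sigma2_between = (MSB − MSW)/k for k sessions.  Values above 0.75 are
conventionally called excellent and 0.59–0.75 good.  Negative estimates
(MSB < MSW) are reported as computed, with a flag, rather than truncated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .graph_metrics import (
    betweenness_hubs,
    characteristic_path_length,
    clustering_coefficient,
    threshold_by_sparsity,
)
from .network_construction import SimilarityMatrix

EXCELLENT_ICC = 0.75
GOOD_ICC = 0.59


@dataclass(frozen=True)
class ICCResult:
    icc: float
    sigma2_between: float
    sigma2_within: float
    f_stat: float
    p_value: float
    quality_band: str
    negative_estimate: bool = False
    property_name: str = ""
    sparsity: float | None = None


def _band(icc: float) -> str:
    if icc > EXCELLENT_ICC:
        return "excellent"
    if icc >= GOOD_ICC:
        return "good"
    return "other"


def icc_one_way(values: np.ndarray, property_name: str = "", sparsity: float | None = None) -> ICCResult:
    """ICC(1,1) from an (n subjects, k sessions) matrix of one graph property.

    The F statistic MSB/MSW tests the between-subject effect on
    (n−1, n(k−1)) degrees of freedom.  Raises if the table is degenerate
    (fewer than 2 subjects or sessions, missing cells, or zero total
    variance).
    """
    M = np.asarray(values, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need an (n >= 2 subjects, k >= 2 sessions) matrix")
    if not np.all(np.isfinite(M)):
        raise ValueError("missing or non-finite cells in repeated measures")
    n, k = M.shape
    grand = M.mean()
    subj_means = M.mean(axis=1)
    ss_between = k * ((subj_means - grand) ** 2).sum()
    ss_within = ((M - subj_means[:, None]) ** 2).sum()
    if ss_between + ss_within <= 0:
        raise ValueError("zero total variance: ICC undefined")
    msb = ss_between / (n - 1)
    msw = ss_within / (n * (k - 1)) if ss_within > 0 else 0.0
    sigma2_within = msw
    sigma2_between = (msb - msw) / k
    icc = (msb - msw) / (msb + (k - 1) * msw) if (msb + (k - 1) * msw) > 0 else 1.0
    if msw > 0:
        f = msb / msw
        p = float(stats.f.sf(f, n - 1, n * (k - 1)))
    else:
        f, p = np.inf, 0.0
    return ICCResult(
        icc=float(icc),
        sigma2_between=float(sigma2_between),
        sigma2_within=float(sigma2_within),
        f_stat=float(f),
        p_value=p,
        quality_band=_band(float(icc)),
        negative_estimate=bool(icc < 0),
        property_name=property_name,
        sparsity=sparsity,
    )


def _property_value(weights: np.ndarray, prop: str, S: float):
    G = threshold_by_sparsity(weights, S)
    if prop == "Cp":
        return clustering_coefficient(G)[1]
    if prop == "Lp":
        return characteristic_path_length(G)[0]
    if prop == "BC":
        return betweenness_hubs(G).bc
    raise ValueError(f"unknown property: {prop!r} (expected Cp, Lp or BC)")


def icc_over_sparsity(
    session1: Sequence[SimilarityMatrix],
    session2: Sequence[SimilarityMatrix],
    property_name: str,
    sparsities: Sequence[float],
) -> list[ICCResult]:
    """ICC of a graph property across a sparsity grid for paired two-session
    networks.

    For Cp and Lp one ICC is computed per sparsity.  For BC, a per-node ICC is
    computed and averaged across nodes to give one curve point per sparsity
    (the per-node table can be recovered by calling :func:`icc_one_way` on
    individual node columns); the reported p-value for BC is the median
    per-node p.
    """
    if len(session1) != len(session2):
        raise ValueError("sessions must contain the same subjects, paired in order")
    if len(session1) < 2:
        raise ValueError("need at least two subjects")
    results = []
    for S in sparsities:
        vals1 = [_property_value(m.values, property_name, S) for m in session1]
        vals2 = [_property_value(m.values, property_name, S) for m in session2]
        if property_name == "BC":
            per_node = []
            V = len(vals1[0])
            for v in range(V):
                M = np.column_stack(
                    [[x[v] for x in vals1], [x[v] for x in vals2]]
                )
                if M.std() == 0:
                    continue  # constant BC across subjects carries no reliability signal
                per_node.append(icc_one_way(M, "BC", S))
            if not per_node:
                raise ValueError("all nodes have constant betweenness")
            icc_mean = float(np.mean([r.icc for r in per_node]))
            results.append(
                ICCResult(
                    icc=icc_mean,
                    sigma2_between=float(np.mean([r.sigma2_between for r in per_node])),
                    sigma2_within=float(np.mean([r.sigma2_within for r in per_node])),
                    f_stat=float(np.median([r.f_stat for r in per_node])),
                    p_value=float(np.median([r.p_value for r in per_node])),
                    quality_band=_band(icc_mean),
                    negative_estimate=bool(icc_mean < 0),
                    property_name="BC",
                    sparsity=float(S),
                )
            )
        else:
            M = np.column_stack([vals1, vals2])
            results.append(icc_one_way(M, property_name, float(S)))
    return results
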