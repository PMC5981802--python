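"""Seeded generator of FreeSurfer-like synthetic cohorts.

Emulates the statistical structure the pipeline assumes in vertex-wise
surface exports: per-region Gaussian feature distributions on six
morphometric features at realistic physical scales (cortical thickness
~2.5 ± 0.3 mm; per-vertex surface area ~0.6 ± 0.2 mm²; gray-matter volume
~1.5 ± 0.5 mm³; sulcal depth, metric distortion and mean curvature
dimensionless), region-to-region heterogeneity of means, test–retest session
noise on the regional parameters, and group effects concentrated in a chosen
set of affected regions.  Clinical scores (MMSE-like, CDR-like) are coupled
to each subject's realized effect magnitude so that affected edges correlate
with the scores.

No spatial autocorrelation on the cortical surface is modelled: vertices are
i.i.d. within a region, which is sufficient for every property the pipeline
measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .surface_io import FEATURE_COLUMNS, ParcellationMap, VertexTable, default_parcellation

#: per-feature population scale: (baseline mean, between-region SD of means,
#: within-region vertex SD)
FEATURE_SCALES = {
    "thickness": (2.5, 0.25, 0.30),
    "area": (0.6, 0.10, 0.20),
    "volume": (1.5, 0.30, 0.50),
    "sulc": (0.0, 0.40, 0.60),
    "metric_distortion": (0.0, 0.15, 0.30),
    "curvature": (0.0, 0.08, 0.15),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``region_means`` / ``feature_sds`` are (V, d) matrices drawn once per
    spec (seeded) to give each atlas region its own characteristic feature
    profile; ``group_effect`` shifts the affected regions' means for the +1
    group; ``within_subject_sd`` scales the Gaussian session perturbation of
    the regional means used for test–retest pairs.
    """

    V: int = 68
    vertex_count_range: tuple[int, int] = (40, 120)
    feature_names: tuple[str, ...] = FEATURE_COLUMNS
    region_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None
    affected_regions: tuple[int, ...] = ()
    effect_size: float = 0.0  # mean shift in units of within-region vertex SD
    within_subject_sd: float = 0.1  # session noise, in vertex-SD units
    between_subject_sd: float = 0.15  # subject-level deviation of regional means
    n_per_group: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.vertex_count_range[0] < 2:
            raise ValueError("minimum vertex count must be >= 2")
        if self.vertex_count_range[1] < self.vertex_count_range[0]:
            raise ValueError("invalid vertex count range")
        if any(r < 0 or r >= self.V for r in self.affected_regions):
            raise ValueError("affected regions must be atlas indices 0..V-1")
        d = len(self.feature_names)
        rng = np.random.default_rng(self.seed)
        if self.region_means is None:
            means = np.empty((self.V, d))
            sds = np.empty((self.V, d))
            for j, name in enumerate(self.feature_names):
                base, between, within = FEATURE_SCALES.get(name, (0.0, 0.2, 0.3))
                means[:, j] = base + between * rng.standard_normal(self.V)
                sds[:, j] = within
            object.__setattr__(self, "region_means", means)
            object.__setattr__(self, "feature_sds", sds)
        else:
            m = np.asarray(self.region_means, dtype=float)
            s = np.asarray(self.feature_sds, dtype=float)
            if m.shape != (self.V, d) or s.shape != (self.V, d):
                raise ValueError("region_means/feature_sds must be (V, d)")
            if np.any(s <= 0):
                raise ValueError("feature SDs must be positive")
            object.__setattr__(self, "region_means", m)
            object.__setattr__(self, "feature_sds", s)

    @property
    def d(self) -> int:
        return len(self.feature_names)


@dataclass(frozen=True)
class SyntheticCohort:
    subjects: list[VertexTable]
    labels: np.ndarray  # ±1
    mmse: np.ndarray
    cdr: np.ndarray
    truth: dict = field(default_factory=dict)


def _parcellation_for(spec: CohortSpec) -> ParcellationMap:
    if spec.V == 68:
        return default_parcellation()
    labels = tuple(f"region{i:03d}" for i in range(spec.V))
    hemis = tuple("L" if i < spec.V // 2 else "R" for i in range(spec.V))
    return ParcellationMap(labels=labels, hemispheres=hemis, region_names=labels)


def generate_subject(
    spec: CohortSpec,
    subject_shift: np.ndarray | None = None,
    seed: int = 0,
    parcellation: ParcellationMap | None = None,
) -> VertexTable:
    """Draw one subject: per region, a uniform vertex count in the spec's
    range, then i.i.d. Gaussian vertex features around the (possibly shifted)
    regional means.  Byte-identical output under the same (spec, seed)."""
    parc = parcellation or _parcellation_for(spec)
    rng = np.random.default_rng(seed)
    means = spec.region_means if subject_shift is None else spec.region_means + subject_shift
    rows_labels = []
    rows_feats = []
    lo, hi = spec.vertex_count_range
    for r in range(spec.V):
        n_r = int(rng.integers(lo, hi + 1))
        feats = means[r] + spec.feature_sds[r] * rng.standard_normal((n_r, spec.d))
        rows_labels.extend([parc.labels[r]] * n_r)
        rows_feats.append(feats)
    feats = np.vstack(rows_feats)
    return VertexTable(
        vertex_id=np.arange(len(rows_labels)),
        region_label=np.asarray(rows_labels, dtype=object),
        features=feats,
        feature_names=spec.feature_names,
    )


def _subject_level_shift(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Stable subject-specific deviation of regional means (the 'trait' that
    test-retest sessions share and that drives between-subject variance)."""
    return spec.between_subject_sd * spec.feature_sds * rng.standard_normal(
        (spec.V, spec.d)
    )


def generate_test_retest_pair(
    spec: CohortSpec, seed: int = 0, parcellation: ParcellationMap | None = None
) -> tuple[VertexTable, VertexTable]:
    """Two sessions of the same subject.

    Both sessions share the subject's trait shift and the same vertex-noise
    stream; session 2 additionally perturbs the regional means by Gaussian
    noise of SD ``within_subject_sd`` (in vertex-SD units).  With
    ``within_subject_sd = 0`` the two tables are byte-identical, so any
    deterministic network property has ICC = 1 across a cohort of such pairs.
    """
    if spec.within_subject_sd < 0:
        raise ValueError("within_subject_sd must be >= 0")
    rng = np.random.default_rng(seed)
    trait = _subject_level_shift(spec, rng)
    vertex_seed = int(rng.integers(0, 2**31 - 1))
    session_noise = spec.within_subject_sd * spec.feature_sds * rng.standard_normal(
        (spec.V, spec.d)
    )
    t1 = generate_subject(spec, trait, seed=vertex_seed, parcellation=parcellation)
    t2 = generate_subject(
        spec, trait + session_noise, seed=vertex_seed, parcellation=parcellation
    )
    return t1, t2


def generate_two_group_cohort(
    spec: CohortSpec, parcellation: ParcellationMap | None = None
) -> SyntheticCohort:
    """Two groups of ``n_per_group`` subjects; the +1 group's affected regions
    are shifted by ``effect_size`` vertex-SDs on every feature.

    Clinical scores decrease with each subject's realized effect magnitude:
    MMSE-like ≈ 29 − 3·effect + noise clipped to [0, 30]; CDR-like maps the
    same latent severity onto {0, 0.5, 1, 2, 3}.  The ``truth`` block records
    the affected regions and the induced affected edges (all pairs with at
    least one affected endpoint).
    """
    if spec.n_per_group < 2:
        raise ValueError("need at least two subjects per group")
    parc = parcellation or _parcellation_for(spec)
    rng = np.random.default_rng(spec.seed + 1)
    subjects, labels, severity = [], [], []
    for g, lab in ((-1, -1), (1, 1)):
        for _ in range(spec.n_per_group):
            trait = _subject_level_shift(spec, rng)
            subj_severity = 0.0
            if lab == 1 and spec.affected_regions:
                # subject-specific effect magnitude around the group effect size
                mag = max(spec.effect_size * (1.0 + 0.15 * rng.standard_normal()), 0.0)
                for r in spec.affected_regions:
                    trait[r] += mag * spec.feature_sds[r]
                subj_severity = mag
            seed = int(rng.integers(0, 2**31 - 1))
            subjects.append(generate_subject(spec, trait, seed=seed, parcellation=parc))
            labels.append(lab)
            severity.append(subj_severity)
    severity = np.asarray(severity)
    mmse = np.clip(29.0 - 3.0 * severity + 0.8 * rng.standard_normal(len(severity)), 0, 30)
    cdr_latent = 0.25 * severity + 0.15 * rng.standard_normal(len(severity))
    cdr_levels = np.array([0.0, 0.5, 1.0, 2.0, 3.0])
    cdr = cdr_levels[
        np.argmin(np.abs(cdr_latent[:, None] - cdr_levels[None, :]), axis=1)
    ]
    affected = set(spec.affected_regions)
    affected_edges = [
        (i, j)
        for i in range(spec.V)
        for j in range(i + 1, spec.V)
        if i in affected or j in affected
    ]
    return SyntheticCohort(
        subjects=subjects,
        labels=np.asarray(labels),
        mmse=mmse,
        cdr=cdr,
        truth={
            "affected_regions": sorted(affected),
            "affected_edges": affected_edges,
            "effect_size": spec.effect_size,
            "severity": severity.tolist(),
        },
    )
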