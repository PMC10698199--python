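"""Synthetic cohorts, reference maps and donor expression tables.

Generators emulating the statistical structure the pipeline assumes, so
every stage runs and is testable without any imaging or microarray
download.

Cohort model (linear latent factors): each planted cluster c carries one
latent factor per subject, f_sc ~ N(0, 1).  Seed voxels of cluster c read
mu_{group(s), c} + loading * f_sc + N(0, noise_sd); the parcels associated
with cluster c share the same factor, so voxel-parcel Pearson correlation
within a cluster is loading^2 / (loading^2 + noise_sd^2) and zero across
clusters — exactly the covariance contrast the parcellation consumes.
Group effects are additive per-cluster mean shifts; CSF biomarkers are
drawn from group-specific normals around the published cut-offs.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import ReferenceMap
from .io import BIOMARKER_CUTOFFS, ParcelTable, SubjectRecord, classify_biomarker_status
from .transcriptomics import DonorExpression, ProbeTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "Cohort",
    "generate_cohort",
    "generate_reference_maps",
    "generate_donor_expression",
]

#: baseline pons-normalized uptake of seed voxels (hippocampal gray matter
#: runs somewhat above the pons reference) and of brain parcels
SEED_BASELINE = 1.2
PARCEL_BASELINE = 1.0

#: additive per-cluster uptake shifts by diagnosis group.  Disease stages
#: lower uptake progressively; cluster 1 (the "anterior subiculum" stand-in)
#: is relatively preserved at the lateMCI stage, mirroring the qualitative
#: region x group interaction the analysis is meant to detect.
DEFAULT_GROUP_EFFECTS: dict[str, float | list[float]] = {
    "HC": 0.0,
    "earlyMCI": -0.02,
    "lateMCI": [-0.02, -0.02, -0.08, -0.10, -0.10],
    "AD": -0.15,
}

#: per-cluster baseline uptake offsets (cycled when k differs): subicular /
#: anterior clusters run higher than CA / posterior ones, so subregion main
#: effects exist already in the healthy sample
DEFAULT_CLUSTER_BASELINE = (0.10, 0.05, 0.0, -0.05, -0.10)

#: CSF biomarker (mean, sd) per group, pg/mL, straddling the published
#: cut-offs (abeta 977, p-tau 24, t-tau 266)
DEFAULT_BM_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "HC": {"abeta": (1350.0, 250.0), "p_tau": (18.0, 4.0), "t_tau": (210.0, 50.0)},
    "earlyMCI": {"abeta": (900.0, 220.0), "p_tau": (26.0, 6.0), "t_tau": (280.0, 60.0)},
    "lateMCI": {"abeta": (780.0, 200.0), "p_tau": (31.0, 7.0), "t_tau": (320.0, 70.0)},
    "AD": {"abeta": (650.0, 170.0), "p_tau": (38.0, 9.0), "t_tau": (380.0, 80.0)},
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the planted-structure setting used throughout the
    tests: 100 high-resolution subjects, 5 planted clusters over 200 seed
    voxels and 60 parcels, unit factor loading, residual noise 0.5.
    """

    n_subjects: int = 100
    n_parcels: int = 60
    n_seed_voxels: int = 200
    k_true: int = 5
    loading: float = 1.0
    noise_sd: float = 0.5
    group_fractions: dict[str, float] = field(default_factory=lambda: {"HC": 1.0})
    cluster_baseline: tuple = DEFAULT_CLUSTER_BASELINE
    group_effects: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    bm_params: dict = field(default_factory=lambda: dict(DEFAULT_BM_PARAMS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.n_seed_voxels < self.k_true:
            raise ValueError("more clusters than seed voxels")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic cohort."""

    voxel_labels: np.ndarray  # planted cluster (1..k) per seed voxel
    cluster_parcel_map: dict[int, list[int]]  # cluster -> associated parcel ids
    groups: list[str]
    bm_status: list[str]

    def __post_init__(self) -> None:
        sets = [set(v) for v in self.cluster_parcel_map.values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("cluster parcel sets must be disjoint")


@dataclass
class Cohort:
    """Synthetic subject sample: seed-voxel matrix plus parcel table."""

    seed_matrix: np.ndarray  # subjects x seed voxels
    parcel_table: ParcelTable
    subjects: list[SubjectRecord]


def _cluster_shift(effects, group: str, cluster: int, k: int) -> float:
    e = effects.get(group, 0.0)
    if np.isscalar(e):
        return float(e)
    e = list(e)
    return float(e[(cluster - 1) % len(e)])


def generate_cohort(cfg: SyntheticConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one synthetic cohort under the latent-factor model."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.k_true

    # planted voxel labels: contiguous, near-equal blocks
    voxel_labels = 1 + (np.arange(cfg.n_seed_voxels) * k) // cfg.n_seed_voxels

    # disjoint parcel sets: each cluster gets n_parcels // (k + 1) parcels,
    # the remainder stays unassociated background
    per_cluster = cfg.n_parcels // (k + 1)
    cluster_parcel_map = {
        c: list(range((c - 1) * per_cluster, c * per_cluster)) for c in range(1, k + 1)
    }

    # diagnosis groups in declared proportions (order preserved)
    groups: list[str] = []
    items = list(cfg.group_fractions.items())
    for g, frac in items:
        groups.extend([g] * int(round(frac * cfg.n_subjects)))
    groups = groups[: cfg.n_subjects]
    while len(groups) < cfg.n_subjects:
        groups.append(items[-1][0])

    f = rng.standard_normal((cfg.n_subjects, k))  # latent factors

    seed_matrix = SEED_BASELINE + cfg.noise_sd * rng.standard_normal(
        (cfg.n_subjects, cfg.n_seed_voxels)
    )
    baseline = np.array([cfg.cluster_baseline[(c - 1) % len(cfg.cluster_baseline)]
                         for c in range(1, k + 1)])
    shift = np.array(
        [
            [_cluster_shift(cfg.group_effects, g, c, k) for c in range(1, k + 1)]
            for g in groups
        ]
    )
    seed_matrix += (baseline[None, :] + shift + cfg.loading * f)[:, voxel_labels - 1]

    parcel_values = PARCEL_BASELINE + cfg.noise_sd * rng.standard_normal(
        (cfg.n_subjects, cfg.n_parcels)
    )
    for c, parcels in cluster_parcel_map.items():
        parcel_values[:, parcels] += cfg.loading * f[:, [c - 1]]

    subjects, bm_status = [], []
    for i, g in enumerate(groups):
        bm = {
            m: max(float(rng.normal(*cfg.bm_params[g][m])), 1.0)
            for m in ("abeta", "p_tau", "t_tau")
        }
        rec = SubjectRecord(
            subject_id=f"sub-{i:04d}",
            group=g,
            native_voxel_size=(2.0, 2.0, 2.0),
            abeta_42=bm["abeta"],
            p_tau=bm["p_tau"],
            t_tau=bm["t_tau"],
        )
        rec.bm_status = classify_biomarker_status(rec)
        subjects.append(rec)
        bm_status.append(rec.bm_status)

    cohort = Cohort(
        seed_matrix=seed_matrix,
        parcel_table=ParcelTable(
            values=parcel_values,
            subject_ids=[r.subject_id for r in subjects],
            parcel_ids=list(range(cfg.n_parcels)),
        ),
        subjects=subjects,
    )
    truth = GroundTruth(
        voxel_labels=voxel_labels,
        cluster_parcel_map=cluster_parcel_map,
        groups=groups,
        bm_status=bm_status,
    )
    return cohort, truth


def generate_reference_maps(
    n_maps: int, n_regions: int, smoothness: int = 0, seed: int = 0, family: str = "term"
) -> list[ReferenceMap]:
    """Random region maps with controllable spatial autocorrelation.

    Each map is white noise moving-averaged over a chain of adjacent
    regions with half-width `smoothness` (0 = white noise); region ids are
    1..n_regions.  Deterministic under seed.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    rng = np.random.default_rng(seed)
    w = 2 * smoothness + 1
    kernel = np.ones(w) / w
    maps = []
    for i in range(n_maps):
        noise = rng.standard_normal(n_regions + w - 1)
        vals = np.convolve(noise, kernel, mode="valid")
        maps.append(
            ReferenceMap(
                values=pd.Series(vals, index=pd.RangeIndex(1, n_regions + 1)),
                name=f"{family}_map_{i}",
                family=family,
            )
        )
    return maps


def generate_donor_expression(
    n_donors: int = 6,
    n_regions: int = 30,
    n_probes: int = 40,
    n_genes: int = 20,
    gradient_genes: int | list[str] = 5,
    noise_sd: float = 0.2,
    n_unannotated: int = 2,
    n_dim_probes: int = 4,
    seed: int = 0,
) -> tuple[ProbeTable, dict[str, DonorExpression], pd.DataFrame, dict]:
    """Donor microarray tables with a planted spatial expression gradient.

    Gene symbols GENE0001.. are indexed by probes with multiplicity
    (round-robin probe -> gene map).  Designated gradient genes share a
    monotone regional gradient across all donors plus donor noise; other
    probes are donor-specific noise around a probe baseline.  The first
    `n_unannotated` probes lack a valid Entrez ID and `n_dim_probes`
    further probes sit below background in most samples, so the filtering
    steps have work to do.  One sample per region per donor, placed near
    the region centroid (left hemisphere, cortex/subcortex divisions).

    Returns (pooled ProbeTable, donor_id -> DonorExpression, region
    metadata, ground-truth dict).
    """
    if n_genes > n_probes:
        raise ValueError("n_genes > n_probes")
    rng = np.random.default_rng(seed)

    genes = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    probe_ids = [f"probe_{i:04d}" for i in range(1, n_probes + 1)]
    probe_gene = {p: genes[i % n_genes] for i, p in enumerate(probe_ids)}
    entrez = {p: (np.nan if i < n_unannotated else 1000 + i) for i, p in enumerate(probe_ids)}
    if isinstance(gradient_genes, int):
        grad_genes = genes[:gradient_genes]
    else:
        grad_genes = [g.strip().upper() for g in gradient_genes]
    # dim probes: pick from probes whose genes also have a bright probe
    dim = set(probe_ids[n_unannotated : n_unannotated + n_dim_probes])

    gradient = np.linspace(0.0, 1.0, n_regions)
    region_ids = pd.RangeIndex(1, n_regions + 1, name="region")
    region_meta = pd.DataFrame(
        {
            "x": -40.0 + 2.5 * np.arange(n_regions),
            "y": np.zeros(n_regions),
            "z": np.zeros(n_regions),
            "hemisphere": "L",
            "division": ["cortex"] * (2 * n_regions // 3)
            + ["subcortex/brainstem"] * (n_regions - 2 * n_regions // 3),
        },
        index=region_ids,
    )

    base = 6.0 + rng.uniform(0, 2.0, size=n_probes)  # log2-scale-like baseline
    background = 5.0
    donors: dict[str, DonorExpression] = {}
    intensity_blocks, flag_blocks = [], []
    for d in range(1, n_donors + 1):
        donor_id = f"donor{d:02d}"
        sample_ids = [f"{donor_id}_s{r:03d}" for r in region_ids]
        coords = region_meta[["x", "y", "z"]].to_numpy() + rng.normal(0, 0.3, (n_regions, 3))
        samples = pd.DataFrame(
            {
                "x": coords[:, 0],
                "y": coords[:, 1],
                "z": coords[:, 2],
                "hemisphere": "L",
                "division": region_meta["division"].to_numpy(),
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        expr = np.empty((n_regions, n_probes))
        for j, p in enumerate(probe_ids):
            level = base[j] - (2.5 if p in dim else 0.0)
            expr[:, j] = level + rng.normal(0, noise_sd, n_regions)
            if probe_gene[p] in grad_genes and p not in dim:
                expr[:, j] += 2.0 * gradient
        expression = pd.DataFrame(expr, index=samples.index, columns=probe_ids)
        donors[donor_id] = DonorExpression(
            donor_id=donor_id, samples=samples, expression=expression
        )
        intensity_blocks.append(expression)
        flag_blocks.append(expression > background)

    annotations = pd.DataFrame(
        {
            "gene_symbol": [probe_gene[p] for p in probe_ids],
            "entrez_id": [entrez[p] for p in probe_ids],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    probe_table = ProbeTable(
        annotations=annotations,
        intensity=pd.concat(intensity_blocks),
        above_background=pd.concat(flag_blocks),
    )
    truth = {
        "gradient_genes": grad_genes,
        "gradient": gradient,
        "dim_probes": sorted(dim),
        "unannotated_probes": probe_ids[:n_unannotated],
        "probe_gene": probe_gene,
    }
    return probe_table, donors, region_meta, truth
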