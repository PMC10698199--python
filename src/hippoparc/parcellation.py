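"""Covariance-based parcellation of the seed structure.

Seed voxels are clustered by the similarity of their Fisher-z co-metabolism
profiles (Euclidean k-means on matrix rows).  Robustness comes from a
subject-level bootstrap: each replicate's clustering is aligned to the
clustering of the non-resampled sample by optimal label assignment, and the
consensus parcellation takes the per-voxel modal label.  The number of
clusters is selected by split-half stability: subjects are split into
halves, the full covariance -> k-means -> consensus chain runs per half,
and the adjusted Rand index between half parcellations is averaged per k.

Label conventions: public labels are 1..k; ties in the mode go to the
smallest label id and ties in k-selection to the smallest k, so the whole
chain is deterministic under fixed seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from ._kmeans import batched_lloyd
from .covariance import CovarianceProfileMatrix, bootstrap_covariance, voxel_parcel_covariance
from .io import LabelAtlas, ParcelTable

__all__ = [
    "Parcellation",
    "StabilityCurve",
    "kmeans_profiles",
    "align_labels",
    "consensus_mode",
    "adjusted_rand_index",
    "bootstrap_consensus",
    "split_half_stability",
    "percent_overlap",
]


@dataclass
class Parcellation:
    """Cluster label (1..k) per seed voxel with provenance."""

    labels: np.ndarray
    k: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        if present.min() < 1 or present.max() > self.k:
            raise ValueError("labels must lie in 1..k")


@dataclass
class StabilityCurve:
    """Mean split-half ARI per candidate k and the selected k."""

    table: pd.DataFrame  # index k: mean_ari, sd_ari, n_splits
    selected_k: int


def kmeans_profiles(
    z: CovarianceProfileMatrix | np.ndarray,
    k: int,
    restarts: int = 500,
    max_iter: int = 255,
    seed: int = 0,
) -> np.ndarray:
    """Euclidean k-means on profile rows; best of `restarts` random inits.

    Defaults mirror the study protocol (500 repetitions, 255 iterations).
    Returns labels in 1..k, deterministic under `seed`.
    """
    X = z.z if isinstance(z, CovarianceProfileMatrix) else np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("profiles must be finite")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of voxels {X.shape[0]}")
    rng = np.random.default_rng(seed)
    labels, _ = batched_lloyd(X, k, restarts=restarts, max_iter=max_iter, rng=rng)
    return labels + 1


def align_labels(candidate: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Permute candidate labels to maximize agreement with the reference.

    Solves the assignment problem on the k x k contingency table
    (Hungarian algorithm), so the mode across bootstrap replicates is well
    defined.  Both label vectors must use 1..k with the same k.
    """
    candidate = np.asarray(candidate, dtype=np.int64)
    reference = np.asarray(reference, dtype=np.int64)
    if candidate.shape != reference.shape:
        raise ValueError("label vectors differ in length")
    k_c = candidate.max()
    k_r = reference.max()
    if k_c != k_r:
        raise ValueError(f"differing k: candidate {k_c}, reference {k_r}")
    k = int(k_c)
    cont = np.zeros((k, k), dtype=np.int64)
    np.add.at(cont, (candidate - 1, reference - 1), 1)
    rows, cols = linear_sum_assignment(-cont)
    perm = np.empty(k, dtype=np.int64)
    perm[rows] = cols
    return perm[candidate - 1] + 1


def consensus_mode(ensemble: list[np.ndarray] | np.ndarray, k: int | None = None) -> Parcellation:
    """Per-voxel modal label across aligned replicates; ties -> smallest id."""
    stack = np.asarray(ensemble, dtype=np.int64)
    if stack.ndim != 2 or stack.shape[0] == 0:
        raise ValueError("ensemble must be a nonempty list of label vectors")
    if k is None:
        k = int(stack.max())
    counts = np.zeros((stack.shape[1], k), dtype=np.int64)
    for row in stack:
        np.add.at(counts, (np.arange(stack.shape[1]), row - 1), 1)
    labels = counts.argmax(axis=1) + 1  # argmax takes the smallest index on ties
    return Parcellation(labels=labels, k=int(labels.max()), provenance={"n_members": len(stack)})


def adjusted_rand_index(a: np.ndarray, b: np.ndarray) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def bootstrap_consensus(
    seed_matrix: np.ndarray,
    parcel_table: ParcelTable,
    k: int,
    n_boot: int = 500,
    restarts: int = 500,
    max_iter: int = 255,
    seed: int = 0,
) -> Parcellation:
    """Full-chain consensus parcellation at a given k.

    The non-resampled sample's clustering is the alignment reference; each
    bootstrap replicate is clustered, aligned to it, and the per-voxel mode
    across replicates is the consensus.
    """
    ref_cov = voxel_parcel_covariance(seed_matrix, parcel_table)
    rng = np.random.default_rng(seed)
    ref_labels = kmeans_profiles(
        ref_cov, k, restarts=restarts, max_iter=max_iter, seed=int(rng.integers(2**31))
    )
    ensemble = bootstrap_covariance(
        seed_matrix, parcel_table, n_boot=n_boot, seed=int(rng.integers(2**31))
    )
    aligned = [
        align_labels(
            kmeans_profiles(m, k, restarts=restarts, max_iter=max_iter,
                            seed=int(rng.integers(2**31))),
            ref_labels,
        )
        for m in ensemble.matrices
    ]
    parc = consensus_mode(aligned, k=k)
    parc.provenance.update({"k": k, "n_boot": n_boot, "restarts": restarts, "seed": seed})
    return parc


def split_half_stability(
    seed_matrix: np.ndarray,
    parcel_table: ParcelTable,
    ks: list[int] = (2, 3, 4, 5, 6),
    n_splits: int = 10_000,
    n_boot_per_half: int = 50,
    restarts: int = 10,
    max_iter: int = 255,
    seed: int = 0,
) -> StabilityCurve:
    """Select k by split-half reproducibility of the consensus parcellation.

    For each split, subjects are randomly divided into two halves; the
    bootstrap-consensus chain runs per half at every candidate k, and the
    ARI between the two half parcellations is recorded.  The curve is the
    mean ARI per k; selected_k is its argmax (ties -> smaller k).  Each
    half uses a reduced bootstrap (`n_boot_per_half`) and `restarts`
    k-means initializations for tractability.
    """
    seed_matrix = np.asarray(seed_matrix, dtype=np.float64)
    n = seed_matrix.shape[0]
    if n < 6:
        raise ValueError("need at least 6 subjects for split-half stability")
    ks = sorted(int(k) for k in ks)
    if not ks:
        raise ValueError("ks must be nonempty")
    rng = np.random.default_rng(seed)
    ari = np.zeros((len(ks), n_splits))
    values = parcel_table.values
    for s in range(n_splits):
        perm = rng.permutation(n)
        halves = (perm[: n // 2], perm[n // 2 :])
        if min(len(h) for h in halves) < 3:
            raise ValueError("half too small for covariance (< 3 subjects)")
        half_labels: list[dict[int, np.ndarray]] = []
        for h in halves:
            sub_table = ParcelTable(
                values=values[h],
                subject_ids=[parcel_table.subject_ids[i] for i in h],
                parcel_ids=parcel_table.parcel_ids,
            )
            half_labels.append(
                _consensus_all_k(
                    seed_matrix[h], sub_table, ks, n_boot_per_half, restarts, max_iter, rng
                )
            )
        for j, k in enumerate(ks):
            ari[j, s] = adjusted_rand_index(half_labels[0][k], half_labels[1][k])
    table = pd.DataFrame(
        {
            "mean_ari": ari.mean(axis=1),
            "sd_ari": ari.std(axis=1, ddof=1) if n_splits > 1 else np.zeros(len(ks)),
            "n_splits": n_splits,
        },
        index=pd.Index(ks, name="k"),
    )
    selected_k = int(table.index[int(np.argmax(table["mean_ari"].to_numpy()))])
    return StabilityCurve(table=table, selected_k=selected_k)


def _consensus_all_k(
    seed_matrix: np.ndarray,
    parcel_table: ParcelTable,
    ks: list[int],
    n_boot: int,
    restarts: int,
    max_iter: int,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Bootstrap-consensus labels for every k, reusing one covariance ensemble."""
    ref_cov = voxel_parcel_covariance(seed_matrix, parcel_table)
    ensemble = bootstrap_covariance(
        seed_matrix, parcel_table, n_boot=n_boot, seed=int(rng.integers(2**31))
    )
    out: dict[int, np.ndarray] = {}
    for k in ks:
        ref_labels = kmeans_profiles(
            ref_cov, k, restarts=restarts, max_iter=max_iter, seed=int(rng.integers(2**31))
        )
        aligned = [
            align_labels(
                kmeans_profiles(m, k, restarts=restarts, max_iter=max_iter,
                                seed=int(rng.integers(2**31))),
                ref_labels,
            )
            for m in ensemble.matrices
        ]
        out[k] = consensus_mode(aligned, k=k).labels
    return out


def percent_overlap(
    parc: Parcellation, voxel_reference_labels: np.ndarray, reference_names: dict | None = None
) -> pd.DataFrame:
    """Percent overlap of each metabolic subregion with each reference field.

    Entry (s, f) = 100 * |voxels in subregion s and field f| / |subregion s|.
    `voxel_reference_labels` gives the reference field id per seed voxel
    (0 = unlabeled); rows sum to <= 100 when fields are disjoint.
    """
    ref = np.asarray(voxel_reference_labels, dtype=np.int64)
    if ref.shape != parc.labels.shape:
        raise ValueError("geometry mismatch: reference labeling length differs")
    fields = np.unique(ref[ref > 0])
    rows = {}
    for s in range(1, parc.k + 1):
        in_s = parc.labels == s
        denom = in_s.sum()
        rows[s] = {
            (reference_names or {}).get(f, f): 100.0 * np.sum(in_s & (ref == f)) / denom
            for f in fields
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subregion"
    return out


def percent_overlap_atlas(
    parc_grid: np.ndarray, parc_affine: np.ndarray, reference: LabelAtlas, k: int
) -> pd.DataFrame:
    """Volume-based variant of percent_overlap for parcellation stored as a grid."""
    if parc_grid.shape != reference.grid.shape or not np.allclose(parc_affine, reference.affine):
        raise ValueError("geometry mismatch: parcellation vs reference atlas")
    voxels = parc_grid > 0
    parc = Parcellation(labels=parc_grid[voxels], k=k)
    names = reference.label_table["name"].to_dict() if "name" in reference.label_table else None
    return percent_overlap(parc, reference.grid[voxels], names)
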