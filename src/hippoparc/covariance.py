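"""Seed-voxel x parcel co-metabolism profiles.

Across a subject sample, each seed voxel's uptake series is correlated
with every parcel's mean-uptake series (Pearson), then Fisher
z-transformed.  Correlations are clipped to +/-(1 - 1e-7) before arctanh
so that perfectly collinear pairs stay finite and usable as k-means
features.  A subject-level bootstrap (resampling subjects with
replacement) yields an ensemble of profile matrices for consensus
clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ParcelTable

__all__ = [
    "R_CLIP",
    "CovarianceProfileMatrix",
    "BootstrapEnsemble",
    "fisher_z",
    "voxel_parcel_covariance",
    "bootstrap_covariance",
]

logger = logging.getLogger(__name__)

#: correlations are clipped to +/- R_CLIP before the z transform
R_CLIP = 1.0 - 1e-7


@dataclass
class CovarianceProfileMatrix:
    """V x P matrix of Fisher-z voxel-parcel correlations."""

    z: np.ndarray
    voxel_index: np.ndarray
    parcel_ids: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.float64)
        self.voxel_index = np.asarray(self.voxel_index)
        self.parcel_ids = np.asarray(self.parcel_ids)
        if self.z.shape != (len(self.voxel_index), len(self.parcel_ids)):
            raise ValueError("z shape does not match voxel/parcel ids")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite z entries")


@dataclass
class BootstrapEnsemble:
    """Bootstrap replicates of the covariance profile matrix."""

    matrices: list[CovarianceProfileMatrix]
    subject_draws: list[np.ndarray]
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if len(self.matrices) != self.n_boot or len(self.subject_draws) != self.n_boot:
            raise ValueError("ensemble length does not match n_boot")


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilizing Fisher transform arctanh(r), clipped at |r| = 1.

    Monotone and odd; r = +/-1 maps to the finite arctanh(+/-(1 - 1e-7)).
    """
    r_arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    z = np.arctanh(np.clip(r_arr, -R_CLIP, R_CLIP))
    return float(z) if np.isscalar(r) else z


def _standardize_columns(X: np.ndarray, what: str, ids) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    bad = ~(sd > 0) | ~np.isfinite(sd)
    if bad.any():
        offenders = [x.item() if hasattr(x, "item") else x for x in np.asarray(ids)[bad][:20]]
        raise ValueError(f"zero-variance {what} columns: {offenders}")
    return (X - mu) / sd


def voxel_parcel_covariance(
    seed_matrix: np.ndarray,
    parcel_table: ParcelTable,
    voxel_index: np.ndarray | None = None,
) -> CovarianceProfileMatrix:
    """Fisher-z Pearson correlation of every seed voxel with every parcel.

    seed_matrix is subjects x V (same subject order as parcel_table).
    Zero-variance voxels or parcels raise, listing the offending ids: the
    caller masks or drops them explicitly rather than receiving NaNs.
    """
    seed_matrix = np.asarray(seed_matrix, dtype=np.float64)
    n, V = seed_matrix.shape
    if parcel_table.values.shape[0] != n:
        raise ValueError("subject count mismatch between seed matrix and parcel table")
    if n < 3:
        raise ValueError("need at least 3 subjects for correlation")
    if voxel_index is None:
        voxel_index = np.arange(V)
    Xs = _standardize_columns(seed_matrix, "seed voxel", voxel_index)
    Ys = _standardize_columns(parcel_table.values, "parcel", parcel_table.parcel_ids)
    r = (Xs.T @ Ys) / (n - 1)
    # numerical guard: |r| can exceed 1 by rounding
    np.clip(r, -1.0, 1.0, out=r)
    return CovarianceProfileMatrix(
        z=fisher_z(r),
        voxel_index=np.asarray(voxel_index),
        parcel_ids=np.asarray(parcel_table.parcel_ids),
        n_subjects=n,
    )


def bootstrap_covariance(
    seed_matrix: np.ndarray,
    parcel_table: ParcelTable,
    n_boot: int = 500,
    seed: int = 0,
    _draws: list[np.ndarray] | None = None,
) -> BootstrapEnsemble:
    """Subject-level bootstrap of the covariance profile matrix.

    Each replicate resamples subjects with replacement and recomputes the
    full profile matrix.  Deterministic under `seed`.  A replicate whose
    resample makes some columns degenerate (constant) has those columns'
    z set to 0 with a logged warning, keeping matrix shapes aligned across
    the ensemble.  `_draws` is a test hook forcing specific resamples.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    seed_matrix = np.asarray(seed_matrix, dtype=np.float64)
    n = seed_matrix.shape[0]
    rng = np.random.default_rng(seed)
    matrices: list[CovarianceProfileMatrix] = []
    draws: list[np.ndarray] = []
    for b in range(n_boot):
        idx = _draws[b] if _draws is not None else rng.integers(0, n, size=n)
        idx = np.asarray(idx)
        sub_table = ParcelTable(
            values=parcel_table.values[idx],
            subject_ids=[parcel_table.subject_ids[i] for i in idx],
            parcel_ids=parcel_table.parcel_ids,
        )
        try:
            mat = voxel_parcel_covariance(seed_matrix[idx], sub_table)
        except ValueError:
            mat = _covariance_dropping_degenerate(seed_matrix[idx], sub_table, b)
        matrices.append(mat)
        draws.append(idx)
    return BootstrapEnsemble(matrices=matrices, subject_draws=draws, n_boot=n_boot, seed=seed)


def _covariance_dropping_degenerate(
    seed_matrix: np.ndarray, parcel_table: ParcelTable, replicate: int
) -> CovarianceProfileMatrix:
    """Replicate-level fallback: zero out z for degenerate columns."""
    sd_v = seed_matrix.std(axis=0, ddof=1)
    sd_p = parcel_table.values.std(axis=0, ddof=1)
    ok_v, ok_p = sd_v > 0, sd_p > 0
    logger.warning(
        "bootstrap replicate %d: %d degenerate voxel / %d parcel columns zeroed",
        replicate,
        int((~ok_v).sum()),
        int((~ok_p).sum()),
    )
    n, V = seed_matrix.shape
    P = parcel_table.values.shape[1]
    z = np.zeros((V, P))
    if ok_v.any() and ok_p.any():
        Xs = (seed_matrix[:, ok_v] - seed_matrix[:, ok_v].mean(0)) / sd_v[ok_v]
        Ys = (parcel_table.values[:, ok_p] - parcel_table.values[:, ok_p].mean(0)) / sd_p[ok_p]
        r = np.clip((Xs.T @ Ys) / (n - 1), -1.0, 1.0)
        z[np.ix_(ok_v, ok_p)] = fisher_z(r)
    return CovarianceProfileMatrix(
        z=z,
        voxel_index=np.arange(V),
        parcel_ids=np.asarray(parcel_table.parcel_ids),
        n_subjects=n,
    )
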