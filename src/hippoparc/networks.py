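"""Seed-GLM metabolic covariance networks.

For one parcellation subregion, each brain parcel's mean uptake is
regressed (OLS) on the subregion's mean uptake across subjects, optionally
with nuisance covariates.  The per-parcel T statistic of the seed slope,
its two-sided p, and Benjamini-Hochberg q values form the network map.
With no covariates the T statistic equals the textbook correlation t,
T = r * sqrt((n - 2) / (1 - r^2)).

The unthresholded T map is always retained — downstream spatial
association consumes it regardless of which parcels pass FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["NetworkMap", "seed_glm", "fdr_select"]


@dataclass
class NetworkMap:
    """Per-parcel slope/T/p/q statistics for one seed subregion."""

    table: pd.DataFrame  # index parcel_id: slope, T, p, q
    seed_subregion: int
    n_subjects: int
    covariates: list[str] = field(default_factory=list)

    @property
    def t_map(self) -> pd.Series:
        return self.table["T"]


def seed_glm(
    parcel_table,
    seed_means: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    seed_subregion: int = 0,
) -> NetworkMap:
    """OLS of every parcel's uptake on the seed subregion's mean uptake.

    parcel_table: ParcelTable (subjects x parcels), subject order aligned
    with seed_means.  covariates: optional subjects x c nuisance matrix.
    All parcels are fit in one vectorized pass.
    """
    Y = np.asarray(parcel_table.values, dtype=np.float64)
    x = np.asarray(seed_means, dtype=np.float64).ravel()
    n = x.shape[0]
    if Y.shape[0] != n:
        raise ValueError("subject count mismatch between seed means and parcel table")
    cols = [np.ones(n), x]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if C.shape[0] != n:
            C = C.T
        cols.extend(C.T)
    D = np.column_stack(cols)
    p_params = D.shape[1]
    if n < p_params + 2:
        raise ValueError("too few subjects for the design")
    if np.linalg.matrix_rank(D) < p_params:
        raise ValueError("rank-deficient design")

    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ D.T @ Y  # (p_params, P)
    resid = Y - D @ beta
    dof = n - p_params
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * DtD_inv[1, 1], 1e-300))
    T = beta[1] / se
    p = 2.0 * sps.t.sf(np.abs(T), dof)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame(
        {"slope": beta[1], "T": T, "p": p, "q": q},
        index=pd.Index(parcel_table.parcel_ids, name="parcel_id"),
    )
    return NetworkMap(
        table=table,
        seed_subregion=seed_subregion,
        n_subjects=n,
        covariates=list(covariate_names or []),
    )


def fdr_select(network: NetworkMap, q_level: float = 0.05) -> list:
    """Parcels significant under Benjamini-Hochberg FDR at q_level."""
    p = network.table["p"].to_numpy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values outside [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return list(network.table.index[reject])
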