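"""Spatial association of network maps with reference maps.

Network T maps and reference maps (behavioral term maps, receptor or
transporter density maps, gene-set expression maps) are compared at the
atlas-region level: Pearson correlation, optionally partialling out a
shared spatial confound (e.g. a gray-matter probability map), Fisher
z-transformed, and tested against a permutation null.  The null can
either shuffle region values freely or preserve the map's spatial
autocorrelation by keeping only candidate permutations whose empirical
variogram best matches the original's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .covariance import fisher_z
from .io import LabelAtlas, UptakeVolume

__all__ = [
    "ReferenceMap",
    "AssociationResult",
    "extract_region_values",
    "partial_spatial_correlation",
    "decode_terms",
    "build_null",
    "association_test",
]


@dataclass
class ReferenceMap:
    """One scalar per atlas region, with name, family and exclusions."""

    values: pd.Series  # index region_id
    name: str = ""
    family: str = "term"  # term | receptor | geneset
    excluded_regions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.size < 3:
            raise ValueError("need >= 3 usable regions")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("non-finite region values")


@dataclass
class AssociationResult:
    """Per reference map: r, Fisher z, t-test p, BH q, null summary."""

    table: pd.DataFrame  # index map name: r, z, p, q, p_perm, n_regions
    n_perm: int
    null_mode: str


def _common(x: ReferenceMap, y: ReferenceMap) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    idx = x.values.index.intersection(y.values.index)
    excl = set(x.excluded_regions) | set(y.excluded_regions)
    idx = pd.Index([i for i in idx if i not in excl])
    return x.values.loc[idx].to_numpy(), y.values.loc[idx].to_numpy(), idx


def extract_region_values(
    voxel_map: UptakeVolume | np.ndarray,
    anatomy: LabelAtlas,
    exclude: list | None = None,
    name: str = "",
    family: str = "term",
) -> ReferenceMap:
    """Mean of a voxel map within each retained atlas region.

    Regions in `exclude` (e.g. white matter, CSF) are dropped; regions
    with no voxels are excluded with a warning flag in excluded_regions.
    """
    if isinstance(voxel_map, UptakeVolume):
        grid = voxel_map.grid
        if grid.shape != anatomy.grid.shape or not np.allclose(voxel_map.affine, anatomy.affine):
            raise ValueError("geometry mismatch: map vs anatomy atlas")
    else:
        grid = np.asarray(voxel_map, dtype=np.float64)
        if grid.shape != anatomy.grid.shape:
            raise ValueError("geometry mismatch: map vs anatomy atlas")
    exclude = set(exclude or [])
    labels = anatomy.grid.ravel()
    vals = grid.ravel()
    nz = labels > 0
    # table may list regions absent from the grid; size bins for both
    minlength = int(max(labels.max(), max(anatomy.label_table.index, default=0))) + 1
    counts = np.bincount(labels[nz], minlength=minlength)
    sums = np.bincount(labels[nz], weights=vals[nz], minlength=minlength)
    region_ids = [r for r in sorted(anatomy.label_table.index) if r not in exclude]
    values, dropped = {}, []
    for r in region_ids:
        if counts[r] > 0:
            values[r] = sums[r] / counts[r]
        else:
            dropped.append(r)
    return ReferenceMap(
        values=pd.Series(values), name=name, family=family, excluded_regions=sorted(exclude) + dropped
    )


def partial_spatial_correlation(
    x: ReferenceMap, y: ReferenceMap, covar: ReferenceMap | None = None
) -> float:
    """Pearson correlation of x and y after both are residualized on covar.

    Each map is regressed on covar plus an intercept and the residuals are
    correlated — the standard partial correlation, removing a shared
    spatial confound.  A constant covar falls back to the plain
    correlation with a warning.
    """
    xv, yv, idx = _common(x, y)
    if covar is None:
        return float(sps.pearsonr(xv, yv).statistic)
    cv = covar.values.reindex(idx)
    if cv.isna().any():
        raise ValueError("covariate missing regions in the common set")
    cv = cv.to_numpy()
    if idx.size < 4:
        raise ValueError("need >= 4 common regions for partial correlation")
    if np.ptp(cv) == 0:
        import warnings

        warnings.warn("constant covariate: falling back to plain correlation", stacklevel=2)
        return float(sps.pearsonr(xv, yv).statistic)
    D = np.column_stack([np.ones_like(cv), cv])
    H = D @ np.linalg.inv(D.T @ D) @ D.T
    rx = xv - H @ xv
    ry = yv - H @ yv
    # a map collinear with the covariate leaves no residual signal
    if np.std(rx) <= 1e-10 * max(np.std(xv), 1e-300) or np.std(ry) <= 1e-10 * max(
        np.std(yv), 1e-300
    ):
        return 0.0
    return float(sps.pearsonr(rx, ry).statistic)


def decode_terms(
    query: ReferenceMap, term_maps: list[ReferenceMap], threshold: float = 0.1
) -> list[tuple[str, float]]:
    """Correlate a network map with every term map; keep r > threshold.

    Returns (term name, r) pairs sorted by descending r — the broad
    behavioral profile of a network rather than a significance test.
    """
    out = []
    for tm in term_maps:
        xv, yv, _ = _common(query, tm)
        r = float(sps.pearsonr(xv, yv).statistic)
        if r > threshold:
            out.append((tm.name, r))
    return sorted(out, key=lambda t: -t[1])


def _variogram(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Mean squared difference per index-distance bin along the region order."""
    v = np.empty(max_lag)
    for i, lag in enumerate(range(1, max_lag + 1)):
        d = values[lag:] - values[:-lag]
        v[i] = np.mean(d * d)
    return v


def build_null(
    ref: ReferenceMap,
    n_perm: int = 1000,
    mode: str = "shuffle",
    seed: int = 0,
    n_candidates: int = 20,
) -> list[ReferenceMap]:
    """Permutation null ensemble for a reference map.

    mode "shuffle": unconstrained random permutations of region values.
    mode "autocorr_preserving": for each draw, `n_candidates` candidate
    permutations are scored by the distance between their empirical
    variogram (over the region ordering, which indexes spatial adjacency
    for chain-structured synthetic maps) and the original's; the best
    candidate is kept.  Values are permuted, never altered, so every null
    map preserves the exact multiset of values.  Deterministic under seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if mode not in ("shuffle", "autocorr_preserving"):
        raise ValueError(f"unknown null mode {mode!r}")
    rng = np.random.default_rng(seed)
    vals = ref.values.to_numpy()
    n = vals.size
    max_lag = min(10, n - 1)
    target = _variogram(vals, max_lag) if mode == "autocorr_preserving" else None
    nulls = []
    for i in range(n_perm):
        if mode == "shuffle":
            perm_vals = vals[rng.permutation(n)]
        else:
            best, best_score = None, np.inf
            for _ in range(n_candidates):
                cand = vals[rng.permutation(n)]
                score = float(np.sum((_variogram(cand, max_lag) - target) ** 2))
                if score < best_score:
                    best, best_score = cand, score
            perm_vals = best
        nulls.append(
            ReferenceMap(
                values=pd.Series(perm_vals, index=ref.values.index),
                name=f"{ref.name}_null{i}",
                family=ref.family,
            )
        )
    return nulls


def association_test(
    observed_z: dict[str, np.ndarray],
    null_z: dict[str, np.ndarray],
    q_level: float = 0.05,
) -> AssociationResult:
    """Test observed Fisher-z correlations against their null ensembles.

    For each reference map, the observed z values (e.g. one per
    hemisphere's seed map) are tested against the null-ensemble mean with
    a one-sample t-test; a two-sided permutation-tail p on the mean z is
    reported alongside for transparency, and is the primary p when only a
    single observed z exists (zero-variance t is undefined).  BH-FDR is
    applied across reference maps.
    """
    if not observed_z:
        raise ValueError("observed set is empty")
    rows = {}
    for name, obs in observed_z.items():
        obs = np.atleast_1d(np.asarray(obs, dtype=np.float64))
        null = np.asarray(null_z.get(name, []), dtype=np.float64)
        if null.size == 0:
            raise ValueError(f"empty null ensemble for map {name!r}")
        null_mean = float(null.mean())
        mean_obs = float(obs.mean())
        # permutation tail: how extreme is the observed mean z under the null
        tail = (np.sum(np.abs(null - null_mean) >= abs(mean_obs - null_mean)) + 1) / (
            null.size + 1
        )
        if obs.size > 1 and obs.std(ddof=1) > 0:
            t, p = sps.ttest_1samp(obs, popmean=null_mean)
        else:
            p = tail
        rows[name] = {
            "z": mean_obs,
            "r": float(np.tanh(mean_obs)),
            "p": float(p),
            "p_perm": float(tail),
            "null_mean": null_mean,
            "null_sd": float(null.std(ddof=1)) if null.size > 1 else 0.0,
            "n_obs": obs.size,
            "n_perm": null.size,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    _, q, _, _ = multipletests(table["p"].to_numpy(), alpha=q_level, method="fdr_bh")
    table["q"] = q
    table["significant"] = table["q"] < q_level
    return AssociationResult(table=table, n_perm=int(table["n_perm"].max()), null_mode="given")


def zmap_correlations(
    query: ReferenceMap,
    references: list[ReferenceMap],
    covar: ReferenceMap | None = None,
) -> dict[str, float]:
    """Fisher-z (partial) correlation of a query map with each reference."""
    return {
        ref.name: fisher_z(partial_spatial_correlation(query, ref, covar)) for ref in references
    }
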