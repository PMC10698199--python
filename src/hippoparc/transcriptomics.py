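"""Region x gene expression matrices from donor microarray tables.

The chain mirrors standard processing of donor brain microarray data:
probes are re-annotated and those without a valid Entrez ID discarded;
probes below background intensity in at least half of all pooled samples
are dropped; where several probes index one gene, the probe with the
highest differential stability (mean pairwise Spearman correlation of its
regional pattern across donors) is kept; samples are assigned to the
nearest atlas region constrained by hemisphere and gross division, with
distance outliers removed; expression is normalized with a robust sigmoid
(median / normalized IQR) and rescaled to the unit interval, first across
genes within each sample and then across samples within each gene; and
samples are averaged within regions per donor, then across donors.
Gene-set expression maps average the normalized columns of the genes in a
set (e.g. a GO list intersected with a differential-expression list).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .assoc import ReferenceMap

__all__ = [
    "ProbeTable",
    "DonorExpression",
    "RegionExpressionMatrix",
    "GeneSet",
    "IQR_NORMAL_DIVISOR",
    "drop_unannotated_probes",
    "intensity_filter",
    "differential_stability",
    "differential_stability_scores",
    "select_probe_per_gene",
    "assign_samples",
    "fill_missing_regions",
    "robust_sigmoid",
    "rescale_unit",
    "normalize_matrix",
    "aggregate_regions",
    "intersect_genesets",
    "geneset_expression_map",
]

logger = logging.getLogger(__name__)

#: normal-consistent IQR scale: IQR of a standard normal is ~1.349 sigma
IQR_NORMAL_DIVISOR = 1.349

DIVISIONS = ("cortex", "subcortex/brainstem", "cerebellum")


@dataclass
class ProbeTable:
    """Probe annotations plus pooled (all-donor) intensities and flags."""

    annotations: pd.DataFrame  # index probe_id: gene_symbol, entrez_id (nullable)
    intensity: pd.DataFrame  # pooled samples x probes
    above_background: pd.DataFrame  # bool, same shape as intensity

    def __post_init__(self) -> None:
        if list(self.intensity.columns) != list(self.annotations.index):
            raise ValueError("intensity columns must match annotation probe ids")
        if self.above_background.shape != self.intensity.shape:
            raise ValueError("background flags must match intensity shape")

    def subset(self, probe_ids: pd.Index) -> "ProbeTable":
        return ProbeTable(
            annotations=self.annotations.loc[probe_ids],
            intensity=self.intensity[probe_ids],
            above_background=self.above_background[probe_ids],
        )


@dataclass
class DonorExpression:
    """One donor's samples (world coordinates, mm) and expression matrix."""

    donor_id: str
    samples: pd.DataFrame  # index sample_id: x, y, z, hemisphere, division
    expression: pd.DataFrame  # samples x probes

    def __post_init__(self) -> None:
        bad = set(self.samples["division"]) - set(DIVISIONS)
        if bad:
            raise ValueError(f"unknown gross divisions: {sorted(bad)}")
        if not np.all(np.isfinite(self.samples[["x", "y", "z"]].to_numpy())):
            raise ValueError("non-finite sample coordinates")
        if list(self.expression.index) != list(self.samples.index):
            raise ValueError("expression rows must match sample ids")


@dataclass
class RegionExpressionMatrix:
    """Regions x genes normalized expression, donor-aggregated."""

    values: pd.DataFrame  # index region_id, columns gene symbols, in [0, 1]
    donors_used: list[str] = field(default_factory=list)
    imputed_regions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9:
            raise ValueError("normalized expression must lie in [0, 1]")


@dataclass
class GeneSet:
    """Named gene list, e.g. a GO category intersected with a DE list."""

    set_id: str
    genes: list[str]
    provenance: str = ""
    empty: bool = False


def _norm_symbol(g: str) -> str:
    return str(g).strip().upper()


# ---------------------------------------------------------------------------
# Probe filtering and selection


def drop_unannotated_probes(pt: ProbeTable) -> ProbeTable:
    """Discard probes without a valid (positive integer) Entrez ID."""
    ent = pd.to_numeric(pt.annotations["entrez_id"], errors="coerce")
    keep = pt.annotations.index[ent.notna() & (ent > 0)]
    if keep.empty:
        raise ValueError("all probes lack a valid Entrez ID")
    return pt.subset(keep)


def intensity_filter(pt: ProbeTable, frac: float = 0.5) -> ProbeTable:
    """Keep probes above background in more than (1 - frac) of pooled samples.

    A probe below background in >= frac of all samples across donors is
    discarded — a probe at exactly the threshold goes.
    """
    below = ~pt.above_background
    frac_below = below.mean(axis=0)
    keep = pt.annotations.index[(frac_below < frac).to_numpy()]
    return pt.subset(keep)


def differential_stability(per_donor: dict[str, pd.Series]) -> float:
    """Mean pairwise Spearman correlation of one probe's regional pattern.

    `per_donor` maps donor id -> Series of regional expression (index
    region).  Every donor pair is correlated on the regions present in
    both; the score is the mean over all N(N-1)/2 pairs.
    """
    donors = sorted(per_donor)
    if len(donors) < 2:
        raise ValueError("need >= 2 donors")
    rhos = []
    for a, b in combinations(donors, 2):
        common = per_donor[a].index.intersection(per_donor[b].index)
        if common.size < 3:
            raise ValueError(f"donors {a}, {b} share < 3 regions")
        rho = sps.spearmanr(per_donor[a].loc[common], per_donor[b].loc[common]).statistic
        rhos.append(rho)
    return float(np.mean(rhos))


def differential_stability_scores(
    regional: dict[str, pd.DataFrame]
) -> pd.Series:
    """Differential stability for every probe column of per-donor matrices.

    `regional` maps donor id -> regions x probes matrix.  Pairs are rank-
    correlated on their common regions in one vectorized pass per pair.
    """
    donors = sorted(regional)
    if len(donors) < 2:
        raise ValueError("need >= 2 donors")
    probes = regional[donors[0]].columns
    acc = np.zeros(len(probes))
    n_pairs = 0
    for a, b in combinations(donors, 2):
        common = regional[a].index.intersection(regional[b].index)
        if common.size < 3:
            raise ValueError(f"donors {a}, {b} share < 3 regions")
        ra = regional[a].loc[common, probes].rank().to_numpy()
        rb = regional[b].loc[common, probes].rank().to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            # constant columns (no regional variation) get NaN stability
            ra = (ra - ra.mean(0)) / ra.std(0)
            rb = (rb - rb.mean(0)) / rb.std(0)
        acc += (ra * rb).mean(axis=0)
        n_pairs += 1
    return pd.Series(acc / n_pairs, index=probes, name="ds")


def select_probe_per_gene(scores: pd.Series, pt: ProbeTable) -> dict[str, str]:
    """Per gene, keep the probe with maximal differential stability.

    Ties break to the lexicographically smallest probe id; genes with no
    surviving probe are excluded with a warning.
    """
    genes = pt.annotations["gene_symbol"].map(_norm_symbol)
    chosen: dict[str, str] = {}
    for gene, grp in genes.groupby(genes):
        probe_ids = sorted(grp.index)
        sub = scores.reindex(probe_ids)
        if sub.isna().all():
            logger.warning("gene %s has no scored probes; excluded", gene)
            continue
        best = sub.max()
        chosen[gene] = min(p for p in probe_ids if sub[p] == best)
    return chosen


# ---------------------------------------------------------------------------
# Sample-to-region assignment


def assign_samples(
    donor: DonorExpression,
    region_meta: pd.DataFrame,
    sd_cut: float = 2.0,
) -> pd.DataFrame:
    """Assign each donor sample to its nearest compatible atlas region.

    region_meta is indexed by region id with columns x, y, z (centroid,
    mm), hemisphere, division.  A sample may only be assigned to a region
    of the same hemisphere and gross division; samples whose distance
    exceeds the donor mean + sd_cut * SD are removed; samples with no
    candidate region are left unassigned (region = -1) and logged.
    Returns a per-sample table: region, distance, kept.
    """
    need = {"x", "y", "z", "hemisphere", "division"}
    if not need <= set(region_meta.columns):
        raise ValueError(f"region metadata missing columns: {sorted(need - set(region_meta.columns))}")
    rows = []
    cent = region_meta[["x", "y", "z"]].to_numpy()
    for sid, s in donor.samples.iterrows():
        ok = (region_meta["hemisphere"] == s["hemisphere"]) & (
            region_meta["division"] == s["division"]
        )
        if not ok.any():
            logger.warning("sample %s of donor %s has no candidate region", sid, donor.donor_id)
            rows.append({"sample_id": sid, "region": -1, "distance": np.nan})
            continue
        d = np.linalg.norm(cent[ok.to_numpy()] - s[["x", "y", "z"]].to_numpy(float), axis=1)
        j = int(np.argmin(d))
        rows.append(
            {
                "sample_id": sid,
                "region": region_meta.index[ok.to_numpy()][j],
                "distance": float(d[j]),
            }
        )
    out = pd.DataFrame(rows).set_index("sample_id")
    assigned = out["region"] != -1
    d = out.loc[assigned, "distance"]
    cut = d.mean() + sd_cut * d.std(ddof=1) if len(d) > 1 else np.inf
    out["kept"] = assigned & (out["distance"] <= cut)
    return out


def fill_missing_regions(
    assignments: dict[str, pd.DataFrame],
    donors: dict[str, DonorExpression],
    region_meta: pd.DataFrame,
    normalized: dict[str, pd.DataFrame],
) -> tuple[dict[int, pd.Series], list]:
    """Estimate expression for regions with no assigned sample in any donor.

    For each such region, the nearest sample to the region centroid is
    found independently per donor and their (normalized) expression rows
    are averaged with inverse-distance weights.  Returns (region ->
    expression Series over genes, list of imputed region ids); regions
    remain missing only if no donor has samples at all.
    """
    assigned_regions = set()
    for a in assignments.values():
        assigned_regions |= set(a.loc[a["kept"], "region"])
    missing = [r for r in region_meta.index if r not in assigned_regions]
    filled: dict[int, pd.Series] = {}
    for r in missing:
        c = region_meta.loc[r, ["x", "y", "z"]].to_numpy(float)
        vals, weights = [], []
        for donor_id, donor in donors.items():
            if donor.samples.empty:
                continue
            d = np.linalg.norm(donor.samples[["x", "y", "z"]].to_numpy(float) - c, axis=1)
            j = int(np.argmin(d))
            sid = donor.samples.index[j]
            vals.append(normalized[donor_id].loc[sid])
            weights.append(1.0 / max(d[j], 1e-12))
        if not vals:
            continue
        w = np.asarray(weights)
        filled[r] = pd.concat(vals, axis=1).to_numpy() @ (w / w.sum())
        filled[r] = pd.Series(filled[r], index=vals[0].index)
    return filled, sorted(filled)


# ---------------------------------------------------------------------------
# Normalization


def robust_sigmoid(x: np.ndarray, iqr_divisor: float = IQR_NORMAL_DIVISOR) -> np.ndarray:
    """Outlier-resistant logistic scaling around the median.

    x_norm = 1 / (1 + exp(-(x - median) / (IQR / iqr_divisor))).  Monotone
    nondecreasing and bounded in (0, 1); a zero IQR yields the constant 0.5
    (degenerate vector).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty vector")
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr_n = (q75 - q25) / iqr_divisor
    if iqr_n <= 0:
        return np.full_like(x, 0.5)
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(-(x - med) / iqr_n))
    # keep the open (0, 1) bound even when the exponent overflows
    return np.clip(out, np.finfo(float).tiny, 1.0 - np.finfo(float).epsneg)


def rescale_unit(x_norm: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant vector maps to all 0.5."""
    x_norm = np.asarray(x_norm, dtype=np.float64)
    lo, hi = x_norm.min(), x_norm.max()
    if hi == lo:
        return np.full_like(x_norm, 0.5)
    return (x_norm - lo) / (hi - lo)


def _sigmoid_rescale(x: np.ndarray, iqr_divisor: float) -> np.ndarray:
    return rescale_unit(robust_sigmoid(x, iqr_divisor))


def normalize_matrix(
    mat: pd.DataFrame, iqr_divisor: float = IQR_NORMAL_DIVISOR
) -> pd.DataFrame:
    """Robust-sigmoid + unit rescale, across genes then across samples.

    First pass normalizes each sample's row across genes (inter-sample
    scale differences); second pass normalizes each gene's column across
    samples.  Output is bounded in [0, 1] and invariant to positive affine
    rescaling of the raw input.
    """
    v = mat.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("expression matrix must be finite")
    across_genes = np.apply_along_axis(_sigmoid_rescale, 1, v, iqr_divisor)
    across_samples = np.apply_along_axis(_sigmoid_rescale, 0, across_genes, iqr_divisor)
    return pd.DataFrame(across_samples, index=mat.index, columns=mat.columns)


# ---------------------------------------------------------------------------
# Aggregation and gene-set maps


def aggregate_regions(
    normalized: dict[str, pd.DataFrame],
    assignments: dict[str, pd.DataFrame],
    region_meta: pd.DataFrame | None = None,
    exclude_hemisphere: str | None = None,
) -> RegionExpressionMatrix:
    """Average samples within regions per donor, then across donors.

    `normalized` maps donor id -> samples x genes matrix; `assignments`
    maps donor id -> assign_samples output.  Donors lacking a region are
    skipped for that region; regions missing from every donor are filled
    by fill_missing_regions upstream or excluded.  Optionally drops all
    regions of one hemisphere (sparse-hemisphere exclusion).
    """
    if not normalized:
        raise ValueError("need >= 1 donor")
    per_donor = {}
    for donor_id, expr in normalized.items():
        a = assignments[donor_id]
        kept = a.loc[a["kept"]]
        joined = expr.loc[kept.index].copy()
        joined["__region"] = kept["region"]
        per_donor[donor_id] = joined.groupby("__region").mean()
    stacked = pd.concat(per_donor, names=["donor", "region"])
    values = stacked.groupby(level="region").mean()
    if exclude_hemisphere is not None:
        if region_meta is None:
            raise ValueError("hemisphere exclusion requires region metadata")
        keep = region_meta.index[region_meta["hemisphere"] != exclude_hemisphere]
        values = values.loc[values.index.intersection(keep)]
    values.index.name = "region"
    return RegionExpressionMatrix(values=values, donors_used=sorted(normalized))


def build_region_expression(
    probe_table: ProbeTable,
    donors: dict[str, DonorExpression],
    region_meta: pd.DataFrame,
    exclude_hemisphere: str | None = None,
    iqr_divisor: float = IQR_NORMAL_DIVISOR,
) -> tuple[RegionExpressionMatrix, pd.Series]:
    """Full chain from donor tables to the regions x genes matrix.

    Annotation and intensity filtering, differential-stability probe
    selection on the raw regional patterns (the per-sample normalization
    would otherwise couple probes), sample assignment, two-pass robust
    sigmoid normalization, and within-donor / cross-donor aggregation.
    Returns the matrix and the per-probe stability scores.
    """
    pt = intensity_filter(drop_unannotated_probes(probe_table))
    assignments = {d: assign_samples(don, region_meta) for d, don in donors.items()}
    regional: dict[str, pd.DataFrame] = {}
    for d, don in donors.items():
        a = assignments[d]
        kept = a.loc[a["kept"]]
        m = don.expression.loc[kept.index, pt.annotations.index].copy()
        m.index = pd.Index(kept["region"], name="region")
        regional[d] = m.groupby("region").mean()
    scores = differential_stability_scores(regional)
    chosen = select_probe_per_gene(scores, pt)
    normalized = {
        d: normalize_matrix(don.expression[pt.annotations.index], iqr_divisor)
        for d, don in donors.items()
    }
    gene_cols = {
        d: normalized[d][list(chosen.values())].set_axis(list(chosen.keys()), axis=1)
        for d in donors
    }
    matrix = aggregate_regions(gene_cols, assignments, region_meta, exclude_hemisphere)
    return matrix, scores


def intersect_genesets(go_list: list[str], de_list: list[str], set_id: str = "") -> GeneSet:
    """Case-normalized intersection of a GO gene list with a DE gene list."""
    go = {_norm_symbol(g) for g in go_list}
    de = {_norm_symbol(g) for g in de_list}
    genes = sorted(go & de)
    return GeneSet(
        set_id=set_id,
        genes=genes,
        provenance=f"|GO|={len(go)}, |DE|={len(de)}, |intersection|={len(genes)}",
        empty=not genes,
    )


def geneset_expression_map(mat: RegionExpressionMatrix, gs: GeneSet) -> ReferenceMap:
    """Per-region mean normalized expression over a gene set's genes.

    Genes absent from the matrix are ignored; no overlap at all is an
    error.  The number of genes used is recorded in the map name.
    """
    cols = [c for c in mat.values.columns if _norm_symbol(c) in set(gs.genes)]
    if not cols:
        raise ValueError(f"gene set {gs.set_id!r} has no genes in the expression matrix")
    vals = mat.values[cols].mean(axis=1)
    return ReferenceMap(
        values=vals,
        name=f"{gs.set_id} (n_genes={len(cols)})",
        family="geneset",
    )
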