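"""Subregional group statistics on local metabolism.

Long-format tables of per-subject, per-subregion mean normalized uptake
feed one-way ANOVA (between subregions, within one group), two-way ANOVA
(subregion x diagnosis group, crossed fixed effects, Type-II sums of
squares by default for unbalanced designs), Tukey-Kramer post hoc pairwise
group comparisons within each subregion (familywise error control), and
the per-subject anterior-posterior uptake delta.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "subregion_means",
    "one_way_anova",
    "two_way_anova",
    "posthoc_pairwise",
    "anterior_posterior_delta",
]


def subregion_means(
    seed_matrix: np.ndarray,
    labels: np.ndarray,
    subjects: list,
) -> pd.DataFrame:
    """Per-subject mean uptake within each parcellation subregion.

    seed_matrix is subjects x voxels; labels (1..k) assign voxels to
    subregions.  Returns a long table with one row per subject x subregion:
    subject_id, group, bm_status, subregion, mean_uptake.
    """
    seed_matrix = np.asarray(seed_matrix, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.shape[0] != seed_matrix.shape[1]:
        raise ValueError("label count must match voxel count")
    ks = np.unique(labels)
    if ks.min() < 1:
        raise ValueError("labels must cover all voxels with ids >= 1")
    rows = []
    for s, rec in enumerate(subjects):
        for k in ks:
            in_k = labels == k
            if not in_k.any():
                raise ValueError(f"empty subregion {k}")
            rows.append(
                {
                    "subject_id": getattr(rec, "subject_id", str(rec)),
                    "group": getattr(rec, "group", "HC"),
                    "bm_status": getattr(rec, "bm_status", "unknown"),
                    "subregion": int(k),
                    "mean_uptake": float(seed_matrix[s, in_k].mean()),
                }
            )
    return pd.DataFrame(rows)


def _with_corrected_total(table: pd.DataFrame, n_obs: int) -> pd.DataFrame:
    table = table.rename(columns={"PR(>F)": "p", "sum_sq": "sum_sq", "df": "df", "F": "F"})
    total = pd.DataFrame(
        {"sum_sq": [table["sum_sq"].sum()], "df": [float(n_obs - 1)], "F": [np.nan], "p": [np.nan]},
        index=["Corrected Total"],
    )
    return pd.concat([table, total])


def one_way_anova(table: pd.DataFrame, factor: str = "subregion") -> pd.DataFrame:
    """One-way ANOVA of mean_uptake between subregions (one diagnostic group).

    Returns an ANOVA table with rows for the factor, Residual and
    Corrected Total; df1 and df2 are reported separately.
    """
    if table[factor].nunique() < 2:
        raise ValueError("need >= 2 subregions")
    if len(table) < table[factor].nunique() + 1:
        raise ValueError("too few observations")
    if table.groupby(factor)["mean_uptake"].var(ddof=1).fillna(0).sum() == 0 and (
        table.groupby(factor)["mean_uptake"].mean().nunique() == 1
    ):
        # all values identical: F = 0 by convention rather than 0/0
        k = table[factor].nunique()
        n = len(table)
        out = pd.DataFrame(
            {
                "sum_sq": [0.0, 0.0],
                "df": [float(k - 1), float(n - k)],
                "F": [0.0, np.nan],
                "p": [1.0, np.nan],
            },
            index=[f"C({factor})", "Residual"],
        )
        return _with_corrected_total(out.rename(columns={"p": "PR(>F)"}), n)
    model = smf.ols(f"mean_uptake ~ C({factor})", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=1)
    return _with_corrected_total(aov, len(table))


def two_way_anova(
    table: pd.DataFrame,
    factor_a: str = "subregion",
    factor_b: str = "group",
    ss_type: int = 2,
) -> pd.DataFrame:
    """Two-way crossed ANOVA (subregion x group) with interaction.

    Unbalanced designs use partial (Type-II by default) sums of squares.
    Empty factor cells are an error listing the offending cells.
    """
    for f in (factor_a, factor_b):
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f} needs >= 2 levels")
    cells = table.groupby([factor_a, factor_b], observed=True).size()
    full = pd.MultiIndex.from_product(
        [table[factor_a].unique(), table[factor_b].unique()], names=[factor_a, factor_b]
    )
    empty = sorted(set(full) - set(cells.index))
    if empty:
        raise ValueError(f"empty design cells: {empty}")
    model = smf.ols(f"mean_uptake ~ C({factor_a}) * C({factor_b})", data=table).fit()
    aov = sm.stats.anova_lm(model, typ=ss_type)
    return _with_corrected_total(aov, len(table))


def posthoc_pairwise(
    table: pd.DataFrame,
    group_col: str = "group",
    within_col: str = "subregion",
    method: str = "tukey",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise group comparisons within each subregion, FWE-controlled.

    method "tukey" (Tukey-Kramer studentized-range, the post-ANOVA default)
    or "bonferroni" (pairwise Welch t-tests with Bonferroni correction).
    Returns one row per (subregion, group pair): diff, p_fwe, significant.
    """
    rows = []
    for sub, chunk in table.groupby(within_col, observed=True):
        groups = sorted(chunk[group_col].unique())
        if len(groups) < 2:
            raise ValueError(f"single group within {within_col}={sub}")
        samples = [chunk.loc[chunk[group_col] == g, "mean_uptake"].to_numpy() for g in groups]
        n_pairs = len(groups) * (len(groups) - 1) // 2
        if method == "tukey":
            res = sps.tukey_hsd(*samples)
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    rows.append(
                        {
                            within_col: sub,
                            "group_a": groups[i],
                            "group_b": groups[j],
                            "diff": samples[i].mean() - samples[j].mean(),
                            "p_fwe": float(res.pvalue[i, j]),
                        }
                    )
        elif method == "bonferroni":
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    t, p = sps.ttest_ind(samples[i], samples[j])
                    rows.append(
                        {
                            within_col: sub,
                            "group_a": groups[i],
                            "group_b": groups[j],
                            "diff": samples[i].mean() - samples[j].mean(),
                            "p_fwe": min(1.0, float(p) * n_pairs),
                        }
                    )
        else:
            raise ValueError(f"unknown FWE method {method!r}")
    out = pd.DataFrame(rows)
    out["significant"] = out["p_fwe"] < alpha
    return out


def anterior_posterior_delta(
    table: pd.DataFrame,
    anterior_set: set[int] | list[int],
    posterior_set: set[int] | list[int],
) -> pd.DataFrame:
    """Per-subject delta = mean(anterior subregion uptake) - mean(posterior).

    The two subregion sets must be nonempty and disjoint.  Returns one row
    per subject (subject_id, group, delta); swap the sets to flip the sign.
    """
    anterior = set(anterior_set)
    posterior = set(posterior_set)
    if not anterior or not posterior:
        raise ValueError("anterior and posterior sets must be nonempty")
    if anterior & posterior:
        raise ValueError(f"overlapping sets: {sorted(anterior & posterior)}")
    piv = table.pivot_table(
        index=["subject_id", "group"], columns="subregion", values="mean_uptake", observed=True
    )
    missing = (anterior | posterior) - set(piv.columns)
    if missing:
        raise ValueError(f"subregions absent from table: {sorted(missing)}")
    delta = piv[sorted(anterior)].mean(axis=1) - piv[sorted(posterior)].mean(axis=1)
    out = delta.rename("delta").reset_index()
    return out


def delta_group_summary(delta_table: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean and SD of the anterior-posterior delta."""
    return (
        delta_table.groupby("group", observed=True)["delta"]
        .agg(["mean", "std", "count"])
        .rename(columns={"std": "sd", "count": "n"})
    )
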