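#!/usr/bin/env python
"""Subregional group statistics on the clinical cohort.

Builds the long per-subject x per-subregion uptake table from the planted
subregion labels, fits the one-way (healthy subjects) and two-way
(subregion x diagnosis group) ANOVAs with Tukey post hoc comparisons, and
computes the per-subject anterior-posterior delta, overall and restricted
to the biomarker-stratified subcohort (HC biomarker-negative, patients
biomarker-positive).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hippoparc.stats import (
    anterior_posterior_delta,
    delta_group_summary,
    one_way_anova,
    posthoc_pairwise,
    subregion_means,
    two_way_anova,
)

OUT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "cohorts"
ANTERIOR, POSTERIOR = {1, 2}, {4, 5}


def main():
    seed = pd.read_csv(DATA / "clinical_cohort_seed_matrix.csv", index_col=0)
    truth = json.loads((DATA / "clinical_cohort_truth.json").read_text())
    subjects = pd.read_csv(DATA / "clinical_cohort_subjects.tsv", sep="\t")

    class Rec:
        def __init__(self, row, bm):
            self.subject_id = row.subject_id
            self.group = row.group
            self.bm_status = bm

    recs = [Rec(row, bm) for (_, row), bm in zip(subjects.iterrows(), truth["bm_status"])]
    tab = subregion_means(seed.to_numpy(), np.asarray(truth["voxel_labels"]), recs)
    tab.to_csv(DATA / "subregion_uptake_long.tsv", sep="\t", index=False)

    ow = one_way_anova(tab[tab.group == "HC"])
    print("one-way ANOVA between subregions (healthy subjects):")
    print(ow.round(3))

    aov = two_way_anova(tab)
    aov.to_csv(OUT / "twoway_anova.tsv", sep="\t")
    print("\ntwo-way ANOVA (subregion x group):")
    print(aov.round(3))

    ph = posthoc_pairwise(tab)
    ph.to_csv(OUT / "posthoc_pairwise.tsv", sep="\t", index=False)
    print(f"\nTukey post hoc: {ph.significant.sum()} of {len(ph)} pairs significant (FWE < .05)")

    delta = anterior_posterior_delta(tab, ANTERIOR, POSTERIOR)
    delta.to_csv(DATA / "anterior_posterior_delta.tsv", sep="\t", index=False)
    summ = delta_group_summary(delta)
    print("\nanterior-posterior delta by group:")
    print(summ.round(4))
    print(f"delta maximal in: {summ['mean'].idxmax()}")

    # biomarker-stratified subcohort
    bm = tab.merge(
        pd.DataFrame({"subject_id": [r.subject_id for r in recs],
                      "bm": [r.bm_status for r in recs]}),
        on="subject_id",
    )
    keep = ((bm.group == "HC") & (bm.bm == "negative")) | (
        (bm.group != "HC") & (bm.bm == "positive")
    )
    sub = bm[keep]
    n_sub = sub.subject_id.nunique()
    aov_bm = two_way_anova(sub)
    aov_bm.to_csv(OUT / "twoway_anova_biomarker.tsv", sep="\t")
    print(f"\nbiomarker-stratified subcohort: {n_sub} subjects")
    print(aov_bm.round(3))


if __name__ == "__main__":
    main()
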