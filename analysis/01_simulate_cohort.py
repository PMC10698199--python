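#!/usr/bin/env python
"""Generate the synthetic study cohorts and write them to results/.

Two cohorts are produced: a 100-subject healthy "parcellation" cohort at
the planted-structure conditions (5 clusters, unit loading, noise 0.5),
and an 846-subject 4-group "clinical" cohort with diagnosis-dependent
uptake shifts and CSF biomarker draws.  Subject tables go out as TSV, the
seed-voxel and parcel matrices as CSV, and the ground truth as JSON.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from hippoparc.io import write_subject_table
from hippoparc.synth import SyntheticConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "cohorts"
STUDY_GROUPS = {"HC": 266 / 846, "earlyMCI": 285 / 846, "lateMCI": 150 / 846, "AD": 145 / 846}


def dump(cohort, truth, tag):
    write_subject_table(cohort.subjects, DATA / f"{tag}_subjects.tsv")
    pd.DataFrame(
        cohort.seed_matrix, index=[r.subject_id for r in cohort.subjects]
    ).to_csv(DATA / f"{tag}_seed_matrix.csv")
    cohort.parcel_table.to_frame().to_csv(DATA / f"{tag}_parcel_table.csv")
    (DATA / f"{tag}_truth.json").write_text(
        json.dumps(
            {
                "voxel_labels": truth.voxel_labels.tolist(),
                "cluster_parcel_map": {str(k): v for k, v in truth.cluster_parcel_map.items()},
                "groups": truth.groups,
                "bm_status": truth.bm_status,
            },
            indent=2,
        )
    )


def main():
    OUT.mkdir(exist_ok=True)
    DATA.mkdir(parents=True, exist_ok=True)

    parc_cohort, parc_truth = generate_cohort(SyntheticConfig(seed=20))
    dump(parc_cohort, parc_truth, "parcellation_cohort")
    print(
        f"parcellation cohort: {parc_cohort.seed_matrix.shape[0]} subjects, "
        f"{parc_cohort.seed_matrix.shape[1]} seed voxels, "
        f"{parc_cohort.parcel_table.values.shape[1]} parcels, "
        f"{parc_truth.voxel_labels.max()} planted clusters"
    )

    clin_cohort, clin_truth = generate_cohort(
        SyntheticConfig(n_subjects=846, group_fractions=STUDY_GROUPS, seed=21)
    )
    dump(clin_cohort, clin_truth, "clinical_cohort")
    counts = pd.Series(clin_truth.groups).value_counts()
    bm = pd.Series(clin_truth.bm_status).value_counts()
    print(f"clinical cohort groups: {counts.to_dict()}")
    print(f"CSF biomarker status: {bm.to_dict()}")
    print(f"cohort matrices under {DATA}; summaries will go to {OUT}")


if __name__ == "__main__":
    main()
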