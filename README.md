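# hippoparc

Metabolic covariance-based parcellation of the hippocampus from FDG-PET,
with the downstream analyses that make the subregions useful: group
statistics under Alzheimer's-disease staging, seed-GLM whole-brain
covariance networks, spatial association with reference maps, and
construction of gene-expression reference maps from donor microarray
tables.

## The problem

Glucose uptake measured with <sup>18</sup>FDG-PET covaries across subjects
between brain locations that are functionally coupled ("co-metabolism").
The hippocampus is not homogeneous in this respect: different parts of it
belong to different whole-brain metabolic networks, and Alzheimer's-related
pathology affects those parts differently. This package implements the
full data-driven pipeline for delineating such subregions and profiling
them, for researchers working with parcel-level uptake data:

1. **Covariance profiles.** For each seed (hippocampal) voxel *v* and each
   brain parcel *p*, the profile is the Fisher-transformed Pearson
   correlation across subjects, *z*(v,p) = arctanh(corr(x<sub>·v</sub>,
   y<sub>·p</sub>)), computed over a quality-filtered sample (native
   resolution ≤ 2 mm) of pons-normalized uptake volumes parcellated by a
   combined cortical + subcortical atlas.
2. **Consensus parcellation.** Seed voxels are clustered by Euclidean
   k-means on their profiles (best of *R* random restarts). Robustness
   comes from a subject-level bootstrap: each replicate's clustering is
   aligned to the full-sample clustering by Hungarian assignment and the
   consensus takes the per-voxel modal label. The number of clusters is
   selected by split-half stability — the mean adjusted Rand index (ARI)
   between parcellations of random half-samples, maximized over k.
3. **Group statistics.** Per-subject subregion means feed one-way and
   two-way (subregion × diagnosis group) ANOVAs with Tukey FWE-corrected
   post hoc pairwise comparisons, CSF-biomarker stratification
   (Aβ<sub>1-42</sub> < 977 pg/mL and p-tau > 24 or t-tau > 266 pg/mL),
   and the per-subject anterior–posterior uptake delta.
4. **Networks.** Each subregion's whole-brain metabolic network is the
   per-parcel OLS of parcel uptake on the subregion mean, with
   Benjamini–Hochberg FDR selection; the unthresholded T map is retained.
5. **Spatial association.** T maps are compared with reference maps
   (behavioral term maps, receptor densities, gene-set expression) at the
   region level via (partial) Pearson correlations, Fisher z, and
   permutation nulls that preserve spatial autocorrelation by variogram
   matching.
6. **Transcriptomics.** Donor microarray tables are reduced to a
   region × gene matrix: Entrez re-annotation, background-intensity
   filtering, probe selection by differential stability
   ΔS(p) = mean over donor pairs of Spearman ρ of the probe's regional
   pattern, constrained nearest-centroid sample assignment, robust sigmoid
   normalization x<sub>norm</sub> = 1/(1 + exp(−(x − median)/(IQR/1.349)))
   with unit rescaling (across genes, then across samples), and
   within-donor / cross-donor averaging. Gene-set expression maps average
   the columns of a gene list (e.g. a GO category ∩ a differential-
   expression list).

A synthetic-data module generates cohorts with planted cluster structure
(a linear latent-factor model), reference maps with controllable spatial
autocorrelation, and donor expression tables with planted spatial
gradients, so the whole pipeline runs and is testable without any imaging
or microarray download.

## Worked example

```python
from hippoparc.synth import SyntheticConfig, generate_cohort
from hippoparc.parcellation import (
    split_half_stability, bootstrap_consensus, adjusted_rand_index,
)

cohort, truth = generate_cohort(SyntheticConfig(seed=20))  # 100 subjects,
# 200 seed voxels in 5 planted clusters, 60 parcels

curve = split_half_stability(
    cohort.seed_matrix, cohort.parcel_table, ks=[2, 3, 4, 5, 6],
    n_splits=100, n_boot_per_half=25, restarts=10, seed=30,
)
print(curve.table.round(3)); print("selected k =", curve.selected_k)

parc = bootstrap_consensus(
    cohort.seed_matrix, cohort.parcel_table, k=curve.selected_k,
    n_boot=100, restarts=10, seed=31,
)
print("ARI vs planted labels:",
      adjusted_rand_index(parc.labels, truth.voxel_labels))
```

prints

```
   mean_ari  sd_ari  n_splits
k
2     0.135   0.171       100
3     0.565   0.287       100
4     0.622   0.096       100
5     1.000   0.000       100
6     0.998   0.009       100
selected k = 5
ARI vs planted labels: 1.0
```

The split-half curve peaks at the planted k = 5 (reproducibility is
perfect there and degrades for coarser solutions, which merge clusters
arbitrarily), and the bootstrap-consensus parcellation at k = 5 recovers
the planted voxel labels exactly.

The `analysis/` directory holds the numbered drivers that run the full
study on synthetic data — cohort simulation, parcellation, group
statistics, networks, spatial association, expression maps — each writing
its tables under `results/`.

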