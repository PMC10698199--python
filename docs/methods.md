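# Methods

## Pipeline model

The package treats subject-level FDG-PET volumes as already preprocessed:
spatially normalized to a common grid, partial-volume handling done
upstream, gray-matter segmented and smoothed. Inside the package the only
intensity operation is reference normalization — dividing every voxel by
the mean uptake in a reference mask (the pons in the intended use), after
which uptake is dimensionless, the reference mean is exactly 1, and the
operation is idempotent and scale-invariant. No resampling is performed
anywhere: volumes, atlases and masks must share their grid and affine
bit-exactly, and any mismatch is an error rather than a silent
interpolation.

Quality control keeps subjects whose largest native voxel dimension is at
most 2 mm, the resolution below which hippocampal subregions are too
coarse to separate. Atlas combination shifts subcortical labels past the
cortical range (default offset 400) and gives subcortical labels
precedence at overlap voxels — equivalent to zeroing the cortical label
there — so no voxel contributes to two parcels and parcel correlations are
not artificially inflated.

## Covariance profiles

Co-metabolism between seed voxel v and parcel p is the Pearson correlation
of their uptake across subjects, Fisher-transformed (arctanh) for variance
stabilization. Correlations are clipped to ±(1 − 1e−7) before arctanh:
perfectly collinear pairs arise in resampled data and unbounded z values
would dominate the Euclidean geometry that k-means relies on.
Zero-variance voxels or parcels are an error that names the offending
columns — the caller masks them explicitly; nothing is silently imputed.
Within a bootstrap replicate (where degeneracy can be created by the
resample itself) degenerate columns are zeroed with a logged warning so
the ensemble keeps a common shape. No nuisance regression is applied to
the covariance computation; a covariate hook exists in the network GLM
instead.

## Parcellation and model selection

Seed voxels are clustered by Euclidean k-means on profile rows. The
package ships its own vectorized multi-restart Lloyd implementation
(`hippoparc._kmeans`): all restarts of a fit are iterated as one
(restarts, k, features) centroid stack, which makes a single 200 × 60 fit
about one millisecond. This matters because stability selection needs on
the order of 10^4–10^5 small fits; a general-purpose clustering object is
roughly 25 times slower per fit at this size. Semantics are the classic
ones — random-row initialization, best restart by within-cluster sum of
squares, empty clusters repaired by relocating the farthest point — and
tests cross-check partitions against scikit-learn's KMeans on separated
data. Paper-scale defaults for the full run are 500 restarts and 255
iterations per fit and 500 bootstrap replicates.

Bootstrap labels are not comparable across replicates, so each replicate
is aligned to the clustering of the non-resampled sample by solving the
assignment problem on the k × k contingency table (Hungarian algorithm)
before the per-voxel modal label is taken. Mode ties break to the smallest
label id and k-selection ties to the smallest k, making the chain
deterministic under fixed seeds.

The number of clusters is chosen by split-half stability: subjects are
randomly halved, the full covariance → k-means → consensus chain runs per
half (with a reduced per-half bootstrap, default 50 replicates, and a
reduced restart count, default 10), and the ARI between the two half
parcellations is averaged per candidate k; the selected k maximizes the
mean. The default split count is 10,000; the analysis drivers, the tests
and the acceptance script use 100 splits with 25 bootstraps per half and
10 restarts, which resolves the stability curve clearly at the synthetic
study conditions while a full stability run finishes in under a minute per
cohort. The candidate range k = 2…6 is a configuration parameter.

Percent overlap between a metabolic subregion and a reference subfield
labeling is 100 × |intersection| / |subregion voxels|, computed per
(subregion, field) pair.

## Group statistics

Subregion means per subject feed crossed fixed-effects ANOVAs: one-way
(between subregions, within a group) and two-way (subregion × diagnosis
group) with interaction, using Type-II sums of squares for unbalanced
designs (configurable). Degrees of freedom are always reported as df1 and
df2 separately, and every table carries a corrected-total row so df
bookkeeping is checkable. Subregion is treated as a crossed factor rather
than a repeated measure — the simpler model whose reported degrees of
freedom match the intended designs; a mixed model would be the natural
extension and is out of scope.

Post hoc pairwise group comparisons within each subregion use the
Tukey–Kramer studentized-range procedure (the standard post-ANOVA
familywise-error control for pairwise means; Bonferroni on Welch t-tests
is available by flag). Significance is p_FWE < 0.05.

CSF biomarker status combines the three Elecsys markers with published
cut-offs — Aβ(1–42) 977 pg/mL (positive below), p-tau 24 pg/mL and t-tau
266 pg/mL (positive above). How the three calls combine is a genuine
design choice; the default is amyloid-positive AND (p-tau- or
t-tau-positive), the standard A/T semantics, with "any" and "all" rules
available and the rule name recorded in provenance. Evaluation uses
three-valued logic, so a subject whose available markers already decide
the rule is classified even with others missing, and "unknown" is returned
only when the rule is genuinely undecidable.

The anterior–posterior delta is the per-subject difference between the
mean uptake of a declared anterior subregion set and a posterior set
(disjoint, intermediate subregion excluded by default). Which subregions
count as anterior/posterior is configuration, since data-driven cluster
ids carry no anatomy by themselves.

## Networks and spatial association

A subregion's metabolic network is the per-parcel OLS of parcel uptake on
the subregion's mean uptake (optional covariates), fit for all parcels in
one vectorized pass. With no covariates the seed-slope T equals the
correlation form r·√((n−2)/(1−r²)) to machine precision — an identity the
tests assert. FDR selection is Benjamini–Hochberg at q < 0.05 (independent
/ PRDS assumption noted); the unthresholded T map is always exported
because downstream spatial association consumes the whole pattern, not the
surviving parcels. Hemispheres are analyzed as separate seeds by default.

Spatial association operates on region-aggregated values (one scalar per
atlas region; white matter / CSF regions excluded), not voxels. The
statistic is the Pearson correlation after both maps are residualized on a
shared confound (e.g. a gray-matter probability map) — a partial
correlation; it is Fisher-transformed. Significance uses permutation
nulls. Because spatially autocorrelated maps violate exchangeability, the
default null is autocorrelation-preserving: each draw keeps the best of
(default 20) candidate permutations by distance between the candidate's
empirical variogram and the original's, computed over the region ordering,
which indexes adjacency for the chain-structured synthetic maps. Values
are permuted, never altered. The observed Fisher-z values of a family of
maps are tested against the null-ensemble mean with a one-sample t-test; a
two-sided permutation-tail p on the mean z is reported alongside and is
the primary p when only a single observed z exists. BH-FDR is applied
across reference maps. Term-map decoding is deliberately not a test: every
term with r > 0.1 is reported, sorted, as a behavioral profile.

## Transcriptomics

Donor microarray tables become a region × gene matrix in the following
order: (1) probes without a valid Entrez ID are dropped; (2) probes below
background intensity in ≥ 50 % of all pooled samples are dropped (a probe
at exactly half goes); (3) among multiple probes per gene, the one with
the highest differential stability ΔS — the mean Spearman correlation of
its regional expression pattern over all donor pairs, computed on raw
regional means — is kept, ties to the smallest probe id; (4) samples are
assigned to the nearest same-hemisphere, same-division region centroid,
and samples farther than the donor mean + 2 SD are excluded; regions with
no sample in any donor are filled by the per-donor nearest sample,
averaged across donors with inverse-distance weights and flagged as
imputed; (5) expression is normalized with a robust sigmoid,
1/(1 + exp(−(x − median)/(IQR/1.349))), rescaled to [0, 1], first across
genes within each sample and then across samples within each gene; (6)
samples are averaged within regions per donor, then across donors.

Two choices deserve emphasis. The IQR divisor 1.349 makes the scale
normal-consistent (the IQR of a standard normal is ≈ 1.349 σ); it is
configurable. And ΔS is computed **before** normalization: the per-sample
across-gene pass couples probes, and on synthetic data it demonstrably
leaks the gradient genes' spatial pattern into pure-noise probes, lifting
their apparent stability from ≈ 0 to 0.3–0.6. Distances are measured to
region centroids; surface meshes are out of scope, and centroids are the
volume-native analogue of nearest-vertex matching. Hemisphere exclusion
(for a sparsely sampled hemisphere) is a flag, off for the synthetic
tests. Gene-symbol matching is case-insensitive with whitespace stripped.

Gene-set maps average the normalized columns of the genes present from a
set, where a set is typically the intersection of a pathway list with a
differential-expression list; empty intersections are flagged, not fatal.

## Synthetic data: what it emulates and what it does not

The cohort generator implements a linear latent-factor model because
across-subject Pearson covariance is exactly what the analysis consumes.
Each planted cluster c carries a factor f_sc ~ N(0,1) per subject; seed
voxels in c read μ_{group,c} + loading·f_sc + N(0, noise_sd), and the
parcels associated with c (disjoint sets, n_parcels/(k+1) per cluster)
share the same factor. Within-cluster voxel–parcel correlation is then
loading²/(loading² + noise_sd²) — 0.8 at the default loading 1, noise 0.5
— and zero across clusters. Defaults are the planted-structure study
conditions used throughout the tests: 100 subjects, 5 clusters over 200
seed voxels, 60 parcels. Baseline uptake is 1.2 for seed voxels (above the
pons reference, as hippocampal gray matter is) with per-cluster offsets
(+0.10 … −0.10) giving the subiculum-over-CA and anterior-over-posterior
gradients, and group effects are additive per-cluster shifts: −0.02 for
early impairment, −0.08…−0.10 for late impairment with the two anterior
clusters relatively preserved (−0.02), −0.15 for dementia. CSF biomarkers
are drawn from group-specific normals straddling the published cut-offs.

Limitations to keep in mind when reading green tests: there is no scanner
physics, no point-spread function, no partial-volume effect, no spatial
smoothness within the seed (voxels are exchangeable within a cluster), and
the factor amplitude needed to give a clean 0.8 covariance contrast makes
the subject-level variance of subregion means (SD ≈ 1) much larger than
real normalized-uptake variability. Group mean shifts of 0.02–0.15 are
realistic, so group-difference statistics on the synthetic clinical cohort
have realistic (i.e. modest) power: the anterior–posterior delta ordering
across groups holds in expectation but not in every sampled cohort. Tests
that assert the delta signature therefore plant stronger contrasts
explicitly. Passing tests demonstrate the estimators and their
calibration, not effect sizes in real cohorts.

The reference-map generator moving-averages white noise along a region
chain (half-width = smoothness), giving controllable autocorrelation for
the null-construction tests. The donor-expression generator plants a
shared monotone gradient in designated genes, donor noise everywhere,
probes with invalid Entrez ids, and dim probes below background, so every
filtering rule has work to do; at zero noise the gradient probes attain
ΔS = 1 exactly.

## Numerical and procedural choices

- Correlation clipping 1 − 1e−7; arctanh applied after clipping.
- k-means: random-row init (no k-means++), inertia-based restart choice,
  empty-cluster relocation to the farthest point, label vectors 1..k.
- All ties deterministic: mode → smallest label, k-selection → smallest k,
  probe selection → smallest probe id, argmax → first index.
- Every stochastic routine takes an explicit seed; pipelines derive child
  seeds from one generator so a single integer reproduces a full run.
- Degenerate inputs: zero reference mean, zero-variance columns, empty
  clusters, zero IQR, constant covariates and empty nulls all have defined
  behavior (error, flag, or documented fallback) rather than NaNs.
- Problem sizes in the shipped drivers, tests and acceptance script — 100
  splits / 25 per-half bootstraps / 10 restarts / 100-replicate consensus,
  1000-replicate calibration nulls — were chosen so a full run completes
  in minutes at desk scale; the library defaults remain the paper-scale
  values (500 bootstraps, 500 restarts, 10,000 splits).
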