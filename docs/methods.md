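# Methods

This note documents the models the package implements, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written
down. Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

Subjects are retained when aged ≥ 18 and when *strictly more than* 70% of
their battery variables are observed (the inclusion rule is a strict
inequality; 22/31 ≈ 0.710 passes, 21/31 ≈ 0.677 does not). Missing cells
are replaced by the column mean of the observed cells, which conserves
column means exactly; imputation happens on raw scores, before scaling.
The reference cohort is z-scored by its own per-variable mean and
*population* standard deviation (ddof 0 — the normative cohort is treated
as the population defining the scale; configurable). Any second cohort is
scaled by the reference parameters, never its own, so both cohorts live
in the same units; a second cohort therefore does not generally come out
standardized, and that is the point. Variables whose raw convention is
"larger is worse" (the two dexterity completion times) are negated
*after* scaling so they remain unit-variance z-scores.

## Factor model

Dimensionality comes from Horn's parallel analysis on the correlation
matrix: data eigenvalues are compared rank-by-rank with the mean (default)
or 95th percentile of eigenvalues from `n_noise = 100` same-shape
standard-normal datasets, and the retained count is the leading run of
exceedances. The mean criterion is the classical choice and is the
default; note its null behavior: on pure noise the top data eigenvalue
exceeds the *mean* of its own null distribution about half the time, so a
strict null error rate requires the `p95` variant (both are tested).

The factor model is the maximum-likelihood common-factor model with
diagonal uniquenesses, `Cov(x) = ΛΛᵀ + diag(σᵢ²)` — the relaxation of
probabilistic PCA's isotropic `σ²I`. Because the isotropic model is
nested, the FA log-likelihood can never fall below the probabilistic-PCA
log-likelihood on the same data (asserted in tests). The fit is delegated
to scikit-learn's `FactorAnalysis` (LAPACK SVD path for determinism);
uniquenesses collapsing below 1e-3 (Heywood cases) are clamped there with
a warning.

Varimax rotation (own implementation, needed anyway as the target of a
brute-force rotation-grid oracle test) maximizes the column-wise variance
of squared loadings, with Kaiser row-normalization on by default,
tolerance 1e-8, up to 1000 sweeps. Rotation leaves communalities and the
model-implied covariance invariant. Factors are then canonicalized: sorted
by explained variance, sign fixed so each factor's largest-|loading|
variable loads positively (ties to the lowest variable index).

Factor scores use the regression (Thurstone) estimator
`F = Z Ψ⁻¹Λ (ΛᵀΨ⁻¹Λ + I)⁻¹` — the posterior mean of the latent traits —
which is deterministic and linear, so the frozen model transfers to any
cohort scaled with the reference parameters. Variance explained is the
ratio of summed communalities to total model-implied variance.

## Clustering

Trait space is modeled as a K-component Gaussian mixture with spherical
component covariances (minimal complexity). EM is scikit-learn's, with
k-means++ seeding, 10 restarts, convergence at log-likelihood change
< 1e-6, and covariance floor 1e-8; degenerate components are handled by
the restart mechanism. K is the BIC argmin over K = 1…8 with
`BIC = −2 log L + p log n`, `p = (K−1) + Kd + K`, which is exactly the
spherical-mixture parameter count scikit-learn uses (asserted). Partition
stability is reported as the mean pairwise adjusted Rand index between
partitions refitted on 20 random 80% subsamples, each pair compared on
its shared subjects (subsample-vs-subsample rather than
subsample-vs-full; the choice was open and this one also measures the
variability of the fit itself). The ARI is implemented from the
contingency-table formula and cross-checked against scikit-learn's in
tests.

Transfer is pure evaluation: the fitted mixture's parameter hash is
asserted unchanged by assignment of a new cohort. Covariate profiles use
Welch (unequal-variance) t-tests of the "outlier" cluster — the one whose
covariate mean deviates most from the grand mean — against every other
cluster; clusters with fewer than two members are skipped with a note.

One behavior worth knowing: on *estimated* (Thurstone) trait scores the
within-cluster score noise is correlated across traits, so a spherical
mixture approximates ellipsoidal clusters and BIC can over-segment. The
cluster-count recovery result is defined on the generator's trait scores,
where the planted components really are spherical; on estimated scores
the BIC curve should be read together with the ARI stability curve.

## Brain-feature regression

Features are z-scored; each trait is regressed separately on all
predictors simultaneously with the lasso, penalty `α` on the
`1/(2n)‖y − Xβ‖² + α‖β‖₁` objective. The named defaults α = 0.05
(prediction) and α = 0.095 (sparse interpretation models) are tied to
this z-scored parameterization and are scale-dependent. One run: a 70/30
train/test split; α tuned by 5-fold CV *inside the 70%* over a 30-point
log grid on [1e-3, 1] (the hold-out never touches penalty selection,
asserted via split bookkeeping); out-of-sample r² = 1 − SSres/SStot on
the 30%; the out-of-sample p-value comes from regressing observed on
predicted values. The ensemble repeats this 100 times over independent
splits; per-feature prevalence is the fraction of runs with
|coefficient| > 1e-10. Stable features need prevalence ≥ 0.8 and a
consistent coefficient sign across runs (sign-conflicted features are
flagged and dropped); morphology decoys are excluded from stable lists by
default since they fit particular splits rather than generalize. Failed
runs are recorded and tolerated up to 10% of the ensemble.

Nodal degrees threshold the connectome at densities 1%…10% (step 1%),
keeping the `⌈d·n(n−1)/2⌉` strongest edges by |weight| (ties broken by
upper-triangle row-major order), binarizing, and concatenating per-node
degree vectors across densities.

On the default planted fixture, raising the penalty from 0.05 to 0.095
roughly halves-to-thirds the per-run feature count while mean OOS r²
drops by well under 20% relative; with the planted 19-edge signal the
sparsity gain is smaller than it would be in data with hundreds of weak
predictors, because there are simply few true features to shed.

## Network annotation

IC maps are labeled by the canonical template with the largest Pearson
correlation, computed between the full continuous map and the binary
template (thresholding is for building template supports, not for
matching; configurable). Thresholding keeps nonzero voxels above the 99th
percentile *of the nonzero voxels* (the open choice between "of nonzero"
and "of all voxels" went to nonzero, since zero voxels are background).
Constant maps give a degenerate percentile (empty support, warned);
all-zero or zero-variance maps are rejected/unlabeled; matches below
r = 0.1 are flagged weak; ties resolve to the earlier template and are
logged. Labeling is invariant to positive rescaling.

## Heritability

Pair resemblance is the **double-entry regression slope**: each pair is
entered in both orders and the slope of the pooled regression is taken,
which equals the intraclass correlation for standardized traits and
removes the arbitrary within-pair ordering. With `r_MZ = A + C` and
`r_DZ = A/2 + C`, Falconer's identities give `A = 2(r_MZ − r_DZ)`,
`C = 2 r_DZ − r_MZ`, `E = 1 − r_MZ`, which sum to one identically.
Estimates are gated: status `not_significant` unless both pair
regressions reach p < 0.05 (the double-entry p-value is mildly
anti-conservative since doubling inflates the nominal df; it gates, it is
not reported as an exact test), and `breakdown` when A or C is negative —
raw values are always retained, clamping to [0, 1] is reporting-only.
Standard errors come from a pair-level bootstrap (1000 resamples by
default); they are our uncertainty statement, not asserted equal to any
external ± convention. Gender handling: either separate analyses using
same-gender pairs, or pooled analysis of OLS residuals on binary gender
(residuals are exactly gender-orthogonal); the two agree within MC error
when no gender effect exists (tested).

Kinship distance profiles report mean ± sd Euclidean pair distance per
relation, in trait space or in the space of stability-selected brain
features; expected distance grows as pair correlation falls, giving the
ordering MZ < DZ ≈ full sib < half sib < unrelated under a positive A.

## Synthetic generator (study conditions)

The generator's defaults define the conditions all recovery results refer
to, chosen once:

- **Battery**: 31 variables in 4 blocks (motor/endurance 8, emotional 8,
  cognitive 9 incl. two sensory tasks, social 6), primary loadings
  ramping 0.5–0.9 within block, sparse cross-loadings 0.10–0.25 (below
  the 0.3 display threshold typical of loading figures, so only block
  structure is assumed knowable), uniquenesses 0.3–0.5. Reference cohort
  n = 1369; missingness MCAR at 2.7%.
- **Clusters**: 4 spherical components, one per trait axis at distance
  4.5 from the origin, within-cluster sd 1.0 → pairwise separation
  ≈ 6.4 sd. With K components the between-cluster covariance has rank
  K − 1, so the within-cluster spread must carry the remaining trait
  dimension — the reason the means are axis-aligned and the sd is not
  small. Weights (0.30, 0.25, 0.25, 0.20); cluster-dependent demographics
  emulate the qualitative pattern "cluster 1 mostly male, cluster 4
  older" (p_male 0.65/0.38/0.38/0.45; age means 38/40/42/62).
- **Families**: per trait, `y = √A·g + √C·c + √E·e` with additive-genetic
  correlations 1 (MZ), 0.5 (DZ, full sib), 0.25 (half sib), 0 (unrelated)
  — the standard additive-genetics values, which the kinship classes
  state rather than estimate — shared c within pairs, independent e. MZ
  co-twins share gender. Pair records are disjoint (no subject appears in
  two pairs), unlike real pedigrees where twins can also be half-siblings
  of others.
- **Brain features**: 50 ICs → 1225 edge features; 19 edges carry planted
  coefficients of magnitude 0.5 and alternating sign (10 on
  Motor-endurance, 9 on Executive and cognitive function; the
  emotional/social traits drive nothing), feature noise sd 1.0, plus 20
  pure-noise morphology decoys. The signal level was set a priori from
  the lasso stationarity condition: planted edges correlate ≈ 0.45 with
  their trait versus a selection threshold of ≈ α = 0.095 and a null
  correlation sd of ≈ 0.04 at the 545-subject training size, so true
  edges clear the threshold by a wide margin and decoys only sporadically.
- **IC maps**: disjoint contiguous template supports over the voxel axis;
  each IC copies one template with amplitude U(1.5, 3) plus white noise.

Everything is a pure function of (config, seed) via
`numpy.random.default_rng`; acceptance replicates derive child seeds from
the base seed with `SeedSequence`.

**What passing tests do not show**: the generator's linear-Gaussian
battery, MCAR missingness, exactly spherical clusters, disjoint pair
records, uniform 18–35 transfer ages and edge-wise independent
connectivity noise are all idealizations. Recovery under these conditions
demonstrates the estimators are implemented correctly and are consistent
under their own assumptions; it does not certify performance on real
battery or connectome data, where non-Gaussian scores, informative
missingness, correlated measurement error and family overlap all bite.

## Problem sizes

Recovery results use the sizes stated with them: 200 replicate twin
cohorts of 1000+1000 pairs for ACE recovery (mean estimates within
±0.02); 100 seeded default cohorts for the parallel-analysis count; 100
(suite) / 50 (acceptance script) cohorts for the BIC cluster count; 1e5
pairs for generator correlation checks; 100-run ensembles for stability
selection. The default pipeline configuration runs the ensembles at fixed
penalties (0.05 / 0.095) and reserves per-run CV for explicit
configuration, trading a redundant hyperparameter search for a leaner
default run; the test suite exercises the CV path directly.

## Known limitations

- Falconer estimation ignores assortative mating, dominance and
  gene-environment interaction; it is the simple two-equation
  decomposition, not a structural-equation ACE fit.
- The double-entry regression p-value is anti-conservative (used only as
  a gate).
- Spherical mixtures over-segment ellipsoidal score clouds (see
  Clustering).
- The λ defaults are tied to the z-scored MSE lasso objective and do not
  transfer across parameterizations.
- The generator does not simulate fMRI time series, ICA estimation, or
  morphometry; IC maps and netmats are consumed as given.
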