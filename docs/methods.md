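# Methods

This note documents the statistical models implemented in `crossconn`, the
design choices that were genuinely open, the synthetic-data model and what it
does and does not emulate, and the numerical conventions. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scan processing

A scan is a node × timepoint matrix with nuisance regressors (task
co-activation regressors, WM/CSF signals, the 24-parameter motion expansion,
frame-wise displacement). Processing order is fixed: **regress, then filter,
then correlate**.

* *Nuisance regression* is OLS on `[intercept | nuisance]`. Collinear
  columns are dropped greedily left-to-right (QR with tolerance 1e-10) with
  a warning naming the dropped columns; residuals are orthogonal to every
  retained regressor. Task regressor construction is not defined here — task
  co-activation columns are accepted as supplied input, because no
  operational definition of "mean task-evoked co-activation" is available at
  the node-time-series level.
* *Temporal filtering* is a zero-phase forward–backward Butterworth
  (`sosfiltfilt`, order 4 per pass, 8 effective). The filter is specified by
  its contract, not its realization: stop-band attenuation ≥ 20 dB and
  pass-band gain within ±10%, verified on probe sinusoids in the tests.
  Defaults: rest 0.008–0.1 Hz band-pass, task 0.008 Hz high-pass.
* *Connectivity* is the Pearson correlation of the processed series; a
  zero-variance node is an error naming the node (dropping it is the
  caller's decision). Edge vectorization is 0-based, upper-triangle,
  row-major everywhere in the package; `E = N(N−1)/2`.

## Cross-paradigm PCA

Orientation: **edges are observations, paradigms are variables** (E × K).
This is the only orientation that produces one loading per paradigm and one
score per edge. Columns are mean-centered but not scaled (covariance PCA),
so paradigms' amplitude differences remain meaningful; a `standardize` flag
provides correlation PCA. Components come from the eigendecomposition of the
K × K covariance; scores are the centered data projected on the unit-norm
first loading vector.

Sign convention: eigenvectors are sign-ambiguous, and the question whether
to harmonize signs across subjects is genuinely open. The package orients
each subject's component so that the correlation between the PC scores and
the across-paradigm mean edge value is non-negative. This makes "higher
score = stronger shared connectivity" interpretable across subjects, which
is what the downstream group analysis requires. Subjects with missing
paradigms are fit on the available K ≥ 2 columns and K is recorded.

Because covariance PCA weights columns by their variance, a noisier
paradigm (the band-passed rest scan has fewer effective degrees of freedom
per volume) receives a somewhat *larger* loading, not a smaller one; the
loading pattern is therefore not a per-paradigm reliability measure.

## Network-based statistic

* *Edge-wise model*: y_e ~ intercept + covariates + group. The group test is
  the extra-sum-of-squares F between the covariate-only and full model,
  computed for all edges simultaneously via orthonormal bases of the two
  design spaces. Categorical covariates are dummy-coded (S levels → S−1
  columns); a rank-deficient design is an error listing the collinear
  columns. The omnibus G-level contrast is the default; an ordered linear
  trend contrast is available in the post-hoc module.
* *Primary threshold*: expressed as an edge-wise p (default 0.001, the
  common regime for component-forming thresholds), converted to an F
  cutoff with the model's degrees of freedom and applied identically to
  observed and permuted statistics. Component statistic: extent (edge
  count) by default; intensity (Σ F − F_crit) optional.
* *Permutation scheme*: naive label permutation is invalid when covariates
  correlate with group, so the null of the maximum component statistic uses
  **Freedman–Lane**: residuals of the reduced (covariate-only) model are
  row-permuted and the full model refit. Because both models contain the
  covariate space, the refit reduces to permuting the reduced residual
  matrix and projecting — one (p × n)(n × E) product per permutation.
* *FWE p*: `(1 + #{null ≥ observed}) / (1 + B)`, never exactly zero. The
  winning mask is the union of components with FWE p ≤ α (default 0.05);
  with no suprathreshold component the result is valid with an empty mask
  and FWE p marked NaN.
* Determinism: identical inputs and seed give bit-identical results. Under
  subject-row reordering, edge statistics, components, and FWE p of the
  observed components are invariant; the permutation null is invariant in
  distribution but not bitwise (the same permutation indices act on
  reordered rows).

## Post-hoc battery

All downstream statistics act on the scalar network mean over a mask's
edges. ANCOVA reuses the edge-wise engine on a single column; the linear
trend is a two-sided t on centered ordinal group codes after covariates.
Pairwise post-hoc tests are contrasts within the *full* model (shared
covariate adjustment and error variance), Bonferroni-corrected over pairs,
with the later (higher-risk) group minus the earlier one as the reported
direction. Cohen's d uses the pooled SD with the n−2 denominator. Spearman
correlations use average ranks on ties; for n ≤ 10 the two-sided p is an
exact permutation enumeration, above that the t approximation. The
specificity test draws same-size edge sets from **all** edges (the observed
network is not excluded, mirroring the sampling the procedure describes) and
reports the observed network's rank plus Bonferroni survival on both sides.
AUC is the Mann–Whitney rank statistic (ties ½) with a one-sided,
+1-corrected label-permutation p. Subset analyses (matched subsample,
minimum follow-up) are re-runs on a filtered design — `CohortDesign.subset`
or the CLI `--subset` expression — with no special code path.

## Synthetic cohort model

The generator's defaults are the study conditions used by the acceptance
battery: 60 nodes, 3 paradigms (rest + 2 tasks), groups of 30 ordered
control < non-converter < converter, a 30-edge planted subnetwork, graded
standardized effects (0, 0.5, 1.0), shared-variance fraction 0.58,
phenotype coupling 0.5.

**Latent connectivity.** Subject i's target covariance is
Σ_i = Λ_i Λ_iᵀ + I with loadings
`Λ_i = [w_i·1 | Λ_base + A_i]`: a global strength column (all nodes) and
`n_factors = 4` structured columns. Converting Σ to a correlation matrix
gives the trait connectome. Key scales (chosen once as a realistic regime,
with the rationale below):

| parameter | default | role |
|---|---|---|
| `base_global_weight` | 0.45 | baseline mean correlation ≈ 0.1–0.15 |
| `subject_global_log_sd` | 0.8 | between-subject global connectivity spread |
| `factor_strength` | 0.65 | structured (network-like) correlation amplitude |
| `subject_factor_sd` | 0.12 | subject-specific deviation of network structure |
| `network_strength_sd` | 0.06 | subject factor on the planted edges |
| `shared_variance_fraction` | 0.58 | trait vs paradigm-specific edge variance |

The global draw is *uniform* (bounded), not lognormal: with a heavy-tailed
global factor the realized per-cohort SD of any network mean is strongly
right-skewed, which distorts standardized effect sizes between replicates.
Real between-subject differences in mean connectivity are large (motion,
arousal, vasculature), and the bounded draw keeps that spread while keeping
Cohen's d well-behaved.

A crucial consequence of this architecture: the column-centering inside the
per-subject PCA removes the global factor from the trait scores, so the
edge-level group analysis operates on much less between-subject variance
than raw connectivity does. This is the mechanism by which the trait
analysis gains sensitivity over single-paradigm connectivity, and it is why
the package's edge-level recovery works at planted effects that are modest
on the raw-connectivity scale.

**Paradigm-specific variation** is a loading perturbation Λ_i + σ_B B_ik.
σ_B is set by a pilot measurement so that the paradigm-specific edge
variance equals `v_shared · (1 − s)/s` minus the predicted finite-scan
sampling variance (1/(T_eff − 3) on the Fisher-z scale, with T_eff the
volumes surviving the paradigm's filter band). Sampling noise is therefore
an irreducible floor: for s near 1 the factor term clips at zero and the
variance-explained saturates — the monotonicity of variance explained in s
holds below that regime. Rest scans default to 240 volumes vs 160 for task
scans because the narrow band-pass leaves roughly a third of the spectrum.
With these defaults the first PC explains ≈ 68–70% of the variance.

**Planted effect.** The only departure from the factor model: planted edges
receive a Fisher-z shift δ_g + c_i (group shift + subject network-strength
factor). Because an arbitrary edge-wise shift is not realizable as a
correlation matrix, the assembled matrix is repaired by eigenvalue clipping
when marginally non-PSD; a negative eigenvalue mass exceeding 5% of the
trace raises a construction error instead. Effects are specified in
Cohen's-d units on the mean planted-edge connectivity. The generator
self-calibrates: a fixed-seed pilot population is simulated at the latent
level (no time series), and the shift for each requested effect size is
iterated until the pilot-realized d — including tanh compression, repair
erosion, and the shift-dependent compression of the within-group spread —
matches the request. Replicate-averaged realized d lands within a few
percent of the request; single-cohort values scatter with ordinary sampling
error.

**Planted topology.** Discovered circuit-level networks are connected
(component-based inference can only ever report connected structures), so
the default planted network is a random connected subgraph: a node subset
sized for ≈ 1.35 edges per node, a random spanning tree, plus uniform extra
edges. A uniformly sampled edge set of the same size on 60 nodes is
fragmented into many small components and is available as
`planted_topology="uniform"` (and as `plant_network`, which the specificity
test's random draws also use).

**Covariates and confounding.** Age, sex, IQ, site, mean FD, and
antipsychotic dose are drawn per subject; FD (slightly group-graded) and
dose (patients only) modulate the log global weight, so motion and
medication confound raw connectivity in the classic direction. The injected
motion/tissue nuisance series are added to the node signals and are exactly
removable by the regression stage; the FD covariate effect is *not*
removable at the scan level and is what the group-level covariate
adjustment must handle.

**Phenotypes.** Planted-network strength ν_i (standardized δ + c) drives a
disorganization-like score (slope = `phenotype_coupling`, unit noise), a
weaker positive-symptom score (0.4 × coupling), and months to conversion
for the highest-risk group via a negative coupling standardized within that
group, mapped monotonically into (0, 36) months. Spearman-based downstream
analyses see exactly the planted monotone relations.

**Degenerate mode.** With `shared_variance_fraction = 1` and
`noise_sd = 0`, a paradigm is an exact replicate of the same scan, so the
generator reuses the subject's random stream across paradigms and the
per-paradigm connectivity matrices are bit-identical. With finite scans and
independent sampling this identity could not hold, so it is implemented as
an explicit degenerate path.

**What the generator does not emulate.** No haemodynamics or voxel data; no
scanner/site effects beyond a categorical covariate; no temporal
autocorrelation in the neural signal (volumes are i.i.d. draws from the
target covariance — effective degrees of freedom per volume are higher than
in real fMRI); no edge-heteroscedastic noise; and the planted effect is
*coherent* across its edges (a single subject-level factor plus a common
shift), which makes network-mean effects stronger relative to edge-level
effects than selection-free real data would show. Passing tests therefore
demonstrate correctness and calibration of the inference machinery under a
realistic covariance structure, not performance guarantees on real cohorts.

## Problem sizes in the test battery

The statistical acceptance tests run the full chain at 60 nodes and 3
paradigms: 200 null cohorts (n = 30/30/30, 500 permutations) for
family-wise-error calibration, 50 recovery replicates (30 planted edges,
d = 0.8, n = 40/40), 20 graded-design replicates at n = 60/group, 50 + 50
phenotype-coupling replicates at n = 100, 20 discovery/transfer cohort
pairs, and 100 + 50 specificity replicates. Replicate-heavy simulations use
shortened scans (80–120 volumes), a deliberate economy: the quantities they
check (calibration rates, orderings, correlation signs) have margins that do
not depend on scan length; the recovery and transfer tests, whose power does
depend on sampling noise, keep the full-length default scans.

## Numerical conventions

Permutation p-values always use the +1 correction. F statistics with a
perfectly fit full model report 0 when the group adds nothing (0/0 → 0) and
infinity otherwise. Eigenvalues are clipped at zero before computing
variance-explained fractions. Correlations are clipped to ±0.995 before
arctanh. All stochastic operations take explicit seeds; cohort generation
derives independent streams (mask, base architecture, covariates, pilot,
subjects, phenotypes) from one `SeedSequence`, and `architecture_seed`
optionally pins the mask + base architecture independently of the subject
draws so that independent cohorts can share a ground truth. TSV files write
floats with 17 significant digits and are read back with round-trip float
parsing, so write→read is exact.
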