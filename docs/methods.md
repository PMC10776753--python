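# Methods

This note documents the models implemented in `imgomix`, their
assumptions, the tunable parameters and their defaults, the synthetic
data generator's design, and the numerical and inferential choices that
were genuinely open. Nothing here reports an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## 1. Regional GMV testing (`gmv`)

Per parcel *j*, the linear model

    gmv_j ~ 1 + group + age + gender + education + medication + TIV

is fit by QR once for the shared design and solved for all parcels
simultaneously; the reported statistic is the Wald *t* of the group
indicator (MDD = 1), two-sided p from the t distribution with residual
df, and the Benjamini–Hochberg step-up q across parcels
(Benjamini–Yekutieli available via `fdr_method="by"`). The identical
machinery drives the per-CpG methylation tests; its type-I error is
checked at 0.05 ± 0.02 on thousands of null responses, and the t equals
an independent residualisation oracle (partial correlation after
regressing covariates out of both response and group) to 1e-8.

Assumptions: linear covariate effects, homoscedastic Gaussian residuals,
listwise deletion of subjects with missing covariates (count logged).
Medication is one binary flag; because in this design medication exists
only in patients, it is strongly collinear with group and inflates the
group-contrast SE by √VIF ≈ 1.22 — a property the synthetic generator
compensates for explicitly (see §7).

## 2. Spatial PLS (`pls_spatial`)

With X the parcel × gene expression matrix (columns z-scored; constant
columns zeroed with a log entry) and y the z-scored t-map, PLS1's weight
vector is w ∝ Xᵀy — verified against both scikit-learn's NIPALS
implementation and a brute-force eigendecomposition of Xᵀy yᵀX on small
instances. `variance_explained[c]` is the R² increment of y regressed on
score columns 1..c; for the first component this equals
corr(Xw, y)² to 1e-10 (an asserted identity). The PLS1 sign is fixed so
corr(scores, y) ≥ 0. Default 15 components are fitted for the
scree-style output; only PLS1 feeds downstream.

**Spin test.** Each of `n_spins` (default 1000) draws a Haar-uniform
rotation (QR of a Gaussian 3×3 with sign fix, determinant forced +1),
rotates the centroids, and gives each parcel the y value of its nearest
*original* centroid (many-to-one allowed; the identity rotation is the
identity assignment). The statistic — PLS1 variance explained by
default, the score–map correlation optionally — is recomputed with X
fixed, and p_spin = (1 + #{perm ≥ obs}) / (1 + n_spins) (add-one, never
zero). Rotating centroids and pulling from the nearest original (rather
than the reverse) is fixed as the convention because the two directions
differ in duplicate handling. Null calibration is checked marginally —
X redrawn per simulation — because the rejection rate conditional on one
fixed X draw legitimately varies around the nominal level.

**Bootstrap Z.** Parcels are resampled with replacement; PLS1 is refit
per resample; each bootstrap vector is sign-aligned to the original
(flipped when the dot product is negative); SE is the per-gene bootstrap
SD; Z = w/SE with two-sided normal p and BH q over all genes (the
"all genes" choice is recorded in output metadata). Weights are kept on
the **covariance scale** (Xᵀy/n) rather than unit-normalised per fit:
the vector norm of a resampled fit is inflated by duplicated parcels
(E[multiplicity²] = 2 − 1/n), and normalising by it would shrink the
bootstrap SD by ≈ √2 and mis-calibrate null-gene Z. With this scaling,
i.i.d. null genes exceed |Z| > 3 at close to the normal-tail rate;
spatially smooth null genes exceed it more often — by design the
bootstrap prices in parcel sampling noise, not spatial autocorrelation,
which is the spin test's job. Degenerate resamples (constant y) are
redrawn and counted. Bootstrap normalisation (rather than a
permutation-based normalisation) is the default because it produces the
Z-score semantics the reported gene lists use; the |Z| > 3 & q < 0.05
partition defines PLS1+/PLS1−, sorted by |Z|.

## 3. Differential methylation (`dmp_analysis`)

Per-CpG GLM on beta values with age, gender, education and medication
as covariates (TIV is a brain-volume covariate and is excluded here).
An M-value mode (logit₂ of beta) is available because beta-scale
variance shrinks near 0/1. The default discovery rule is nominal
p < 0.05 restricted to promoter CpGs — at epigenome scale a strict FDR
at n ≈ 100–300 leaves almost nothing, and the promoter-restricted
nominal rule matches the scale of candidate-gene counts this design
produces; FDR mode is one flag away and both choices are logged.
Δβ is the covariate-adjusted group coefficient (equal to the raw group
mean difference to 1e-10 when no covariates are supplied); direction is
hyper/hypo by its sign. CpGs without gene annotation are dropped from
the gene roll-up with a logged count.

## 4. Integration and principal-component regression (`integration_pcr`)

Overlap is an exact set intersection. Enrichment is the one-sided
hypergeometric upper tail per pathway with BH q; pathway members outside
the declared universe are dropped with a log entry. Features are the
DMPs whose gene is in the overlap pool **and** in at least one enriched
pathway (q < 0.05), sorted by cpg_id; an empty feature set raises an
explanatory error (the orchestrator records it and reports a clean
"nothing to model" run rather than crashing).

PCA of the patient × feature beta matrix (centered, optionally scaled)
keeps the smallest k with cumulative explained variance ≥ 0.80;
loadings are orthonormal right singular vectors with each vector's
largest-|value| element forced positive so component orientation is
reproducible. Reconstruction at rank k equals the Eckart–Young optimum
(asserted against a brute-force SVD).

**Stepwise regression and region-level inference.** Model building is
classical forward-entry (best candidate enters while its partial-F p <
0.05) with backward removal (p > 0.10). The final model's F p-value is,
however, not a valid region-level test after selection: with ~25
candidate components, pure-noise regions would be declared significant
in the majority of runs. The region-level p used for FDR across regions
is therefore the *selection-adjusted* first-entry p,
p_model = 1 − (1 − min_j p_j)^k over the k offered components — a Šidák
correction that is exact under orthogonal component scores (PCA scores
are orthogonal in-sample) and calibrates at 0.05 ± 0.02 under the null.
Both p-values are reported; a region is "significant" when its BH q on
p_model is below α and the model is non-empty. This is the package's
resolution of an inherent tension between classical stepwise thresholds
and calibrated region-level FDR; the naive F and its p remain in the
output for comparability.

**LOOCV.** The entire PCA + stepwise chain is refit on each training
fold by default, so the held-out patient never leaks into the component
space; a fixed-components mode reuses one PCA (the cheaper literal
protocol). Folds with empty selection predict the training mean
(counted). The summary is Pearson r between observed and predicted with
its two-sided p.

**Top-weight DMPs.** Per significant region, weight(dmp) =
Σ_c |loading(dmp, c) × standardised coefficient(c)| over that region's
selected components; entries above 0.2 are reported with gene and
region, sorted descending. The composite (loading × standardised
coefficient, summed) is this package's concrete definition of a
"summed component weight" — the underlying quantity is not otherwise
pinned down — and is recorded in the output. When a region's top-weight
table has fewer than three expression-annotated genes (common at desk
scale), the orchestrated coupling stage falls back to the region's full
feature set, logged and labelled `all_features` in the report.

**Clinical models.** Four stepwise fits on patients — HAMD and HAMA,
each on the DMP components and on the significant regions' GMV — with
the same selection-adjusted significance rule. A constant response
raises a degenerate-response error.

## 5. Methylation–expression coupling (`meth_expr_link`)

Per region: per-gene mean beta (patient mean over the gene's top DMPs,
then mean over those CpGs), paired with the gene's regional expression;
Spearman ρ with average-rank ties (Pearson co-reported on request);
permutation null built by uniformly permuting the gene pairing —
not by spinning, because the test runs across genes within one region.
The default tail is the "one-way cumulative probability" in the
direction of the observed sign, matching the reporting convention this
analysis style uses; note that choosing the tail after seeing the sign
is anti-conservative by up to 2× under the null, so fixed tails
(`"left"`, `"right"`, `"two"`) are provided, and the calibration test
uses a fixed tail. All p estimates are add-one. The permutation p
matches exhaustive enumeration at n = 5 genes within Monte-Carlo error.
Gene classes for the map-level check are split by the sign of the PLS
bootstrap Z; each class's mean expression map is Pearson-correlated
with the t-map, plus a pooled gene × parcel long-format correlation
(the exact aggregation is a documented choice).

## 6. Orchestration (`cli_io`)

A single strict-schema YAML config (unknown keys rejected, all
violations reported at once) drives `run_all`. One root seed fans out
through `numpy.random.SeedSequence(entropy, spawn_key=(stage_index,))`
to fixed per-stage substreams — recorded in the run report — so adding
or skipping a stage never shifts another stage's stream. All outputs are
text (CSV/TSV/GMT/JSON) at 12 significant digits; two runs with the
same config and seed are byte-identical apart from the report's
`timing` block and output paths. Thresholds default to the printed
analysis settings: |Z| > 3, 80% cumulative variance, composite weight
0.2, α = 0.05, 5,000 coupling permutations.

## 7. The synthetic study generator (`synthetic_data`)

The generator emulates the full data constellation of a two-group
imaging-epigenomics study at a desk scale of 180 parcels, 2,000 genes,
20,000 CpGs and 60 + 60 subjects (a `paper_scale()` constructor gives
10,027 genes and 269 + 416 subjects).

* **Geometry.** Parcels are a Fibonacci lattice on the unit sphere under
  a seed-determined random rotation: deterministic, pairwise distinct,
  evenly spaced.
* **Spatial fields.** Gene expression maps and null maps are draws from
  a Gaussian process with covariance exp(−d/κ) on geodesic distance
  (κ = 0.5 rad by default; one smoothness knob, any positive-definite
  kernel would serve), standardised per draw; a jittered Cholesky is
  reused across draws.
* **Planted deficit.** `effect_parcels` defaults to a contiguous cluster
  of 15 (≈ 8% of cortex, chosen so the FDR threshold's adaptivity gives
  stable per-parcel recall). Cases lose `gmv_effect_size` (default 0.8)
  × the covariate-adjusted residual SD × √VIF of the group column — i.e.
  the effect size is defined on the scale of the adjusted group
  contrast, the quantity the downstream test actually estimates. Without
  the √VIF term the medication–group collinearity (48% of patients
  medicated, none of the controls) silently shrinks the realised
  noncentrality from ≈ 4.4 to ≈ 3.6.
* **Expression coupling.** The first `n_coupled_genes` (100) are mixed
  with the standardised deficit pattern as
  x = ±r·pattern + √(1−r²)·GP with r = `coupling_r` (0.6), alternating
  sign so both PLS tails are populated; the mixture weight is solved
  analytically so the expected spatial correlation is exact — no
  iterative tuning.
* **Methylation.** Beta values are simulated on the logit scale
  (baseline N(0, 1.5); mid-range N(0, 0.6) for true DMPs so the shift
  is representable) with subject noise SD 0.12, giving within-group
  beta SDs of ≈ 0.02–0.05 as on real 850K arrays. True DMPs (50) are
  annotated to distinct coupled genes with promoter flags set, receive
  a case shift mapped locally so the *beta-scale* difference is exactly
  ±`dmp_delta_beta` (0.05; a shift that would push a mean outside (0,1)
  is rejected), and load (0.10) on the subject latent factor.
* **The PCR plant.** One latent factor u per subject, orthogonalised to
  the group contrast (so the deficit and the methylation–GMV association
  stay separate by construction and neither group test is confounded),
  enters both the true DMPs and the effect parcels' GMV; the GMV loading
  is λ = r/√(1−r²) × the empirical parcel SD so corr(GMV, u) =
  `pcr_signal_r` in expectation. The default 0.6 comes from a design
  power analysis: the stepwise stage runs within the 60 patients only
  and its selection-adjusted test needs a realised per-region
  correlation ≳ 0.45, so with sampling SD ≈ 0.1 a planted 0.6 yields
  per-region power ≈ 0.9–0.95, where 0.4–0.5 would leave recovery near
  chance of the stated targets. HAMD in patients carries the same
  latent at `clinical_signal_r` (0.6); HAMA is generated independent of
  everything as a built-in negative control.
* **Pathways.** 50 sets of 40 genes; 5 designated sets contain
  `fold` × the uniform-expected number of true-DMP genes (fold = 10,
  ≈ 10 planted genes per enriched set — enough for the hypergeometric
  tail to be unambiguous at a 2,000-gene universe); fold ≤ 1 produces
  pure null sets.

Identical configs (including seed) give byte-identical studies on disk;
all randomness flows through `SeedSequence` substreams.

**What the generator does not emulate** — and therefore what passing
tests do *not* establish about real data: measurement artefacts and
batch effects, cell-type composition in blood methylation, probe
cross-reactivity, non-Gaussian GMV distributions, site effects,
genuine biological pathway structure, spatial non-stationarity of
cortical expression, and any causal ordering between methylation,
expression and anatomy. Recovery results show the *pipeline's
statistics behave as designed under their own model*, not that the
biological conclusions of any particular cohort are correct.

## 8. Problem sizes in the test and acceptance suites

Chosen so the full suite runs in minutes on one core: module tests use
a 120-parcel / 300-gene / 2,000-CpG / 60+60-subject study; null
calibrations use 500 simulations each (2,000 vectorised response
columns for the mass-GLM checks, 200 spins × 500 sims at 60 parcels,
199-permutation coupling tests); planted-effect recovery runs the
default 180-parcel scale for seeds 1–20 with 300 spins and 300
bootstraps per run; the acceptance script uses the full defaults
(1,000 spins, 1,000 bootstraps, 5,000 permutations). Recovery
thresholds are evaluated as mean per-entity recall across seeds — the
only coherent reading, since all-entities-per-run joint power is below
any stated target even at ideal noncentrality.

## 9. Known limitations

* The spin test requires genuine spherical centroid geometry; arbitrary
  (e.g. volumetric) parcel coordinates violate its null.
* The selection-adjusted SMLR p is exact only for orthogonal predictors
  (true for in-sample PCA scores) and is mildly conservative when the
  shared residual variance couples the component t-statistics.
* Bootstrap gene Z treats parcels as exchangeable; it quantifies
  sampling noise, not spatial autocorrelation (see §2).
* At desk scale the composite-weight threshold of 0.2 passes few DMPs,
  so the orchestrated coupling stage frequently uses its documented
  full-feature fallback.
* The observed-sign permutation tail mirrors the field's reporting
  convention but is anti-conservative under the null; use a fixed tail
  for calibrated inference.
* Cell-type correction, M-value-based discovery pipelines, and
  right-hemisphere analyses are out of scope.
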