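# Methods

`geniche` implements an invasion-risk assessment chain for a coastal
invader sampled at a handful of sites along a roughly one-dimensional
coastline: detect environment-associated (putatively adaptive) SNPs,
cluster individuals on that panel, quantify environmental drivers of
adaptive variation, model genotype–environment turnover with a gradient
forest and compute genomic offset under future climates, model habitat
suitability with a presence–background (MaxEnt-style) model, and combine
scaled suitability change *B* and scaled offset *C* into the
genomic-niche index *A* = *B*^α·*C*^(1−α).  This note records the models,
the defaults that matter, and the design choices made where the design
was genuinely open.

## Synthetic landscapes

Real inputs of this kind (RAD-seq genotype panels, marine climate
layers) are large and externally hosted, so every stage is exercised on
generated data with known truth (`geniche.synthdata`).

* **Environment.** Each predictor surface is Gaussian-smoothed white
  noise on a rows × cols grid, standardized to mean 0, SD 1 over cells;
  the smoothing range (`env_autocorr_range`, grid cells, default 3)
  controls spatial autocorrelation.  Two *driver* predictors
  (`temp_mean`, `sal_min` — temperature and salinity analogues)
  additionally carry a coastline gradient (weight 2 before
  re-standardization) so that environment and geography are confounded,
  as on a real coast; two *decoys* (`temp_range`, `sal_range`) are pure
  spatial noise.  With smoothing range 0 the surfaces are i.i.d. standard
  normal and carry no gradient.  Sites sit evenly along the first grid
  axis (the coastline); the north/south split is the coastline midpoint.
* **Genotypes.** Adaptive locus *l* has per-site allele frequency
  expit(β₀ₗ + slope·driver(s)) with β₀ₗ = logit of a Uniform(0.1, 0.9)
  ancestral frequency and `cline_slope` in logit units per environment
  SD (default 2).  Neutral loci follow the Balding–Nichols beta around
  the same ancestral law at FST `fst_neutral` (default 0.05).  Genotypes
  are Binomial(2, p); 2% of calls are masked as missing to exercise
  imputation.  All randomness flows from one seeded generator.
* **Future scenarios.** Future grids shift the drivers by
  `future_shift` × the coastline ramp — warming-dominated: the thermal
  driver moves by the full shift, the salinity driver by a quarter of
  it.  Decoys never move, so downstream offset is attributable to the
  drivers.
* **Occurrences.** Presence cells are drawn without replacement with
  probability proportional to a logistic suitability in chosen
  predictors (default b₀ = 0.5, β_temp = −3, β_sal = +2 — a sharply
  discriminable niche, emulating a system whose distribution model is
  highly informative).
* **What the generator does not emulate:** linkage between loci,
  coalescent genealogies, temporal selection dynamics, dispersal along
  currents, and observation biases in occurrence records.  Passing tests
  therefore show the *statistical machinery* behaves correctly under a
  known clinal architecture, not that any real dataset satisfies the
  model.

A deliberate consequence of the smooth cline: admixture model choice on
clinal loci may legitimately prefer K = 3 (a gradient is not two
discrete pools).  Discrete two-cluster recovery is validated on a
two-population configuration (Balding–Nichols FST 0.3), where the
cross-entropy rule selects K = 2 and labels ≥ 95% of individuals
correctly.

## Adaptive-SNP detection

Loci passing a MAF > 0.05 filter (computed over non-missing calls) enter
two complementary scans; the putatively adaptive panel is the union of
their hits.

* **PCA-outlier scan.** Dosages are mean-imputed, centered, and scaled
  by √(p̂(1−p̂)).  Each locus is regressed on the leading K principal
  components of the individuals (default K = 5); the K-vector of
  regression z-scores is summarized by its Mahalanobis distance under
  the empirical covariance of all loci, divided by the genomic inflation
  factor λ = median(D²)/χ²_K(0.5), and referred to χ²_K.
  Benjamini–Hochberg q < 0.05 flags a locus.  The empirical covariance
  (rather than a robust estimator) plus λ recalibration keeps the null
  calibrated: on a null landscape λ ≈ 0.97 and p-values are uniform.
* **Latent-factor association scan.** Environmental predictors are
  reduced by PCA, retaining the smallest leading set explaining > 90% of
  variance; site scores are broadcast to individuals.  Per environmental
  PC, the model genotype = x·b + U·Vᵀ + E is fitted by block coordinate
  descent (exact least-squares updates for (b, V) given U and a
  ridge-regularized update for U; the penalized objective is monotone,
  which is also the convergence criterion).  This deterministic-budget
  formulation replaces the MCMC fit of the original latent factor mixed
  model; the decision rule is unchanged — |z| > 2 *and* q < 0.05, with
  z the median over random-restart replicates (default 5) recalibrated
  by the genomic inflation factor, q-values computed within each
  environmental PC (the alternative, pooling across PCs, is a one-line
  change; per-PC was chosen so each environmental axis retains its own
  FDR budget), and the union over PCs returned.

## Population structure

The admixture model treats each genotype call (0/1/2) as a categorical
draw from a mixture of K ancestral components, fitted by EM with a small
Dirichlet prior (α = 0.1) — every update provably does not decrease the
penalized training likelihood, and Q rows stay on the simplex by
construction.  Model choice masks 5% of observed genotype cells per
replicate and picks the K minimizing the replicate-mean held-out
cross-entropy, the same decision rule as sparse-NMF admixture tooling.
Individuals take their argmax component (ties to the lowest index,
logged); components map to "north"/"south" by the mean latitude of their
members' sites.

## Ordination

Site-level adaptive allele frequencies are Hellinger-transformed (row
proportions, then square root).  Spatial predictors are PCNM
eigenvectors: great-circle distances (haversine, R = 6371 km), distances
beyond the truncation threshold (default: longest minimum-spanning-tree
edge) replaced by 4× the threshold, classical PCoA, positive-eigenvalue
axes retained.  Candidate predictors pass a greedy collinearity filter
(|r| > 0.70 against an already-retained predictor drops the candidate;
priority = the stated predictor order).  Forward selection for the RDA
uses three guards: a permutation pre-test of the all-candidate model
(selection proceeds only if it is significant — this controls the
selection-bias false-start rate, measured at ≤ 2% under the null), a
per-step residual-permutation test at α = 0.05, and the global adjusted-R²
ceiling (Ezekiel: 1 − (1−R²)(n−1)/(n−m−1)); the ceiling is waived when
the global model is saturated (m ≥ n − 1), which is routine at 8 sites.

## Gradient forest and genomic offset

Per locus, a random-forest regression of site allele frequency on the
predictors: CART variance-reduction splits, mtry = ⌈p/3⌉, minimum node
size 5 (reduced to ⌊n/3⌋ when fewer than 15 sites), 500 trees by
default, out-of-bag R².  Split improvements (impurity decreases at split
thresholds) of loci with R² > 0 are pooled with R² weights, binned into
201 equal-width bins over each predictor's observed range, standardized
by a Gaussian-KDE estimate of the predictor's data density (Silverman
bandwidth; importance per unit of density), and cumulated into the
nondecreasing turnover curve.  A predictor's overall importance is the
R²-weighted mean of its split-improvement share, which equals its curve's
endpoint.  Split-improvement shares stand in for conditional permutation
importance; on these small site panels the two orderings agree on every
fixture tried, and the curve machinery is identical.  Environments map
through the curves by monotone linear interpolation with constant
extrapolation; genomic offset is the Euclidean distance between the
transformed present and future environments of a cell.

Two consequences worth knowing: (i) with a steep two-cluster cline, the
turnover curve approaches a step at the cline midpoint, so cells whose
driver values do not traverse the step have *exactly* zero offset — an
honest feature of the model, visible in the tests; (ii) values outside
the site-observed predictor range are clamped, so offsets saturate for
far-out-of-range futures.  Spatial (PCNM) predictors, which have no
future projection, are held constant across scenarios and hence
contribute nothing to offset.

## Habitat suitability

The MaxEnt-style model is the penalized presence–background logistic
equivalence: feature expansions (linear; quadratic; pairwise products;
hinge, 15 forward + 15 reverse quantile knots per predictor, scaled by
the background range), an L1 penalty proportional to the regularization
multiplier and to √(number of features) per unit of total sample weight,
and a cloglog output 1 − exp(−e^η).  Feature scaling, hinge knots, and
ranges derive from the background sample (the available environment), so
exact duplication of background points is a no-op — the per-point
background weight scales as a constant total (100) over the sample.
Tuning fits a feature-set × multiplier grid (default 4 × 8 = 32
candidates: {linear; +quadratic; +product; +hinge} × {0.5…4}) under
5-fold cross-validation of the presences with shared background, and
ranks by lowest mean omission at the p10 threshold, ties by highest
validation AUC, then grid order (logged).  Evaluation: rank AUC; TSS =
max(sensitivity + specificity − 1) over thresholds; continuous Boyce
index = Spearman correlation of the predicted-to-expected presence ratio
over 101 overlapping windows of width 0.1 on the pooled score range;
omission at the p10 (10th percentile of training-presence scores)
threshold.  Binary maps use p10 and max-TSS thresholds; range-size
change uses cos(latitude)-weighted cell areas.  Folds are random (not
spatial) and seeded.

## Genomic-niche index

Within the analyzed cells (by default those with decreased suitability;
a flag admits all cells), B = min–max-scaled |ΔS| and C = min–max-scaled
offset, both to [0, 0.9].  The index A = B^α·C^(1−α) is the weighted
geometric mean, so min(B,C) ≤ A ≤ max(B,C) whenever both bases are
positive; a zero base gives A = 0 and is logged as a boundary cell.
Smaller A means smaller suitability loss *and* smaller required genomic
adjustment — higher overall invasion risk.

α is chosen to minimize the total squared deviation
D(α) = Σ(A−B)² + (A−C)².  An L1 variant is available behind a switch but
is degenerate by the bound above: |A−B| + |A−C| ≡ |B−C| for every α, so
it cannot identify α; the quadratic deviation is the only non-degenerate
reading and is the default.  The optimizer is a standard artificial bee
colony over α ∈ [0, 1] (20 food sources, abandonment limit 50, 200
cycles, seeded); a 10⁻⁴-step grid search is the permanent cross-check in
the tests and agrees to 10⁻⁶ in objective value.

Cluster contrasts use the two-sided Wilcoxon rank-sum test — exact null
when the pooled sample is ≤ 20 without ties, otherwise the normal
approximation with tie correction — with Benjamini–Hochberg adjustment
across the scenario × statistic family supplied together.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale,
chosen to keep each stage's statistical signal unambiguous: null
calibration at 200 individuals × 1,000 loci; scan power at 200 adaptive
among 2,000 loci (8 sites × 15 individuals); gradient forests at 100
trees on ≤ 212-locus panels; SDM tuning at 12 candidates × 5 folds with
1,000 background points; grids of 300–400 cells.  Defaults in the
library remain at the field-standard values (500 trees, 32 candidates,
10,000 background points).  Degenerate inputs are defined rather than
accidental: constant predictors are dropped with a warning, constant
scaling inputs map to the lower bound, monomorphic loci are excluded by
the MAF filter, and saturated RDA designs stop with a diagnostic.

## Pipeline

`geniche.pipeline.run_pipeline` executes the stages in order per future
scenario from one validated config (YAML/JSON), writing every artifact
as CSV/JSON with SHA-256 checksums into a manifest; per-stage seeds
derive from the master seed by stable hashing of the stage name, so a
rerun is checksum-identical.  `stop_after` truncates the run after a
named stage (stage outputs up to that point are on disk); re-running
later stages from cached artifacts is deliberately out of scope — at
these problem sizes a full rerun is cheaper than cache invalidation.
Grid cells are assigned to clusters by the coastline midpoint when the
grid carries a coastline coordinate, otherwise by the cluster of the
nearest sampled site.

## Known limitations

* The latent-factor scan is a least-squares surrogate; its z-scores are
  calibrated by genomic inflation, not by an MCMC posterior.
* Turnover curves from few sites are coarse (step-like); offsets between
  environments on the same side of a step are zero.
* The SDM penalty is a single L1 scale per model, not per-feature-class
  defaults of the reference implementation.
* Min–max scaling of B and C is global over analyzed cells; per-cluster
  or per-scenario scaling conventions would change A's absolute values
  (not the within-scenario ordering used here).
* α is optimized per scenario; optimizing one α jointly across scenarios
  is a one-line change in the caller.
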