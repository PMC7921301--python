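# Methods

This note documents the models, estimators, calibration choices and
numerical details behind `lolium`, and what the synthetic-data tests do
and do not demonstrate about real data.

## FvCB model and temperature scaling

Net assimilation is modelled as the pointwise minimum of the
Rubisco-limited and RuBP-regeneration-limited branches (no
triose-phosphate-use branch; TPU-affected points are excluded rather
than fitted, and mesophyll conductance is not modelled, so C_i stands
in for chloroplastic CO₂). Mole fractions (µmol mol⁻¹) are used
throughout; at 1 atm they are numerically interchangeable with partial
pressures in µbar.

Kinetic constants default to the Bernacchi in-vivo values at 25 °C
(K_C = 404.9 µmol mol⁻¹, K_O = 278.4 mmol mol⁻¹, Γ* = 42.75 µmol mol⁻¹,
O = 210 mmol mol⁻¹) with single-exponential Arrhenius activation
energies (kJ mol⁻¹): K_C 79.43, K_O 36.38, Γ* 37.83, V_Cmax 65.33,
J_max 43.90, R_d 46.39. They live in one editable block
(`fvcb.BERNACCHI_KINETICS_25C`, `fvcb.BERNACCHI_ARRHENIUS`) and can be
replaced from configuration; which exact J_max temperature function a
given lab used is often ambiguous, so the activation-energy form is
deliberately simple and swappable. Scaling uses
exp(ΔH_a (T_t − T_r)/(R T_t T_r)) with temperatures in kelvin, which is
exactly invertible (round-trip identity to 1e−12 is a test).

## A–Ci fitting

Stages: (1) linear leak correction, A_corr = A − k·(C − C_ambient),
with k = 0 by default since leak coefficients are instrument-specific;
(2) TPU-tail exclusion — trailing highest-C_i points are dropped while
the last point lies more than 0.5 µmol m⁻² s⁻¹ below the running
maximum *and* C_i ≥ 800 µmol mol⁻¹ (both thresholds configurable; a
curve left with < 5 points is rejected as unusable); (3) phase
assignment and estimation.

Phase assignment is automated: every contiguous split of the sorted
points into a Rubisco-limited prefix and an RuBP-limited suffix with at
least two points per phase is a candidate, plus the two one-phase
assignments. Manual "initial inspection" assignment is replaced by this
exhaustive enumeration because it is deterministic and checkable: the
selected split provably minimizes the joint SSE over all candidates
(the test suite re-enumerates them independently).

Conditional on a split, the model is *linear* in (V_Cmax, J_max, R_d):
A_i = V_Cmax·f(C_i) − R_d on the prefix and A_i = J_max·g(C_i) − R_d on
the suffix, with f, g known given the kinetics. Each candidate is
therefore solved exactly with bounded linear least squares
(`scipy.optimize.lsq_linear`, BVLS; bounds V_Cmax, J_max > 0, R_d ≥ 0),
which is strictly stronger than iterative nonlinear least squares with
multi-start: it finds the global per-split optimum with no starting
values and no seeds. One R_d is shared across both phases per curve.
Ties between splits go to the smaller transition C_i. For the selected
solution the branch ordering (A_C ≤ A_J on the prefix, the reverse on
the suffix) must hold within 0.5 µmol m⁻² s⁻¹, else the result is
flagged `converged=False` rather than raising. One-phase solutions
report the inactive branch's rate as unidentifiable
(`jmax_identifiable`/`vcmax_identifiable` flags); parameter sets whose
true transition leaves a single point in one phase cannot be
represented by the ≥ 2-points-per-phase candidates and are recovered
only approximately (SSE well below 1 in practice).

Fitted values are reported at leaf temperature and Arrhenius-normalized
to 25 °C; the two are exactly consistent under `arrhenius_scale` by
construction.

## Derived traits

LMA = blade dry mass / blade area; C:N = C_mass/N_mass; WUE_op =
A_op/E (µmol CO₂ per mmol H₂O — the flux-over-flux definition is the
one consistent with those units, which is why the generator emits
transpiration rather than deriving it); LA_tiller =
DW·LMF_ab/(LMA·tillers); A_plant = A_op·DW·LMF_ab/LMA. A_plant assumes
every leaf of the plant receives the measured average irradiance and
photosynthesizes at A_op; this is an acknowledged approximation, not a
canopy model. LMF_ab (aboveground leaf dry-mass fraction) is a
species × treatment constant: perennial 0.66 (ambient) / 0.59 (elevated
CO₂), annual ryegrass 0.57 / 0.53; the hybrid uses the perennial
values. Genotype summaries are means of per-plant values, never ratios
of means — e.g. LA_tiller evaluated at the trait means (≈ 0.00375 m²)
differs from the mean of per-plant LA_tiller (≈ 0.0040 m²), and the
pipeline reports the latter.

## Synthetic-data generator

The generator emulates the study design: 38 genotypes (11 cultivars,
16 semi-natural, 9 wild perennial accessions, plus one annual and one
hybrid), two CO₂ treatments (400 vs 800 µmol mol⁻¹), two chambers per
treatment, five plants per genotype per treatment (≈ 190 per arm), and
an A–Ci subsample of two plants per genotype × treatment carrying
V_Cmax, J_max, R_d and A_sat.

Strictly positive traits are log-normal. Each trait's per-treatment
mean and SD default to the emulated study's summary statistics (e.g.
DW 23.0 ± 10.8 → 33.4 ± 17.5 g; tillers 131 ± 51 → 146 ± 65; A_op
13.5 ± 3.2 → 16.8 ± 3.1 µmol m⁻² s⁻¹; WUE_op 5.0 ± 1.4 → 7.9 ± 2.7).
Two structural knobs per trait govern the hierarchy:

* **genotype fraction** f_g — share of log-variance between genotypes
  (0.65 for growth/morphology traits, 0.10 for A_op, 0.2–0.5
  elsewhere);
* **response concordance** ρ — correlation of a genotype's deviation
  across treatments. Under elevated CO₂ the genotype deviation is
  ρZ + √(1−ρ²)U with U independent, so 1−ρ sets the genotype-specific
  CO₂-response spread while the per-arm mean/SD targets are preserved
  exactly.

The concordance defaults were derived from the precision of the
emulated study's printed treatment comparisons, which bounds the
genotype × treatment interaction noise per trait: leaf composition
responds almost in parallel across genotypes (ρ ≈ 0.95–0.99 — a −4%
N_mass shift detected at t ≈ −5 admits almost no interaction variance),
gas exchange and biochemistry at ρ ≈ 0.9–0.95, and LMA loosest
(ρ = 0.85, matching its non-significant, high-variance response).
Growth traits at f_g = 0.65, ρ = 0.90 make the population-level
genotype-mean concordance of biomass emerge at Spearman ρ ≈ 0.79
(rank-regression R² ≈ 0.62) while A_op, with its small genotype
fraction, lands near 0.3 — the double structure of stable biomass
rankings but labile leaf-rate rankings. One known tension: a Gaussian
log-scale response model cannot simultaneously honour the per-arm SDs,
this concordance, and the most extreme published per-genotype response
ranges (−27% to +280% in DW); the generator prioritizes the SD and
concordance calibration, and its DW responses span roughly −10% to
+190%.

Cross-trait correlations are imposed on the standard-normal deviations
at both levels: tillering vs per-tiller leaf area −0.25 and per-tiller
area vs LMA −0.45 (size–number and leaf-economics trade-offs, solved so
that composed DW reproduces its target CV of ≈ 0.47 and LMA stays
nearly uncorrelated with DW), tillering vs leaf N −0.45 (growth
dilution, making C:N the second-best biomass predictor), conductance vs
WUE −0.75 (the collinear pair), A_op vs WUE +0.3, V_Cmax vs A_sat +0.8,
and J_max = 1.89 × V_Cmax × small noise (the collinear biochemistry
set).

With the mechanistic link on (default), DW is not drawn but composed:
DW = tillers × LA_tiller × LMA / LMF_ab × exp(ε_mech), ε_mech with SD
0.05, with a closed-form log-normal mean correction so E[DW] hits the
configured treatment means despite the covariances. Tiller counts are
rounded (≥ 1); blade dry mass is LMA × blade area exactly;
E = A_op/WUE_op exactly, so every record satisfies the derived-trait
identities to numerical precision. Chamber offsets are N(0, 0.005²) on
the log scale; with only two chambers per treatment a chamber
contribution is inseparable from the treatment effect, so larger
chamber variance would inflate every treatment test — a limitation of
the emulated design itself, not of the estimators.

`null_config()` gives the model-consistent null used for calibration:
ambient means in both arms, ρ = 1, chamber offsets zero, genotype
variance retained.

What passing generator-based tests shows: the estimators recover the
structure they assume (log-normal traits, random genotype intercepts,
multiplicative responses). What it does not show: robustness to real
measurement error structure, non-log-normal trait distributions,
spatial chamber gradients, or genotype-by-chamber interactions, none of
which are simulated.

## Treatment inference

The comparison model is trait ~ treatment + chamber (fixed) +
(1 | genotype), REML. Chambers are nested in treatments, so chamber
enters as centered within-treatment contrasts (sum-to-zero), making the
treatment coefficient the chamber-averaged treatment difference;
a raw four-level chamber factor would be aliased with treatment.

For this single-random-intercept family the REML criterion profiles to
one dimension in the variance ratio γ = σ²_g/σ²_e (fixed effects and
σ²_e have closed forms given γ, via per-group Woodbury identities), so
the fit is a deterministic bounded scalar optimization with an explicit
γ = 0 boundary check. It matches statsmodels MixedLM and R lmerTest
REML estimates to ≤ 1e−6 on test data (frozen reference values in the
suite); it is used directly because it is faster, has no optimizer
fragility, and exposes what Satterthwaite needs.

Satterthwaite degrees of freedom for a contrast c'β: df =
2g²/(∇g'A∇g) with g(θ) = c'(X'V⁻¹X)⁻¹c, θ = (σ²_g, σ²_e), and A the
inverse observed REML information (central-difference Hessian of the
REML log-likelihood, relative step 1e−4, forward-difference fallback at
the σ²_g = 0 boundary). df is clipped to [1, n−p].

Decision tree (diagnostic α = 0.05 throughout): if σ²_g <
1e−8 × σ²_e, plain regression is used, with an HC3 covariance when a
Breusch–Pagan test finds heteroscedastic residuals. Otherwise
Shapiro–Wilk on the conditional (BLUP-adjusted) residuals and Levene by
treatment decide between the plain mixed model and robust
re-estimation. The robust path whitens the data with the exact V^(−1/2)
of the REML fit and re-estimates the fixed effects by Huber
M-estimation (tuning constant 1.345, configurable); its t is reported
with the Satterthwaite df of the regular fit. Because a Huber location
difference is not an estimator of a difference of *means* under skewed
residuals, the GLS estimate and SE are always carried in the
diagnostics; recovery of a configured mean effect is judged against
those.

ANCOVA relationships use the same machinery with the covariate as a
fixed effect; marginal R² = var(Xβ̂)/(var(Xβ̂)+σ²_g+σ²_e) and
conditional R² adds σ²_g to the numerator (variance-components
definition; invariant to affine rescaling of the covariate). Pairwise
status contrasts are Benjamini–Hochberg adjusted within each
treatment's contrast family, not globally. Spearman statistics use
average ranks for ties; the rank-concordance R² is the R² of the
rank-on-rank regression.

The "neat" attribution z-scores all variables, fits the full OLS
regression for standardized coefficients, and reports for each
predictor the drop in R² when it alone is removed. VIF > 10 flags
collinearity but does not auto-remove: which member of a collinear set
is scientifically prior (e.g. C:N over N_mass) is the caller's call,
and the pipeline's default predictor set (tillers, A_op, WUE_op,
C_mass, C:N, LMA) already excludes the derived LA_tiller (a function of
the response) and one member of each collinear pair. Exactly collinear
predictors raise an error naming the offending pair. Durbin–Watson,
Breusch–Pagan, residual normality and maximum Cook's distance are
reported alongside.

Germination tables get Pearson's chi-square without continuity
correction (any 2×k) and Fisher's exact test (2×2).

## Clustering

Genotype × trait mean matrices (complete-case genotypes, z-scored per
trait with sample SD after subsetting) are clustered over a
method × k grid: Ward hierarchical (scipy linkage on Euclidean
distances — the squared-distance Lance–Williams update, i.e. the
classic "Ward.D2" contract, with provably monotone merge heights) and
optionally k-means with 25 seeded restarts. Internal validation:
connectivity with neighbourhood size L = 10 (the cluster-validation
literature's default; configurable), mean silhouette, and Dunn index
(min between-cluster distance / max within-cluster diameter). Solutions
are ranked by silhouette with connectivity as tie-break — one
documented rule rather than a three-metric vote, since the metrics can
disagree; all three are reported per solution. The default trait set is
the eight full-sample traits; subsample-only biochemistry and one
member of each collinear pair are excluded. Intercluster trait tests
follow Shapiro–Wilk → Levene → Student/Welch/Mann–Whitney. Dendrograms
serialize to Newick with merge heights as branch lengths.

## Problem sizes and determinism

Simulation-based checks run at two scales, chosen as the smallest that
make the target statistics stable: study scale (380 plants) for
realization-level behaviour, and population scale (500 genotypes) for
calibration-level quantities such as rank concordance (Monte-Carlo SE
< 0.02 there). Type-I calibration uses 500–1000 null replicates, which
bounds the rejection-rate SE near 0.007. All randomness flows through
explicit `numpy` Generators seeded from user-supplied seeds; the
hierarchical fits, A–Ci fits and Ward clustering are themselves
seed-free and deterministic, and the pipeline stamps every output with
the seed and a configuration hash.

## Known limitations

* C_i is used for leak correction when cuvette CO₂ is not recorded —
  only a proxy for the true gradient.
* The robust mixed estimator is a pragmatic whiten-then-Huber scheme,
  not a full joint robust estimation of variance components.
* Chamber pseudo-replication (2 chambers/arm) is inherent to the
  emulated design; treatment inference is calibrated only under
  negligible chamber variance.
* The generator's Gaussian-on-log-scale response model understates
  extreme per-genotype response tails (see above).
* A_plant inherits the single-irradiance, single-leaf-rate assumption;
  within-canopy light gradients are out of scope.
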