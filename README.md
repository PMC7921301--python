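# lolium

Why do some ryegrass genotypes grow much more than others — and respond
much more strongly to elevated atmospheric CO₂ — when their leaves
photosynthesize at similar rates? `lolium` is an analysis pipeline for
genotype × CO₂ growth-chamber experiments on grasses (perennial ryegrass,
*Lolium perenne*, is the motivating system) built to answer exactly that
kind of attribution question. It is aimed at plant ecophysiologists and
grass breeders who have per-plant trait tables and leaf gas-exchange
curves and want a reproducible inference chain from raw measurements to
"which trait drives biomass".

The pipeline has four scientific layers:

1. **FvCB photosynthesis model and A–Ci fitting.** Net CO₂ assimilation
   of a C₃ leaf is the minimum of a Rubisco-limited and an
   RuBP-regeneration-limited rate,

   $$A_C = V_{Cmax}\frac{C_i-\Gamma^*}{C_i+K_C(1+O/K_O)}-R_d,\qquad
     A_J = J_{max}\frac{C_i-\Gamma^*}{4C_i+8\Gamma^*}-R_d .$$

   A measured A–Ci curve is leak-corrected, trimmed of any
   triose-phosphate-use-limited tail at very high C_i, split into the
   two limitation phases by exhaustive enumeration, and fit by exact
   bounded least squares (the model is linear in
   $V_{Cmax}, J_{max}, R_d$ once the phase split is fixed). Estimates
   are Arrhenius-normalized to 25 °C with the Bernacchi kinetics.
2. **Whole-plant traits.** Leaf mass per area (LMA), C:N ratio,
   water-use efficiency $\mathrm{WUE_{op}} = A_{op}/E$, mean leaf area
   per tiller $\mathrm{LA_{tiller}} = DW\cdot LMF_{ab}/(LMA\cdot
   \mathrm{tillers})$, and whole-plant carbon gain
   $A_{plant} = A_{op}\cdot DW\cdot LMF_{ab}/LMA$.
3. **Inference.** Treatment comparisons with random-genotype-intercept
   mixed models (REML, Satterthwaite degrees of freedom) and a
   documented decision tree (robust Huber re-estimation when residual
   diagnostics fail; plain/heteroscedasticity-consistent regression when
   the genotype variance collapses); mixed-model ANCOVA trait
   relationships with Nakagawa marginal/conditional R²; per-genotype CO₂
   responses and cross-treatment rank concordance; Spearman
   correlograms; multiple-regression "neat" attribution (the ΔR² each
   predictor adds on top of all others) with VIF screening; germination
   contingency tests.
4. **Clustering.** Ward hierarchical clustering of z-scored genotype ×
   trait mean matrices, method/k selection by connectivity, silhouette
   and Dunn index, and per-trait intercluster tests.

Because per-plant raw data from such experiments are rarely published, a
first-class **synthetic-data generator** reproduces the study design
(38 genotypes × 2 CO₂ treatments × 2 chambers × ~5 plants, with genotype
random effects, genotype-specific CO₂ responses, and biomass composed
mechanistically as tillers × leaf area per tiller × LMA), so every stage
is testable end to end.

## Worked example

Run the whole pipeline on a simulated experiment:

```bash
lolium all --seed 1 --out demo/
```

which prints

```
report bundle in demo (seed=1)
DW rank concordance: rho=0.68 R2=0.46
```

— the Spearman correlation between genotype biomass rankings under
ambient and elevated CO₂ for this one simulated experiment (at
population scale the generator's concordance is ≈ 0.79). The treatment
summary (`demo/treatment_summary.csv`) gives Table-style comparisons;
for example:

```
trait         treatment   mean    t_value  p_value   sig  model_path
DW            ambient     19.8    14.2     2.6e-36   ***  robust_mixed
DW            high_CO2    31.2
A_op          ambient     14.2     8.9     3.1e-17   ***  robust_mixed
A_op          high_CO2    17.1
tiller_count  ambient    126.8     3.9     1.0e-04   ***  robust_mixed
tiller_count  high_CO2   140.6
```

so elevated CO₂ raised aboveground dry mass from ~19.8 to ~31.2 g per
plant in this realization, with the robust mixed-model path chosen
because the biomass residuals are right-skewed. The predictor
attribution (`demo/neat_analysis.csv`, ambient arm) shows what drives
biomass differences *between* genotypes:

```
predictor     std_coefficient  delta_r2  vif
tiller_count  0.54             0.200     1.43
A_op          0.08             0.006     1.04
WUE_op       -0.07             0.005     1.09
CN_ratio      0.16             0.016     1.68
LMA           0.24             0.054     1.04
```

Tiller count contributes by far the largest unique ΔR² to biomass,
while the leaf photosynthetic rate A_op contributes almost nothing —
the canopy-size-over-leaf-rate structure the pipeline is designed to
detect.

Individual stages are available as `lolium simulate`, `lolium fit-aci`,
`lolium traits`, `lolium analyze` and `lolium cluster`, or directly as
library functions (`lolium.fit_aci`, `lolium.compare_treatments`,
`lolium.neat_analysis`, ...).

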