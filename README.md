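# bmrscale

Comparative analysis of basal metabolic rate (BMR) scaling across the
six principal endotherm clades — Monotremata, Marsupialia, Eutheria,
Palaeognathae, Neognathae–Non-Passeriformes, and
Neognathae–Passeriformes — for comparative physiologists and
phylogenetic comparative-methods users.

## The model

Metabolic allometry is the power law

    BMR = a · m^b        ⇔        log10 BMR = log10(a) + b · log10(m)

with body mass *m* in grams, BMR in ml O₂/h, scaling exponent *b* and
allometric coefficient *a* (BMR predicted at 1 g). The package:

1. fits clade-level allometries by **OLS**, **WLS** (e.g. species-count
   weights), or **PGLS** with Pagel's **λ** estimated by maximum
   likelihood from a Newick tree (the error covariance is the shared
   root-to-ancestor branch length, off-diagonals scaled by λ ∈ [0, 1]);
2. tests slope homogeneity across clades by comparing three nested
   pooled models with AIC/BIC — one line (M0), common slope with clade
   intercepts (M1), free slopes and intercepts (M2) — and by the
   ANCOVA interaction F-test;
3. refits clade intercepts at the common exponent (the reference value
   for this dataset family is b = 0.7248) and forms the **dimensionless
   BMR ratio** a_clade / a_Passeriformes, a size-free measure of
   metabolic level;
4. regresses the scaling parameters and the BMR ratio on clade
   divergence time (mya), and the ratio against group-mean activity
   duration (24 h − sleep) and body temperature;
5. ships a synthetic-data generator (pure-birth trees, λ-Brownian
   residuals, clade-structured intercepts) so the entire pipeline is
   testable without any external dataset.

Fitted exponents can be tested against the theoretical 3/4 slope with
Welch's *t*-test, and standard errors of *a* are propagated from the
log-space intercept by the delta method: se(a) = a · ln 10 · se(log10 a).

## Worked example

Generate a six-clade synthetic dataset with the default study
conditions (50 species per clade, shared exponent 0.7248, residual sd
0.08 on log10 BMR, λ = 0.6 on one shared tree) and run the pipeline:

```python
from bmrscale import *

table, tree, truth = generate_dataset(default_config(seed=11))
comp = fit_pooled_models(table)
print(f"best model by BIC: {comp.best_by_bic}")
print(f"common slope b = {comp.common_slope:.4f} +/- {comp.common_slope_se:.4f}")

ratios = bmr_ratio_table(refit_groups(table, comp.common_slope),
                         "Passeriformes", common_b=comp.common_slope)
for row in sorted(ratios.rows, key=lambda r: r.ratio):
    print(f"{row.group_label:18s} a={row.a_common:5.2f}  ratio={row.ratio:.3f}")

fit = regress_on_divergence(ratios.ratios(), builtin_group_meta(), "bmr_ratio")
print(f"ratio vs divergence time: slope={fit.slope:.4f}/mya  "
      f"R2={fit.r2:.3f}  p={fit.p:.4f}")
```

Output:

```
best model by BIC: M1
common slope b = 0.7252 +/- 0.0036
Monotremata        a= 1.68  ratio=0.253
Marsupialia        a= 2.69  ratio=0.405
Palaeognathae      a= 3.37  ratio=0.508
Eutheria           a= 3.80  ratio=0.574
Non-Passeriformes  a= 4.32  ratio=0.651
Passeriformes      a= 6.63  ratio=1.000
ratio vs divergence time: slope=-0.0037/mya  R2=0.851  p=0.0088
```

BIC correctly prefers the common-slope model, the recovered exponent
sits on the generating 0.7248, the ratio series spans the generated
0.26 → 1.00 range, and the ratio declines by about 0.004 per million
years of clade age — older clades have lower size-corrected metabolic
levels.

The same pipeline is available from the shell:

```sh
bmrscale simulate --seed 11 --out-prefix demo
bmrscale run --species demo_species.csv --tree demo_tree.nwk --out-dir results/
bmrscale fit --species demo_species.csv --method pgls --tree demo_tree.nwk
```

Real data enter as a CSV with headers `species,group,mass_g,bmr_mlO2_h`
plus an optional Newick tree whose tip labels match the species column
(underscores and spaces are interchangeable), and a group-metadata CSV
(`group,mya,sleep_h,tb_c,n_species`); a packaged nine-clade metadata
table is used when none is supplied.

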