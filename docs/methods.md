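# Methods

This note documents the statistical model behind `bmrscale`, the
conventions and numerical choices the implementation commits to, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Allometric regression

All regressions operate on base-10 logarithms of body mass (g) and BMR
(ml O₂/h); natural logs are never exposed. OLS and WLS use the
classical closed-form estimators with residual variance on n − 2
degrees of freedom and no small-sample corrections. WLS weights are
normalized internally to mean 1, so fits are invariant to rescaling all
weights by a constant, and integer weights reproduce OLS on the
correspondingly replicated dataset. The allometric coefficient is
a = 10^intercept by construction, with the delta-method standard error
se(a) = a · ln 10 · se(intercept); this linearization is accurate to a
few percent for the intercept uncertainties met here (checked by Monte
Carlo in the tests). Tests of a fitted exponent against the theoretical
3/4 treat the reference as an exact constant (one-sample t on the fit's
residual df); comparisons of two fitted slopes use Welch–Satterthwaite
df. All p-values are two-sided with significance at 0.05.

## PGLS and Pagel's λ

The Brownian-motion covariance of tip values is C(i, j) = depth of the
most recent common ancestor of tips i and j, with root-to-tip distances
on the diagonal. Trees need not be ultrametric; the diagonal keeps the
actual root-to-tip distances. Pagel's λ multiplies the off-diagonal
entries only and is restricted to [0, 1]; no extension past 1 is
offered even when the profile likelihood is still increasing at the
boundary. Polytomies are accepted (they only flatten the covariance).

GLS estimation solves the whitened least-squares problem through a
Cholesky factorization of C; an explicit inverse is never formed, and
the results agree with the textbook (XᵀC⁻¹X)⁻¹XᵀC⁻¹y formula to 1e-10
(tested). The residual variance is profiled by maximum likelihood
(σ̂² = rᵀC⁻¹r / n — ML, not REML), and the log-likelihood carries the
log-determinant of C. λ is estimated by scanning a 0.01-step grid on
[0, 1] and refining around the best grid point with a bounded scalar
search to 1e-6; the returned optimum is guaranteed to be at least as
good as every grid point. Coefficient standard errors use the unbiased
residual scale (n − 2).

Two conventions the source material leaves open are fixed here:

* **PGLS R²** is computed in the whitened space as 1 − RSS_w/TSS_w,
  with TSS taken about the GLS-estimated mean of the response.
* **Tip matching** between species tables and trees is exact after
  normalization (trim, collapse whitespace, underscores ↔ spaces);
  unmatched names on either side are reported and dropped, never
  fuzzy-matched.

Root-to-tip paths of zero length are jittered by 1e-8 × tree depth
before inversion, with a warning. PGLS refuses fewer than 4 matched
species (a 3-species clade such as the monotreme sample cannot support
a λ estimate, which is why such fits carry undefined uncertainties in
published tables).

## Slope homogeneity and the BIC convention

Three nested pooled OLS designs are compared: M0 (single line), M1
(common slope, clade intercepts), M2 (free slopes and intercepts). The
Gaussian log-likelihood with profiled variance is
lnL = −(n/2)(ln(2π·RSS/n) + 1), and the parameter count includes the
residual variance (k = coefficients + 1), matching R's `stats::AIC`/
`BIC` on `lm` objects — verified against `Rscript` in the test suite,
since any published BIC value is only meaningful under a stated
convention. BIC ties closer than 1e-9 go to the simpler model. Slope
heterogeneity is additionally tested by the M2-vs-M1 F statistic
[(RSS₁ − RSS₂)/Δdf] / [RSS₂/df₂]. Groups with fewer than 2 species are
excluded with a warning. The M1 shared slope equals the within-group
(demeaned) regression slope by the Frisch–Waugh–Lovell theorem, which
the tests use as an independent oracle.

## Common-slope normalization and the BMR ratio

With the slope fixed at b, the per-clade intercept is the mean of
y − b·x; its standard error is the sample sd of those offsets over √n
(the source analyses do not state an SE convention for the refitted
coefficient, so this residual-based choice is flagged in output
metadata). R² about the constrained line can be below the free-slope
R². The dimensionless ratio divides each clade's a_common by the
reference clade's (Passeriformes by default, configurable); the
reference ratio is exactly 1, ratios are invariant to the BMR unit, and
rounding to 3 decimals happens only at the presentation layer.

## Group-level correlates

Second-stage regressions (coefficient, exponent, or ratio vs divergence
time; activity or body temperature vs ratio) are plain OLS at the
group level, optionally WLS with species-count weights; no phylogenetic
correction is applied at the 6–9 group scale. Activity duration is
24 h minus sleep duration. Monotremata is excluded from exponent-vs-time
regressions (its 3-species slope estimate is not meaningful).
Slopes are reported with their fitted signs; the BMR ratio declines
with divergence time, so its regression slope is negative and analyses
that quote the magnitude use |slope|. The generic
`regress_paired_difference` utility regresses per-clade OLS-minus-PGLS
parameter differences on λ̂ to quantify how phylogenetic signal moves
the coefficient estimates.

### Packaged group metadata

The nine-clade metadata table stores divergence times (465, 365, 322,
217, 193, 115, 110, 90, 50 mya) and extant species counts. The
monotreme divergence is stored as 217 mya — the value entering the
cross-clade regressions — with the alternative molecular estimate
(271 mya) exposed as a named constant. The sleep-duration and
body-temperature columns are **reconstructed group means**: the
underlying compilations report per-species values and the group means
are not printed anywhere, so the fixture carries synthetic summaries
chosen to respect the documented constraints (mammals sleep ≈ 40%
longer than birds; body temperature rises from 32 °C in monotremes to
≈ 40 °C in passerines). Regressions on these two columns therefore test
the machinery and the documented directions, not exact published
coefficients. Missing values (ectotherm sleep/temperature) are explicit
nulls, never zeros.

## Synthetic data generator

`generate_dataset` draws, per clade: log-uniform masses within the
clade's observed log10 range; log10 BMR = log10 a(clade) + b·log10 m
plus a residual from a multivariate normal with covariance
σ² · λ-transform of the tree covariance. Defaults are the study
conditions: the six published clade coefficients at the common slope
(1.63 … 6.18), shared exponent b = 0.7248, σ = 0.08 on log10 BMR,
λ = 0.6, 50 species per clade; `compilation_scale_config` keeps the same
structure at the 1817-species compilation's clade sizes (3/84/730/9/
404/587). Trees are pure-birth (Yule) with exponential waiting times at
total rate equal to the number of extant lineages, rescaled to unit
root-to-tip depth so that σ² is directly the tip-level residual
variance. One tree spans all clades, each clade a monophyletic subclade
hanging off a short pectinate backbone (so between-clade covariance
exists); `shared_tree=False` attaches the clades at the root instead,
giving block-diagonal covariance. Phylogenetic structure is applied to
the BMR residuals only — masses are fixed covariates, matching the
PGLS model being fitted. All randomness flows from one integer seed
through a single `numpy` generator.

What the generator does **not** emulate: measurement error in mass,
unbalanced within-clade tree shape from real diversification,
non-Brownian trait evolution (no Ornstein–Uhlenbeck, no κ/δ), body-mass
phylogenetic structure, and intraspecific variation. Passing recovery
tests therefore demonstrate correctness of the estimators under the
assumed model, not robustness to these real-data features.

### An irreducible limit of ratio recovery

Under the default conditions the clade-mean residual does not average
out: tips within a clade share deep branches, so each clade's intercept
estimate carries an O(σ√(λ·shared-depth)) random offset (~0.03–0.05 in
log10 units) that no estimator can remove. Two clades whose true ratios
differ by less (Eutheria 0.571 vs Palaeognathae 0.532) consequently
swap order in a substantial fraction of replicates, and single-run
ratio errors up to ~0.2 occur under the default conditions. Recovery
tests therefore assert the ordering of clades separated by more than
0.1 in true ratio (recovered in ≥ 95% of replicates) and an error
envelope of 0.25, rather than an unattainable exact ordering. The model-selection and ANCOVA calibration simulations use
iid residuals (λ = 0) so that the generating model is exactly M0, M1,
or M2 — with λ > 0, clade-mean offsets make M1 the genuinely better
description of data generated from a single line, which would
mis-specify the null being tested.

## Problem sizes used in checks

Simulation-based checks use: 200 replicates of the six-clade default
for 2-SE coverage of the common slope; 200 λ-profile replicates on
200-tip trees (four trees × 50 datasets); 60 replicates per generating
model at 200 species/clade for BIC selection; 1000 null replicates
(six clades × 30 species) for the ANCOVA type-I rate; 50 random
instances for the GLS/whitened-OLS identity; and one 1817-species
replicate for the compilation-scale integration check. The acceptance
script uses the same designs with 100 replicates where the suite uses
200.

## Known limitations

* λ is the only covariance transform; no OU, κ, or δ models.
* One tree per run; no averaging over posterior tree distributions.
* The common-slope SE ignores residual phylogenetic correlation, so
  2-SE intervals are mildly anticonservative when λ is high (empirical
  coverage ≈ 93–97% rather than 95% under the default λ = 0.6).
* No RMA/SMA regression; the analysis family uses OLS/WLS/PGLS only.
* Unit handling is fixed to grams and ml O₂/h; no watt conversion.
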