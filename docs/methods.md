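# Methods

## Statistical model

Each pathway is analyzed by one stacked linear model.  For sample *i* and
protein *j*,

    y_ij = α_j + β_j·x_pkd + γ_j·x_dose + δ_j·x_mcat + η_j·x_mcat·x_dose + ε_ij

with ε_ij ~ N(0, σ_j²) and indicator covariates: `x_pkd = 1` for
disease-causing genotypes (RC/RC and RC/null), `x_dose = 1` for the severe
genotype (RC/null), `x_mcat = 1` under treatment, plus the interaction.
Heterozygous RC/+ animals are phenotypically normal and encode as
`x_pkd = 0`.  Abundances live on the relative scale (wild-type baseline
≈ 1), so β_j = −0.31 reads as a 31% decrease; the restoration percentage
100·δ_j/(−β_j) is scale-free.  The five-group cohort saturates the five
per-protein parameters, so with zero noise unpenalized least squares
recovers them exactly — the basis of several oracle tests.

The stacked design is block-diagonal by protein: each protein contributes
its own baseline indicator plus the four covariates on its rows.  Proteins
are therefore coupled only through the shared penalty level λ and the
pathway-wide model-selection criterion, which is what "fitting by pathway"
adds over protein-by-protein regressions.

## Composite MCP and its parameterization

The penalty applies an outer MCP to the sum of inner MCPs of member
magnitudes, with the per-protein effect bundle {β, γ, δ, η} as the group
(baselines are never penalized — selecting away a baseline would be
meaningless):

    P_λ(β) = Σ_g f_out( Σ_{j∈g} f(|β_j|; λ, γ_in) )

where f(t; λ, γ) = λt − t²/(2γ) for t ≤ γλ and γλ²/2 beyond.  The outer
MCP is taken with unit slope at zero and group-size-scaled concavity
γ̃_g = γ_out·K_g·λ²/2 (K_g = members in group g).  This choice has three
consequences we rely on:

* the outer plateau sits exactly at the saturated inner sum, so a group is
  "fully in" precisely when all its members have escaped shrinkage;
* the composite derivative at zero equals λ, so the path starts at the
  familiar λ_max = max_j |x_jᵀr|/n (r = residual after fitting the
  unpenalized baselines) and the first grid point has an empty penalized
  support by construction;
* the objective is homogeneous of degree two under (β, λ) → (cβ, cλ),
  giving exact scale equivariance: rescaling the response by c rescales
  solutions by c when λ is rescaled by c (property-tested).

Defaults γ_in = γ_out = 3, the customary MCP concavity.  λ grid: 100
log-spaced values from λ_max down to 0.001·λ_max.

## Algorithm

Cyclic local coordinate descent with warm starts along the decreasing λ
grid.  At each coordinate the concave outer penalty is majorized by its
tangent at the current group sum (weight w_g = max(0, 1 − s_g/γ̃_g) ∈
[0, 1]); the resulting univariate problem — quadratic plus weighted inner
MCP — has the closed-form firm-threshold solution (soft thresholding
inflated by 1/(1 − w/γ) inside the concave region, identity beyond γλ).
Because the tangent majorizes the outer penalty and the inner univariate
problem is solved exactly, the true objective is non-increasing at every
update; the per-sweep objective log is stored and asserted in tests.
Convergence: max coefficient change < 1e-8 (tol), cap 10⁴ sweeps;
non-convergence is flagged per grid point, not fatal.  The inner kernel is
numba-compiled with a pure-Python fallback.  Penalized columns are
centered and scaled to unit root-mean-square before fitting (penalties are
scale-sensitive); the recorded transform is inverted exactly when
reporting coefficients, and the centering shift is absorbed by the
baseline coefficients.

The penalty is nonconvex, so only a stationary point is guaranteed.
Correctness is therefore defined operationally: a KKT check reports the
maximum coordinate-wise stationarity violation, and on problems small
enough to enumerate, path solutions are compared against brute-force
lattice minimization (201 points per axis) and against the normal
equations in the λ→0 limit.

## Selection, refit, inference

The reporting λ minimizes BIC = n·log(RSS/n) + df·log(n) with df = number
of nonzero coefficients, ties broken toward the sparser (larger-λ) model.
BIC keeps the default pipeline deterministic; cross-validation is
deliberately not in the default path.  The selected effects are then
refitted by OLS — per protein, since the stacked design is block-diagonal —
with per-protein residual variance and two-sided t tests (statsmodels).
Unselected effects are exact zeros with no p value.

Significance flags use the refit t tests at α = 0.05 with no multiplicity
correction by default (selection already sparsifies the model; a
Benjamini–Hochberg option is exposed via `p_adjust="bh"`).  Flag
definitions: *altered* = significant mutation or dosage effect;
*suppressed* = altered with negative mutation effect; *dose-prominent* =
significant dosage effect with the mutation effect's sign; *ameliorated* =
significant treatment effect opposing the mutation effect;
*reversed_gt10* = ameliorated with restoration strictly above 10%.

Pathway rows average effects over the full membership (unselected effects
contribute 0 — shrinkage to zero is the meaning of non-selection), and the
pathway restoration percentage is the ratio of the pathway-mean treatment
effect to minus the pathway-mean mutation effect (ratio of means, matching
how a printed pathway pair like −0.29 / 80.7% relates).  The treatment
effect entering restoration is δ_j (its value on the RC/RC scale) by
default; the RC/null variant δ_j + η_j is emitted alongside, since either
convention is defensible.  Per-protein restoration is undefined (missing,
never 0) when the mutation effect is zero.

## Synthetic cohorts

The generator draws per-protein parameters around per-pathway means and
produces data from exactly the model above, returning the ground truth
for recovery tests.  Defaults encode the study conditions: 27 samples in
groups 4 WT / 9 RC/RC / 7 RC/RC+mCAT / 4 RC/null / 3 RC/null+mCAT, and a
137-protein panel over 8 pathways (TCA 26, FAO 22, respiratory complexes
30, antioxidants 12, glycolysis 15, peroxisome 10, proteostasis 12, other
10).  Pathway-mean mutation effects follow the reported pathway table
(TCA −0.31, FAO −0.29, respiratory complexes −0.28, antioxidants −0.25;
weaker pathways −0.05…−0.15); treatment-effect means are implied by the
reported restoration fractions (FAO 80.7% → +0.234, TCA 47.8% → +0.148,
complexes 53.7% → +0.150, antioxidants 62.1% → +0.155); dosage-effect
means are set to half the mutation means (dosage effects reinforce the
mutation direction); interaction means are 0.  The catalase entry gets a
fixed treatment effect of +0.64 — the delivered transgene's ~64%
overexpression.  Where no value is reported, choices are fixed once at
realistic magnitudes for relative-scale SRM data: between-protein effect
SD 0.10 (0.05 for interactions), residual SD 0.08 (signal-to-noise ≥ 3
for the strong pathways), baselines N(1, 0.1²).  Noise is Gaussian and
homoscedastic per protein — the simplest model consistent with the linear
fits.

What the generator does **not** emulate: peak-integration artifacts,
missing values, between-protein correlation beyond shared design effects,
heavy-tailed or intensity-dependent noise, batch structure.  Passing
recovery and calibration tests therefore demonstrates the statistical
machinery is correct under its own assumptions, not that real SRM data
satisfy those assumptions.

OCR traces are simulated as piecewise-constant phase rates plus Gaussian
noise with injection annotations between phases; this suffices to test
segmentation and the activity arithmetic, not instrument drift or
background-well behavior.

## Flux-assay arithmetic

Phase means use the last 3 measurement cycles before the next injection
(equilibration discard, standard flux-assay practice); phases are
half-open intervals [injection, next injection).  Complex activity =
(substrate mean − inhibitor mean)/µg protein; negative values are returned
unclipped with a warning.  Citrate-synthase normalization divides by the
CS activity (CS > 0 enforced).  Enzyme kinetics: least-squares slope
(ΔA/min) → ΔA/(ε·l) mM/min → ×V nmol/min → /mg protein, reported as a
positive magnitude (DTNB gains absorbance, NADH loses it).  Extinction
defaults: 13.6 mM⁻¹cm⁻¹ (DTNB/TNB, 412 nm) and 6.22 mM⁻¹cm⁻¹ (NADH,
340 nm), path length 1 cm — literature constants, all overridable (plate
readers need their own effective path length).  The unit chain is audited
in tests against a symbolic computation with explicit physical units.

Power for the small flux cohorts uses the noncentral t distribution:
two-sided two-sample test, noncentrality d·√(n/2), df = 2n − 2, checked
against Monte-Carlo simulation.

## Numerical and design notes

* Degenerate inputs: zero-variance penalized columns (a cohort lacking a
  design cell), missing abundances, rank-deficient refits, empty phases
  and non-finite configs all raise named validation errors rather than
  being silently patched.
* Problem sizes in the tests/acceptance script: 100-seed recovery and
  null-calibration sweeps at full study size (27×137, 8 pathways),
  20-cohort averages for the headline pathway quantities, 10⁵-replicate
  power Monte-Carlo, 201-per-axis lattices up to 3 coefficients — sizes at
  which the oracles are exact or their Monte-Carlo error is far below the
  tolerances tested.
* Determinism: one seeded generator per simulation; identical config+seed
  gives byte-identical CSV outputs (hash-tested), and the provenance
  record (config hash, seed, library versions) suffices to reproduce any
  run.
* Known limitations: no mixed/random effects or continuous gene-dosage
  coding; BIC on the stacked fit assumes pooled residual scale during
  selection even though refit variances are per-protein; post-selection
  p values are not selective-inference-corrected (coverage of ~95% CIs on
  selected strong effects is verified empirically at ≥90%); the
  restoration ratio is unstable for pathways whose mean mutation effect is
  near zero — consumers should read it jointly with the effect columns.
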