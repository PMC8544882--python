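# Methods

This note documents the models behind `coralith`, the defaults and why they
were chosen, what the synthetic generator emulates, and the numerical
decisions a maintainer would want written down.

## Buoyant-weight densitometry

A skeletal fragment suspended in seawater weighs less than in air by the
mass of the water it displaces. With the seawater density ρ_SW known, the
dry mass DM and wet (suspended) mass WM give the **biomineral volume**

    V_Bio = (DM − WM) / ρ_SW

and the **microdensity** (density of the biomineral itself, excluding pore
space) ρ_Micro = DM / V_Bio. For assay fragments weighed only wet, the dry
mass is estimated from a species-level microdensity reference:

    DM = WM / (1 − ρ_SW / ρ_Micro)

which is the exact algebraic inverse of the two relations above, so the
estimated route and the measured route agree identically when the reference
density is exact. Bulk volume comes from re-weighing the fragment after a
paraffin dip seals the pores; the wax shell's own volume is subtracted
using the wax mass (coated minus uncoated dry mass) and the wax density
(default 0.90 g cm⁻³). Porosity is P = V_Bulk − V_Bio, reported also as the
fraction P / V_Bulk.

**A published-formula inconsistency.** Some protocol write-ups divide the
buoyant mass deficit for *estimated* volumes by ρ_Micro rather than ρ_SW.
That is dimensionally a volume but inconsistent with Archimedes (it
understates the volume by ρ_SW/ρ_Micro ≈ 0.37). The package defaults to the
physically consistent ρ_SW denominator for both routes; `literal_eq2=True`
reproduces the literal published form so fidelity comparisons remain
possible. This is a deliberate design decision, not an oversight.

**Seawater density** uses the UNESCO EOS-80 one-atmosphere equation of
state (Millero & Poisson 1981), valid for 0–40 °C and 0–42 practical
salinity, reproducing the published check values to 1e-5 g cm⁻³.
Temperature is quantized to a 0.1 °C grid before evaluation, emulating a
monitoring protocol that recalculates density at every 0.1 °C change.
Pressure dependence is out of scope (all weighings are near-surface).

**Species reference density** aggregates per-specimen microdensities by
arithmetic mean (configurable to median); the spread column is the sample
standard deviation (scaled MAD under the median). References outside
(1.0, 2.94) g cm⁻³ are rejected — 2.94 is the density of aragonite single
crystals, a hard physical ceiling for coral skeleton.

## Endolith assays

**AFDW.** Organic (microbial) mass is the loss on ignition: dried mass
(70 °C) minus ashed mass (550 °C), divided by the fragment's estimated
biomineral volume, in mg cm⁻³. Ash exceeding the dried mass is rejected as
physically impossible.

**Quadrichroic chlorophylls.** Four wavelengths resolve four pigments
simultaneously. With E the 4×4 matrix of pigment-specific absorption
coefficients (rows = wavelengths, columns = chlorophylls a, b, c, d; units
OD per µg ml⁻¹ per cm), the mean of the triplicate ODs satisfies
E·c = OD and is solved directly for the extract concentrations c. The
shipped coefficients are a manual transcription of Ritchie (2008) for 90 %
acetone, stored in the published "concentration = M·OD" form and inverted
numerically; the solver itself is generic and validated exclusively with
synthetic matrices, so a transcription slip cannot silently corrupt the
test suite's evidence. Matrices with condition number above 1e8 are
rejected. The cuvette path length is fixed at 1 cm (configurable).

Negative solutions — measurement noise pushing a truly absent pigment below
zero — are clamped to zero and flagged not-detected; the pre-clamp values
are always reported alongside. Note the flag follows the solved sign, so an
exactly-zero true concentration can round to either side of zero at the
1e-16 level.

Two wavelength labellings are supported: the conventional quadrichroic set
(630, 647, 664, 691) nm and a variant that lists 674 nm in place of 647 nm,
as some field reports print. They differ only in the label of the second
channel; the coefficient values are those of the cited source. The
ambiguity is surfaced here rather than silently resolved. HCl
decalcification converts part of the chlorophyll *a* pool to phaeophytin
*a*, depressing the 664 nm channel; no correction is applied (documented
limitation — reported chlorophyll *a* is a mild underestimate).

## Morphometrics

Corallite complexity is the weighted septa sum 2·(primary) + (secondary):
only two septal cycles are modelled, and input carrying higher cycles is
rejected rather than silently weighted. The calice-to-coenosteum ratio per
corallite is mean(max width, width at 90°) over mean(two flanking
coenosteum widths); the per-specimen value is the **mean of per-corallite
ratios** (each corallite's ratio is a measurement in its own right), with a
pooled-means alternative for sensitivity checks. Tissue thickness is the
mean of nominally 10 point measurements; shorter profiles are accepted with
a warning and the count recorded, since field data are imperfect.

## Interspecific comparisons

Responses (AFDW, chlorophylls) are strictly positive and right-skewed, so
the one-way ANOVA runs on natural logs (the base affects nothing
inferential). Pairwise contrasts use the pooled residual variance and the
studentized-range distribution with (k, n−k) — Tukey's HSD — and reports
echo the (k−1, n−k) degree-of-freedom pair. Homogeneity of variance across
species is checked with the Breusch–Pagan LM statistic, n·R² of the
auxiliary regression of squared residuals on the group design (df = k−1).
Influence is screened with Cook's distance at the conventional 4/n
threshold (0.08 at the n = 50 study design); flagged points trigger an
automatic refit without them and a side-by-side contrast table, so the
decision to retain or exclude is auditable rather than silent.

Chlorophyll *c* is frequently exactly zero (absent from skeletons dominated
by green algae), which a log transform cannot accommodate. The default
policy excludes zero-inflated responses from log-scale ANOVA with an
explicit warning; an alternative replaces exact zeros with half the
smallest positive value. Neither is hidden: the policy is a named config
flag. Summaries are medians ± MAD with the 1.4826 normal-consistency
constant (the default in most statistical environments; the raw MAD is
available via the constant argument). Medians use the standard
midpoint-of-middle-pair rule for even n.

## Principal-component regression

The five morphology variables (microdensity, porosity fraction, complexity,
calice/coenosteum ratio, tissue thickness) are centred and scaled with the
sample (n−1) standard deviation. (Some environments' PCA routines divide by
n; the difference is a uniform scale on scores and cannot affect loading
directions or variance fractions.) PCA is the eigendecomposition of the
resulting correlation matrix; components are ordered by decreasing
eigenvalue and each loading vector is oriented so its largest-magnitude
entry (first such entry on ties) is positive, making the decomposition
invariant to row order. Rank deficiency yields zero eigenvalues, not
failure. Exactly two components enter the regressions.

**Lognormal model**: OLS of ln y on (1, PC1, PC2); deviance = residual sum
of squares on the log scale; the model F-test against the intercept-only
null is reported for this family only.

**Gamma GLM (log link)**: with variance function V(μ) = μ² and log link the
IRLS weights are identically 1, so each iteration regresses the working
response z = η + (y − μ)/μ on the design. Initialization is μ⁰ = y;
convergence is relative coefficient change < 1e-10 (max 100 iterations)
with step-halving on any deviance increase; non-convergence is flagged on
the fit, never silently returned. Dispersion is φ = Pearson χ²/(n−p) (the
common reporting convention; the deviance-based estimate is also recorded),
shape α = 1/φ, per-observation rate β = α/μ. Coefficient covariance is
φ(XᵀX)⁻¹ and Wald t-statistics use n−p degrees of freedom. For the
intercept-only gamma-log model the MLE of μ is the sample mean, which
anchors the null deviance.

Goodness of fit is the deviance pseudo-R² = 1 − D/D₀. Candidate families
(normal, lognormal, gamma) are compared by AIC at their maximum-likelihood
fits (closed form for normal/lognormal, profile MLE with zero location for
the gamma); non-positive samples fall back to normal-only with a warning.

**Diagnostics** are a seeded parametric bootstrap, a deliberately
simplified analogue of simulation-based residual packages: n_sims response
sets are drawn from the fitted family at (μ̂, φ̂), the model is refitted to
each, and the observed Pearson dispersion is ranked two-sidedly among the
refitted simulated dispersions (the refit per simulation is what keeps the
test calibrated when dispersion is freely estimated). Simulation-rank (PIT)
residuals are tested for uniformity with a Kolmogorov–Smirnov test. An
optional external response vector lets the same machinery check new data
against an already-fitted model. Default n_sims = 250; fewer than 100 warns,
fewer than 20 errors.

**Pairing.** Morphology and assays are measured on different fragments (a
destructive-assay constraint), so the regression requires an explicit
`pair_id` joining each morphology specimen to an assay specimen. Real
studies must state how individuals are paired; the synthetic generator
sidesteps the ambiguity by emitting matched pairs. Responses regressed are
AFDW (lognormal) and chlorophylls a, b, d (gamma); chlorophyll c is
excluded as zero-inflated.

## Synthetic data

The generator is an *inverse construction*: it states ground truth first
and then runs the physics backwards — WM = (ρ_Micro − ρ_SW)·V and
DM = ρ_Micro·V for a drawn volume; wax readings consistent with the target
porosity (the wax-mass increment and buoyancy deficit carry their own
reading noise, preserving the orderings the wax protocol guarantees
physically); OD = E·c for the realized pigment concentrations; furnace
masses consistent with the realized AFDW over a 20 mg salt residue. With
zero instrument noise the pipeline therefore recovers every target to
floating-point precision, which turns the generator into an oracle for the
whole chain.

Defaults describe a five-species reef-flat community, ten specimens per
species in each of two sample sets (one destructively assayed, one measured
morphometrically). Pigment and AFDW species medians follow published
reef-flat values for these species (e.g. AFDW medians 110.3, 86.5, 27.9,
29.1, 39.2 mg cm⁻³ across the five species); microdensities span a
low-density *Goniastrea* (2.50 g cm⁻³) to dense (~2.8 g cm⁻³)
*Isopora*/*Montipora* skeletons. Morphometric spreads are plausible values,
not literature constants, and are labelled as such. Biological variation is
gamma for pigments and lognormal for AFDW — the same families the
regression assumes — parameterized so the species *median* equals the
stated target (gamma scale set via the inverse CDF at 0.5). Chlorophyll c
is zero-inflated for two species (90 % and 50 % absent), reproducing the
non-detection pattern such communities show. Instrument noise defaults:
0.1 % (balance), 1 % (OD), 3 % (widths), 5 % (tissue points), all relative.

What the generator does **not** emulate: within-colony spatial structure,
macroborer damage, correlated instrument drift, non-detection censoring in
AFDW, or real covariance between a colony's morphology and its endolith
load beyond species-level differences. Passing tests therefore demonstrate
that the measurement algebra and the inference machinery are correct and
calibrated under the stated models — not that those models capture every
feature of field data.

Planted-effect datasets for the regression harness draw five correlated
morphology variables from two latent axes, standardize and decompose them,
and generate responses from the *realized* PC scores, so the planted
coefficients are exactly the estimands of the downstream fit (no leakage of
the latent construction into the estimator).

All randomness descends from one seed through named
`numpy.random.SeedSequence` spawns, one stream per measurement family, in a
fixed documented order; identical seeds give byte-identical bundles.

## Pipeline

Stages write outputs only on success (a failed stage leaves nothing
partial), log one structured line per decision (outlier flagged, clamp
applied, policy invoked, refit run), and record a manifest with the config
snapshot, seed, version and per-stage row counts. All data products are
byte-identical across reruns with the same config and seed; the manifest's
wall-clock timestamp is the single documented exception. CLI exit codes:
0 success, 2 input/schema error, 3 statistical-fit failure; warnings never
change the exit status.

## Problem sizes

The shipped tests and the acceptance script run the default 5 × 10 × 2
community, 1000-case property sweeps for the Archimedean chain, 2000-draw
samples for distribution selection, and seeded simulation studies of
400 (type-I), 200 (recovery/power) and 500 (diagnostics calibration)
replicates — sizes at which the binomial uncertainty of the checked rates
is comfortably inside the asserted bands.

## Known limitations

* The shipped absorption coefficients are a transcription; anyone using the
  package for real extracts should verify them against the original table
  (the config file format makes substitution trivial).
* Cook's distance for the gamma GLM uses the one-step IRLS working-model
  approximation, the standard GLM influence measure, not exact case
  deletion.
* The diagnostics' dispersion test is conservative for well-specified
  models (observed dispersion is compared against refitted simulations).
* No phaeopigment correction, no mixed models, no more than two retained
  components.
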