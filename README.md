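# coralith

Tools for linking coral skeletal morphology to the biomass of the endolithic
microbiome — the microbial biofilm (dominated by the boring green alga
*Ostreobium*) that lives inside the skeletons of living corals.

The package implements the full measurement-to-inference chain such a study
needs, for ecologists working from balance readings, spectrophotometer ODs
and calliper/image measurements:

* **Buoyant-weight densitometry** (`coralith.densitometry`). From dry/wet
  balance readings and the seawater density ρ_SW (UNESCO EOS-80 equation of
  state), Archimedes' principle gives the biomineral volume
  V_Bio = (DM − WM)/ρ_SW, the microdensity ρ_Micro = DM/V_Bio, and — with
  wax-coated readings — the bulk volume and porosity P = V_Bulk − V_Bio.
  For fragments weighed only wet, the dry mass is estimated as
  DM = WM / (1 − ρ_SW/ρ_Micro) from a species-level microdensity reference.
* **Endolith assays** (`coralith.assays`). Ash-free dry weight
  (dried − ashed mass, normalized to skeletal volume, mg cm⁻³) and
  quadrichroic chlorophyll spectrophotometry: chlorophylls *a–d* resolved
  from ODs at four wavelengths by solving E·c = OD (Ritchie 2008, 90 %
  acetone coefficients shipped as config), with negative solutions clamped
  and flagged not-detected.
* **Morphometrics** (`coralith.morphometrics`). Corallite complexity
  (2 × primary + secondary septa), calice-to-coenosteum width ratio, and
  tissue thickness, averaged per specimen.
* **Interspecific statistics** (`coralith.interspecific`). Median ± MAD
  summaries, log-scale one-way ANOVA with Tukey-adjusted contrasts,
  Breusch–Pagan homogeneity tests, and Cook's-distance outlier screens at
  the 4/n threshold with automatic with/without refits.
* **Principal-component regression** (`coralith.pcreg`). Standardization,
  PCA of the five morphology variables, and regression of responses on PC1
  and PC2 under a lognormal model (OLS on ln y) or a log-link gamma GLM
  fitted by IRLS, with dispersion φ (shape α = 1/φ, rate β = α/μ), the
  deviance pseudo-R² = 1 − D/D₀, AIC-based family selection, and seeded
  parametric-bootstrap residual diagnostics.
* **Synthetic data** (`coralith.synth`). An inverse-construction generator
  that emits every raw table the pipeline reads for a configurable
  five-species community, plus planted-effect datasets for parameter
  recovery; with zero instrument noise the pipeline recovers the ground
  truth exactly.
* **Pipeline + CLI** (`coralith.pipeline`, `coralith` command). Orchestrated
  `simulate → derive → analyze → report` stages with YAML/JSON config,
  structured logging of every outlier/clamping decision, run manifests, and
  byte-deterministic outputs for a given config and seed.

## Worked example

`examples/pc_regression.py` plants a known effect of the leading morphology
axis on a gamma-distributed response and recovers it:

```
variance explained: PC1 57.6%, PC2 37.4%, PC3 2.2%
PC1 loadings (beta):
  rho_micro_g_cm3        +0.575
  porosity_fraction      +0.334
  complexity             -0.501
  ctc_ratio              -0.495
  tissue_thickness_mm    -0.248

planted (b0, b_PC1, b_PC2) = (1.0, 0.5, -0.3)
  intercept estimate +0.982  se 0.062  t +15.80  p 1.98e-20
  PC1       estimate +0.522  se 0.037  t +14.10  p 1.68e-18
  PC2       estimate -0.227  se 0.046  t -4.94  p 1.04e-05
dispersion phi = 0.193 -> shape alpha = 1/phi = 5.17 (truth 5.0)
pseudo-R^2 = 1 - deviance/null deviance = 0.790
parametric-bootstrap diagnostics: dispersion p = 0.900, residual-uniformity p = 0.942
```

The fitted coefficients sit within a standard error or two of the planted
(1.0, 0.5, −0.3); the dispersion estimate recovers the generating gamma
shape; the bootstrap p-values show no evidence of misspecification. The
other scripts in `examples/` walk through densitometry, pigment
quantification, interspecific comparisons and the four-stage pipeline, one
capability each.

The same chain from a shell:

```sh
coralith simulate --outdir raw --seed 1
coralith derive   --data-dir raw --outdir derived
coralith analyze  --data-dir derived --outdir analysis --seed 1
coralith report   --data-dir analysis --outdir analysis
```

## Design notes

See `docs/methods.md` for the models and their assumptions, the default
parameter choices, what the synthetic generator does and does not emulate,
and the numerical details (IRLS initialization, sign conventions,
tie-breaking, degenerate inputs).
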