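# Methods

This note records the models implemented in `scorpcam`, the parameter
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data generators do and do not emulate.

## Visual modelling

**Spectra and grids.** All spectra (reflectance, illuminant, receptor
sensitivity) live on a common uniform wavelength grid, by default 300–700 nm
in 1 nm steps (401 points). External spectra are resampled by linear
interpolation and must cover the grid. D65 ships with the package as the
standard tabulated illuminant (5 nm source data, interpolated); a synthetic
depth-attenuated daylight (`make_depth_illuminant`) is provided as a
labelled stand-in for coastal underwater light — it is a Beer–Lambert
attenuation of D65 with an absorption minimum near 480 nm, not a field
measurement.

**Pigment templates.** Observer sensitivities are Govardovskii et al.
(2000) A1 alpha-band nomograms parameterised only by λmax, the standard
choice for fish visual pigments. The beta band is off by default: for the
peaks used here (455–530 nm) its contribution above ~430 nm is negligible,
and the behavioural stimuli carry little power below that. A switch enables
it. Ocular media transmission is not modelled. Supported λmax range is
330–600 nm (template validity).

**Observers.** Two presets:

| preset | peaks (nm) | cone ratio η | ω | luminance channel |
|---|---|---|---|---|
| `scorpaena_porcus` | 455, 530 | 1 : 1 | 0.05 | long-wavelength cone |
| `tripterygion_delaisi` | 468, 517, 530 | 0.25 : 1 : 1 | 0.05 | mean of the two long cones |

*S. maderensis* vision is assumed equal to *S. porcus* (no separate preset);
the Weber fraction anchors the most abundant cone class.

**Quantum catches.** `Q_i = Σ_λ R(λ) I(λ) S_i(λ) Δλ`. No von Kries
normalisation is applied to catches themselves: the RNL distances used
downstream are invariant to any per-receptor scaling common to both
stimuli, so a von Kries step would cancel. Grey-standard normalisation of
*camera* measurements is linear: the one-standard rule maps channel values
through `value/standard × nominal`; with two standards (12%/72%) a
two-point straight line is fitted per channel. The camera-to-cone transform
is a linear least-squares map fitted on training spectra; this is a
deliberate desk-scale simplification of multispectral camera calibration,
adequate because both the synthetic camera and observer integrate the same
linear world. Its training RMS relative error is reported so gamut problems
are visible. ROI values are averaged per channel *before* conversion (the
alternative — convert per pixel, then average — differs only through the
map's linearity and is not offered).

**RNL distances.** Log receptor signals `Δf_i = ln(Q_i,a/Q_i,b)`; noise
`e_i = ω√(η_max/η_i)`; dichromat and trichromat closed forms for ΔS. The
achromatic distance uses the log form `|ln(L_a/L_b)|/ω` for consistency
with the log-signal chromatic channel; a symmetric linear Weber form is
available via `form="linear"`. Both chromatic and achromatic distances
canonicalise the pair order internally so symmetry is bit-exact, not just
within floating-point rounding. JND thresholds: values below 1
"indistinguishable", 1–3 "above_1", ≥ 3 "above_3"; boundary values go to
the more detectable class so detection claims are conservative.

## The GLMM engine

All four analysis stages use one model family: a Gamma(log) or
binomial(logit) GLMM with categorical fixed effects (with interactions,
patsy treatment coding) and a single random intercept (photo ID or fish
ID). No random slopes — every model in scope has one grouping factor.

* **Likelihood.** The random intercept is integrated out by adaptive
  Gauss–Hermite quadrature with 15 nodes: each group's integrand is
  recentred at its posterior mode (found by a damped, vectorised Newton
  iteration) and rescaled by its curvature. With one node this is exactly
  the Laplace approximation; 15 nodes refine it, which matters for the
  binomial models with only three observations per fish. One code path
  serves both families.
* **Optimisation.** L-BFGS-B over (β, log shape, log σ), relative tolerance
  1e-11, max 500 iterations; starting values from a small internal IRLS
  (binomial) or an OLS fit on log responses (Gamma). Non-convergence raises
  `FitError` with diagnostics — it is never silently accepted. A fit with
  log σ at its lower bound reports `random_sd = 0`.
* **Covariance.** Wald: the fixed-effect block of the inverse
  central-difference Hessian of the negative log-likelihood at the optimum.
* **Posterior simulation.** 10,000 multivariate-normal draws of the fixed
  effects from (β̂, Σ̂); medians and 2.5/97.5 percentiles of the
  inverse-linked linear predictor give predicted medians and 95%
  compatibility intervals; response ratios are `exp(η_a − η_b)` per draw.
  Random-effect uncertainty is *not* propagated into these intervals —
  a documented choice matching common practice with simulated parameter
  sets; the intervals are therefore intervals for the typical
  (random-effect-zero) group.
* **R².** Nakagawa–Schielzeth latent-scale form: marginal
  `var_f/(var_f+var_r+var_e)` with var_e = π²/3 (logit) or trigamma(shape)
  (Gamma log link).
* **Quantile residuals.** Unconditional simulation from the fitted model
  (fresh random intercepts per simulation), rank position of the
  observation among `n_sim` simulations with uniform tie jitter; Uniform(0,1)
  under a correct model. `n_sim ≥ 20` enforced; 250 default.
* **Separation.** Binomial fits whose coefficients exceed 8 on the logit
  scale are refitted with a weak Gaussian ridge of variance 25 *on the
  cell logits* (one prior term per distinct design row, not per raw dummy
  coefficient — penalising raw coefficients would inflate interaction-cell
  intervals far beyond what the prior intends). The fit is flagged
  `penalized`.

## Pipeline stages

**Substrate contrasts.** Between two types, every photo of one is compared
with every photo of the other (n_A × n_B rows); within a type, all
unordered pairs of distinct photos (n(n−1)/2) — a photo is never compared
with itself. Six types give 21 comparison categories. The Gamma contrast
models use the *first* photo's ID as the random intercept; each row
involves two photos, but a single grouping factor is used, mirroring the
single "photo ID" random factor of the study design. The crossed
two-intercept alternative is out of scope.

**Background design.** The medium grey minimises |Weber contrast| to the
medium-adapted fish (ties to the darker patch); the light/dark greys come
closest to +0.33/−0.33 against the light-/dark-adapted fish — the sign
convention (light background lighter than the fish, dark darker) is the
package's reading of "same absolute contrast". Starting-zone luminance is
the geometric mean of the two backgrounds: "intermediate" is interpreted on
the log scale, where Weber-type perception is uniform. Adapted fish
luminances are user inputs; the synthetic fixtures use 0.67/1.0/1.5.

**Behavioural scoring.** Stationary bouts shorter than 5 s are stop-and-go
pauses, not choices (boundary included); the first stationary bout of at
least 60 s defines *first settled*. The which-background-under-the-eyes
tie-break is assumed resolved upstream in the event table. Choices are
encoded 1 when they match the a-priori expectation (dark over light, medium
over light, medium over dark). Fish that never settled in any treatment are
excluded before fitting; fish that settled in some treatments contribute
those trials. The binomial GLMM uses species × treatment fixed effects and
fish ID random intercepts; a cell CI excluding 0.5 is a non-random choice.

**Pattern analysis.** Bar-vs-background contrast is the *mean of the eight
per-sample JNDs*, not the JND against the mean sample, so within-background
variation raises the contrast (the pooled alternative is a one-line change
in `bar_background_contrast`). Chromatic bar contrasts are computed by the
same machinery but not modelled. Light-background choices are excluded
before modelling. The two bar-level responses use species × bar ×
background fixed effects; internal pattern contrast is defined per fish ×
treatment (not per bar), so its model uses species × background — the only
reading under which the factor "bar" is well defined for each response.

## Synthetic data

The generators define the package's study conditions:

* **Substrates:** photo census 12/9/9/3/5/5 over rubble-and-sand, seagrass
  leaves, turf algae, red sponge, yellow algae, seagrass stems. Each type
  is a baseline plus 1–2 Gaussian reflectance bumps chosen once to resemble
  the named material (bright broadband sand, green seagrass, dark stems and
  turf, yellow algae, red sponge). Photo-to-photo variation is lognormal:
  σ_log = 0.22 on the whole spectrum (achromatic) and 0.12 per bump
  (chromatic), giving within-type achromatic JNDs well above 1 and
  between-type separation larger than within-type on average.
* **Choice experiment:** 23 *maderensis* + 27 *porcus*; never-settle rates
  0 and 5/27 (the realised count is round(rate·n) fish, so the default
  reproduces exactly five excluded *porcus*); expected-success
  probabilities 0.9 (dark–light), 0.8 (medium–light), 0.15 (medium–dark) —
  the direction and rough size of the observed choices, including the
  reversed medium–dark preference. Event streams contain 1–3 stop-and-go
  decoys (< 5 s), optionally a sub-minute bout, and (for settlers) exactly
  one qualifying ≥ 60 s bout, all inside the 600 s trial; scoring the
  stream reproduces the intended choice exactly.
* **Fish colouration:** log dark-bar luminance = log(base) + gain·(log L_bg
  − log L_medium) + fish effect + noise, with gain 0.6 (partial luminance
  adjustment), fish-level σ_log 0.15, residual σ_log 0.05; the light bar
  sits a species-specific internal contrast above the dark bar (14 JND
  *maderensis*, 7 JND *porcus*, lognormal individual variation), so light >
  dark always and the species ratio of internal contrast is ≈ 2.
  Backgrounds at luminance 0.5/1.0/2.0 with eight lognormal (σ_log 0.08)
  samples each.

What the generators do **not** emulate: spatial image structure (bars and
samples are catch-level, spectrally flat stimuli), illuminant variation
across photos, correlated substrate texture, treatment-order or
arena-orientation effects, and any real spectral measurement of the two
species. Passing tests therefore demonstrate the pipeline's correctness and
calibration on data with the study's statistical structure — not agreement
with the original field measurements, which require the deposited data.

## Problem sizes and determinism

Simulation-based checks use study-scale sizes: 43 photos (903 contrast
rows), 50 fish × 3 treatments, 200 replicate datasets per family for CI
coverage, 50 replicates for choice-probability recovery. All generators and
posterior simulations are deterministic under (seed, config); the CLI
threads one seed through every stage and reruns are byte-identical.

## Known limitations

* The camera route is a linear approximation; strongly metameric stimuli
  outside the training gamut will map poorly (watch the reported training
  error).
* Wald covariances and fixed-effects-only posterior simulation understate
  uncertainty when groups are few and the random variance is large.
* The Gamma contrast models treat photo-pair rows as exchangeable given one
  photo's intercept; the second photo's identity is ignored.
* JND classifications use point medians; classification uncertainty is
  visible only through the CIs, not propagated into the class label.
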