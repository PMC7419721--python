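# Methods

`stereosim` simulates and analyzes dichoptic stereoacuity measurement: how
interocular suppression and acuity loss limit stereo depth perception, and
what happens when the interocular contrast balance is manipulated.  This
note documents the generative model, the measurement machinery, the
statistical pipeline, and the choices made where the design was open.

## The observer model

### Stereo task

The stereo stimulus is a 4AFC judgment (position of a missing sector in a
disparity-defined pie) at disparity `d` arcsec.  A simulated observer
responds correctly with probability

    p(d) = γ + (1 − γ − λ) Φ((log₂ d − α_eff) / β)

with guess rate γ = 0.25, lapse rate λ (default 0.01), spread β in octaves,
and threshold location α_eff on the log₂-arcsec axis.  The stereoacuity
threshold is defined throughout as the disparity at 62.5% correct — the
midpoint of the 4AFC range — which for λ = 0 coincides with α_eff.

### Contrast imbalance and suppression

Each observer has a dichoptic-letter contrast ratio CR ≥ 1 (the presented
nondominant/dominant contrast ratio at which either eye's letter is equally
likely to be reported; the standard interocular-suppression measure), with
letter reports following a cumulative normal in log₁₀ ratio with spread
`sigma_cr`.

The stereo threshold location depends on the presented contrast pair
(c_d, c_nd) through a *balance point* b:

    α_eff = α + [κ · max(0, c_nd/b − c_d)/10
                 + κ_rel · (max(0, log₁₀ b − log₁₀ ρ) − log₁₀ b)] · log₂10

where ρ = c_nd/c_d is the presented ratio.  `α` is the threshold location at
*equal presented contrast* — the condition in which baseline stereoacuity is
always measured — so the suppression penalty κ_rel·log₁₀ b is already folded
into `α`, and the second term is never positive.

* For a normally-sighted observer, b = 1 and the expression reduces to a
  pure imbalance penalty of κ log₁₀-units per 10% attenuation of the
  dominant eye (κ = 0.35 by default, the empirical slope of log stereo
  threshold against dominant-eye contrast decrement in normal observers).
  Percent correct is then monotone nonincreasing in the decrement.
* For an amblyopic observer, b = CR: the suppressed nondominant eye needs
  CR times the dominant eye's contrast for the two inputs to balance.
  Attenuating the dominant eye toward c_d = c_nd/CR *releases* suppression
  (by κ_rel log₁₀-units per log₁₀-unit neutralized, κ_rel ≈ 0.2 with
  individual spread), and the effective threshold is V-shaped in c_d with
  its minimum exactly at the balance point.  Rebalancing at the true CR
  therefore never worsens the model threshold — the generative counterpart
  of the all-points-below-unity rebalancing result.

This composite model is the package's resolution of an apparent tension: a
pure decrement penalty reproduces the normal-observer contrast-attenuation
experiment but cannot produce any rebalancing benefit for amblyopes, while a
pure balance-point model would wrongly predict that normals improve when the
dominant eye is attenuated.  Keying the balance point to the group (1 for
normals, CR for amblyopes) captures both phenomena with one expression.

### Bangerter degradation

Bangerter filters are modeled phenomenologically: each filter label maps to
(va_decrement, cr_multiplier, stereo_multiplier) applied to a normal
observer's dominant eye.  Defaults come from the degradation experiment's
group relative-change columns (0.8 → no CR/stereo change; <0.1 → CR ×6.8,
stereo ×2.2, VA +0.95 logMAR) and are nondecreasing with filter density.
No optics (microbubble scatter, phase scrambling) are modeled.

## Cohort generation

Cohorts are drawn from truncated distributions parameterized by arithmetic
mean/SD (lognormal for CR and thresholds — positive and right-skewed;
normal truncated at 0 for VA differences), sampled by inverse CDF from
per-observer substreams of a single root seed.

* Normal group (default n = 19): CR 1.45 ± 0.33 in [1.03, 2.19]; thresholds
  40 ± 14 arcsec in [15, 73]; VA difference 0.02 ± 0.04 in [0, 0.10] logMAR.
* Amblyopic group (default n = 21): CR 9.62 ± 11.27 in [1.29, 39.16]; VA
  difference 0.36 ± 0.30 in [0.02, 0.96] logMAR; equal-contrast log₂
  threshold generated from CR — log₂40 + 4.2·(log₁₀ CR − log₁₀ 1.29) +
  N(0, 0.9 octaves) — so deep suppressors range up to and beyond the
  4096-arcsec measurable ceiling (such observers come out "unmeasurable",
  as in the target population, where a third of the abnormal group had no
  measurable threshold).

The threshold–CR linkage (slope 4.2 octaves per log₁₀ CR, chosen so the CR
and threshold ranges map onto each other; noise 0.9 octaves, giving a rank
correlation near 0.85) builds the suppression–stereo association in, and the
VA difference is drawn independently of the threshold — the weakest
admissible linkage — so the suppression-versus-acuity dissociation is a
property of the generative model, not of any analysis choice.  What passing
the dissociation test shows is therefore that the pipeline *detects* a
planted dissociation at realistic n, noise and truncation, not that real
amblyopic data must behave this way.

## Staircase procedure

Two interleaved staircases (two-down/one-up and one-down/one-up) control
log₂ disparity; each trial one active staircase is chosen uniformly.  Each
staircase stops at 70 trials or 9 reversals, whichever comes first; levels
clamp to [1, 4096] arcsec.  Open parameters the source design leaves
unstated, fixed here and configurable: start at 1024 arcsec (suprathreshold
for all simulated observers), initial step 2 octaves halving at each of the
first two reversals to a 0.5-octave floor.  A reversal is a change in the
direction of applied movement; a move fully absorbed by the range clamp is
not movement.  The two-down/one-up track converges near the 70.7% point, as
verified by simulation (mean reversal level maps to ~69% correct on the
generating function, within the classical 66–75% band).

The letter task runs a one-down/one-up staircase on log₁₀ presented ratio
(60 trials, step 0.3 halving to 0.1, bounds 10⁻² to 10²·⁵), tracking the 50%
balance point.

## Fitting

Thresholds are binomial MLEs of (α, β) with γ = 0.25 and λ fixed at 0.01
(a free lapse is unidentifiable from ≤ 140 staircase trials), pooling both
staircases into one likelihood.  Bounds: α ∈ [log₂ 0.5, log₂ 8192],
β ∈ [0.1, 8] octaves.  The likelihood is multimodal when a sharp-step
solution competes with a shallow one, so optimization is multi-start
L-BFGS-B seeded from a coarse NLL scan.  The reported threshold is the
62.5% crossing of the full fitted curve (criterion percent-correct holds
verbatim even with λ > 0); a fit is "unmeasurable" when the crossing leaves
[1, 4096] arcsec, the optimum sits on a parameter bound, or the optimizer
fails.  A brute-force grid-search fitter serves as an independent oracle in
the tests (near-ties on flat chance-data ridges break toward large α, where
the unattained MLE limit lies).  CR estimates are the fitted 50% point of
the letter-report function; one-sided data are flagged unconverged.

## Scoring and rebalancing

* BF score: round(log₁₀ level, 1) for a graded stereo level in
  [40, 2000] arcsec (1.6–3.3); 4 = fusion without stereo; 5 = suppression.
* Relative change: condition mean / baseline mean at one decimal,
  round-half-to-even — the convention that reproduces every internally
  consistent printed table cell.
* Rebalancing: nondominant eye fixed at the 80% baseline contrast, dominant
  eye set to 80/cr_eff with cr_eff ∈ {1, CR, 1.25·CR, 0.75·CR}
  ("CR ± 25%CR" scales the attenuation, not the contrast points), clamped
  to the [1, 100]% display range with a flag.

## Statistics

Correlations (Pearson/Spearman) and paired t-tests via scipy, OLS via
statsmodels, repeated-measures ANOVA via pingouin with Greenhouse–Geisser
corrected (fractional) dfs — Huynh–Feldt behind a flag.  Paired threshold
comparisons run on log₁₀ values (the only transform consistent with the
packaged individual-observer table: t(6) = 4.31, p = 0.005, frozen as a
regression test after independent recomputation).  Pairwise versus-baseline
comparisons use Bonferroni adjustment with family = number of
versus-baseline contrasts, flagged at adjusted p < 0.01.  Zero-variance
inputs (identical conditions, constant ratios) are reported as degenerate
rather than as inferential results.

## Rendering

Stimuli are pairs of 10° discs of isotropic log-Gabor micropatterns
(peak frequency 6 c/deg for the default 10-arcmin element, 1-octave spectral
FWHM, random polarity, ~25 elements/deg²) on a mid-gray background.  The
radial spatial profile is obtained once by inverse FFT of the log-Gaussian
spectrum, tapered to zero at the element-size support radius with the
residual DC removed so each element integrates to zero; dots are stamped by
evaluating that continuous profile at sub-pixel centers.  Dots inside the
pie (disc minus a 90° sector at one of four positions) are displaced by
±disparity/2, the left-eye copy rightward for crossed disparity.  The
summed field is clipped to a symmetric range (the smallest of the four
per-eye extremes) and scaled so the rendered Michelson contrast equals the
per-eye request exactly while the mean luminance stays at the background
level.  Luminance is normalized to [0, 1]; physical cd/m² calibration is
out of scope.  Default 32 px/deg (minimum 20): arcsec-scale disparities are
represented by the continuous profile, not the pixel grid.

## Experiment replicas and problem sizes

`run_experiment` orchestrates cohort → sessions → fits → scoring → tables →
statistics from one root seed.  Replica sizes follow the study designs
(n = 21 amblyopic, n = 19 normal, n = 7 rebalanced); the acceptance script
uses 500 staircase sessions for convergence, 200 for parameter recovery and
500 synthetic cohorts for the dissociation rates.  In group condition
tables an unmeasurable fit is recorded at the 4096-arcsec ceiling (the
paper-facing alternative — dropping subjects — would break the
repeated-measures design); in Experiment 2's letter task a non-converged CR
estimate falls back to the generative value (rare, and flagged in code).
Acuity "measurements" add 0.05 logMAR test-retest noise to the generative
value.

## Known limitations

* The balance-point dichotomy (b = 1 versus b = CR) is a deliberate
  simplification; real observers presumably sit on a continuum.
* Generative distributions are calibrated to group summaries (means, SDs,
  ranges) only; no per-subject raw data exist to validate their shapes.
* Experiment 3's replica rebalances at the *estimated* CR; a large
  estimation error can leave residual imbalance, so the all-observers
  improvement guarantee is stated for rebalancing at the true CR.
* The renderer models stimulus geometry and contrast, not display
  luminance, gamma, or shutter-glass crosstalk.
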