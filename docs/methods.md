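# Methods

## The generative observer

Every simulated response in both paradigms comes from one model. The
observer receives the probe's retinal velocity (a 2-vector on the screen
plane, cm/s) and internal estimates of the optic flow at the probe's
location, and computes

    perceived = retinal − g_G (1+ε) F_global − g_L (1+ε') F_local,
    ε, ε' ~ N(0, σ_flow)

`F_global` is the field-level flow estimate: it is available in every
hemifield configuration because it is recovered from the whole visual
field, which is why tilt survives in the Opposite configuration.
`F_local` is the surround motion-contrast signal and exists only when dots
occupy the probe's hemifield; Full and Same configurations receive
identical inputs (the small Full > Same difference reported in humans is
deliberately not modelled). The observer evaluates flow from the scene
model, not from per-dot sampling — the Opposite configuration demonstrates
the computation does not require local dots.

For direction discrimination the observer takes the horizontal
scene-relative component of the percept, adds decision noise
N(0, σ_disc), lapses to a random response with probability `lapse`, and
answers right iff the result is positive. The induced response curve is
exactly a cumulative Gaussian in the probe's scene velocity, which is what
licenses the psychometric analysis. For the tilt task the observer reports
the perceived direction plus angular noise N(0, σ_report), clipped to the
paddle's [0, 180]° range.

## Stimulus geometry

All kinematics use eye-centered coordinates (X right, Y up, Z along gaze,
cm) with pinhole projection `(x, y) = f (X/Z, Y/Z)` at viewing distance
f = 57 cm and the instantaneous flow of a scene-stationary point under
observer translation T:

    dx/dt = (−f·Tx + x·Tz)/Z,   dy/dt = (−f·Ty + y·Tz)/Z.

Scene objects and flow dots are treated as points; only motion vectors
enter the observer. Degrees are converted by exact arctangent (at these
eccentricities the difference from the small-angle equivalence is < 2 %).

*Discrimination scene.* 11 × 5 grid, 3.5 cm spacing, ±1.2 cm x/y jitter,
depths uniform ±25 cm about 82 cm; objects initially projecting inside a
10° × 2° rectangle around fixation are removed (the 55-object count is
read as the pre-exclusion grid size). Self-movement (12.5 cm/s) is aimed
at the probe's *initial* position for the whole 1-s trial, so the probe
starts exactly at the focus of expansion. Because the flow at the probe is
then proportional to the probe's own displacement from the focus, the
residual (unparsed) flow multiplies the response slope rather than
shifting the PSE: a veridical subtractor (g_G = 1) has scene-unit slope
exactly 1, a non-subtractor (g_G = 0) at most ~8 % more. The human
moving-condition PSE bias is attributed in the source literature to
distance/speed misestimation, which this observer intentionally does not
encode; simulated moving PSEs are therefore near zero. The observer uses
the trial-midpoint flow vector; frame-accurate advection exists separately
in the dot-field generator.

*Tilt scene.* 300 dots uniform on a 47.3 × 29.6 cm screen, depths uniform
107–207 cm, translation 120 cm/s along gaze, 20-frame lifetime at 120 Hz
(initial dot ages are staggered so regeneration is spread over the trial;
dots leaving the screen or the active hemifield respawn immediately). The
flow the observer subtracts at the probe (±4°, horizontal meridian) is
horizontal with expected speed `x · Tz · E[1/Z]`, using the mean inverse
depth of the uniform cloud, E[1/Z] = ln(Z_max/Z_min)/(Z_max − Z_min) —
flow scales with 1/Z, so this is the density-weighted average a field
estimate would return. Numerically ≈ 3.16 cm/s against a 0.8 cm/s probe.

## Staircases

The Kesten accelerated stochastic-approximation rule
`level[n+1] = level[n] − c/(2+m)·(z − φ)` is adopted as the canonical
reading of a staircase that "changes step size depending on the number of
previous reversals"; a reversal is a response-category shift (the first
trial never counts). `c` is calibrated so the first step — for the
response expected at the start level — equals the published 0.33 cm/s
(both tracks give c = 0.825). Levels are clipped to ±2 cm/s to bound
pathological observers; no convergence detection is applied — all 50
trials always run. Interleaving draws the active track uniformly at random
each trial (strict alternation is available as an option).

## Psychometric fitting

Bernoulli maximum likelihood for `P(right|v) = λ/2 + (1−λ)Φ((v−μ)/σ)`
with the lapse λ *fixed* (0 by default; a small fixed value is available
for robustness studies). σ is optimized through a log transform with wide
bounds (1e−4 to 1e2 cm/s); Nelder-Mead from three starts (a
binned-probit-regression estimate, the same with 3× σ, and a moments
fallback) guards against the boundary failures that staircase-concentrated
designs provoke. Perfect response separation leaves σ unidentified and is
flagged (`converged=False`) rather than raised; all-one-category data are
an error. Per-participant fits pool both staircases and both sessions
(200 trials per condition). An independent probit-GLM route (statsmodels)
and a brute-force likelihood lattice pin the optimizer in the test suite.

## Tilt analysis

Relative tilt is reported-minus-actual for right-side probes and
sign-flipped for left-side probes, so positive always means toward the
focus of expansion. Side collapsing mirrors the geometry about the
vertical axis: a left probe moving at global angle θ plays the role of a
right probe at 180° − θ, and the equivalent-90° transform uses that
mirrored angle. The transform itself solves
`tan(θ + relT) = v sinθ / (v cosθ − h)` for the inward horizontal illusory
component, giving `h = v·sin(relT)/sin(θ + relT)` and the equivalent
vertical-probe tilt `atan(h/v)`; it is the identity at θ = 90° and is
pinned in the tests by a root-finder oracle on the defining equation and a
round-trip through its numerical inverse (both to 1e−9°). Trials whose
perceived direction falls at or beyond horizontal (undefined transform)
are excluded and counted. Configuration means are plain arithmetic means;
`Global = Opposite`, `Local = Same − Opposite` by construction. The global
gain is recovered by inverting the vertical-probe model:
`g = v·tan(relT_global)/F`.

## Bayes factors and regression

Both Bayes factors are computed by adaptive quadrature (scipy `quad`,
relative tolerance 1e−10, convergence enforced at 1e−6) rather than
closed-form approximations, so they can be pinned against an independent
trapezoid-rule oracle. The t-test uses the JZS form: noncentral-t
likelihood integrated against a Cauchy(0, 0.707) effect-size prior, with
effective n = n for one-sample/paired and n₁n₂/(n₁+n₂) for two-sample
designs. The correlation uses the exact bivariate-normal sampling density
of r (hypergeometric form) integrated against a stretched beta(1/w, 1/w)
prior on ρ, width 1 (uniform); ρ-independent normalizing constants cancel
in the ratio. Only two-sided tests are provided, and no multiplicity
correction is applied. The regression ladder is cumulative OLS via
statsmodels with ΔR² F-tests on (k_added, n − k_total − 1) df and
standardized betas B·sd(x)/sd(y).

## Synthetic cohort: what it emulates, and what it does not

Defaults: n = 30, ages uniform on [20, 76];
g_G = 0.25 + age/120 (≈0.42 → 0.88 across the range) plus N(0, 0.08)
between-subject jitter, clipped to [0, 1.5]; g_L = 0.2 constant;
σ_disc = 0.15 cm/s static and 0.225 cm/s moving (ratio 1.5) with a shared
log-normal (sd 0.15) participant factor that preserves the ratio;
σ_report = 5°; σ_flow = lapse = 0. Single-session participants (36 tilt
trials per configuration instead of 72) can be emulated via
`missing_second_session`. All randomness descends from one master seed
through spawned generators; reruns are bit-identical.

These defaults encode the target dissociation: the globally subtracted
component grows with age while discrimination noise does not, so the
pipeline should find a positive age–global-tilt correlation and a flat
age–FPI relation — and does (the 100-replicate end-to-end check passes
with the age–tilt correlation positive in ≥95 replicates and median
|r(age, FPI)| < 0.2). The gain-to-age map and noise magnitudes are
calibration choices, not measured human values.

Known limitations of the calibration and model:

- With the default gain span applied to the geometric flow speed
  (~3.16 cm/s), simulated tilts run 59–76°, larger than the ~20–40°
  humans report; the corresponding human gains under this geometry would
  be nearer 0.1–0.2. All recovery results are invariant to this scale.
- Because those tilts sit on the compressed part of the arctangent, the
  constant local *gain* yields a local *tilt* that declines with age in
  the synthetic cohort, unlike the age-flat human local component. The
  decomposition identity and the zero-local-gain null are unaffected.
- The moving-condition PSE bias seen in humans is absent by design (see
  above); Full = Same by construction; no vestibular/efference cues, no
  eccentricity-dependent gain field, no temporal dynamics of parsing.
- Passing tests therefore demonstrate correctness of the analysis chain
  and recoverability of generative parameters at the published design's
  trial counts — not realism of any particular human effect size.

## Validation problem sizes

Staircase convergence: 500 replicates per track (observer σ = 0.25 cm/s),
mean generating-function probability at the final level within ±3
percentage points of the 20 %/80 % targets. Threshold recovery: 200
replicates of the full staircase→fit pipeline at 200 trials/condition,
median |σ̂−σ|/σ ≤ 20 %, FPI centred on the generating noise ratio (1.0 and
1.5 cases, ±0.1). Gain recovery: 100 replicates of 72 Opposite trials at
σ_report = 5°, mean |ĝ−g| ≤ 0.05, local tilt centred on zero when
g_L = 0. Bayes factors: 1e−6 relative agreement with a 4×10⁵-node
trapezoid oracle over a statistic × n grid. End-to-end: 100 seeded
30-participant cohorts. The `recover` command reruns the first three
suites at 200/50/50 replicates.
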