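# flowparse

Simulation and analysis of **optic-flow parsing** psychophysics across an
ageing cohort.

When an observer moves forward through a static world, everything on the
retina streams outward from the direction of heading. To judge whether an
*object* is moving relative to the scene, the visual system must discount
that self-movement component — a computation known as **flow parsing**,
modelled here as partial subtraction of the estimated optic flow from the
object's retinal motion:

```
perceived = retinal − g_G · F_global − g_L · F_local
```

where `F_global` is the field-level flow estimate at the probe's location,
`F_local` the surround motion signal (present only when dots occupy the
probe's hemifield), and `g_G`, `g_L` the subtraction gains.

The package is written for visual psychophysicists who want to (a) simulate
the two standard flow-parsing paradigms end to end against parameterized
generative observers, (b) validate every analysis stage by parameter
recovery, and (c) analyse real trial tables in the same CSV dialects.

## The two paradigms

**Direction discrimination (staircases).** A probe embedded in a sparse 3-D
scene receives horizontal scene-relative velocity `v`; the observer reports
left/right. Trial placement uses two interleaved **Kesten staircases**
(accelerated stochastic approximation),

```
level[n+1] = level[n] − c/(2 + m[n]) · (z[n] − φ)
```

with `z` the binary response, `m` the number of response-category shifts,
and `c` calibrated so the first step is 0.33 cm/s. One 50-trial track
descends from +1 cm/s toward the 20 % rightward point (φ = 0.2), the other
ascends from −1 cm/s toward 80 %. Responses are fitted with a
maximum-likelihood cumulative Gaussian `P(right|v) = Φ((v − μ)/σ)`: μ is the
point of subjective equality (PSE), σ the direction-discrimination
threshold, and the **flow-parsing index** `FPI = σ_moving / σ_static`
measures the sensitivity cost of simulated self-movement.

**Relative tilt (paddle reports).** A probe at ±4° moves at 0.8 cm/s at
75/90/105° within a 300-dot radial flow field (full-screen or confined to
one hemifield). The signed difference between reported and physical
trajectory — **relative tilt**, positive toward the focus of expansion — is
mapped to an equivalent vertical-probe tilt via the horizontal illusory
component `h = v·sin(relT)/sin(θ + relT)`, recoded by hemifield
configuration (Full / Same / Opposite), and decomposed as
`Global = Opposite`, `Local = Same − Opposite`.

**Inference.** Default-prior Bayes factors (Cauchy 0.707 for t-tests,
stretched-beta width 1 for correlations, both by adaptive quadrature),
Pearson correlations, and two-step hierarchical regression with ΔR²
F-tests.

**Synthetic cohort.** Thirty observers aged 20–76 whose global gain rises
linearly with age (≈0.42 → 0.88) while discrimination noises are
age-constant with a 1.5× moving/static ratio — the generative version of
the dissociation the paradigms are designed to detect: flow subtraction
grows with age, motion sensitivity does not.

## Worked example

```
cat > config.yaml <<EOF
cohort:
  n_participants: 30
seed: 7
EOF
flowparse simulate --config config.yaml --out data/
flowparse analyze  --data data/ --out results/
```

`simulate` writes `participants.csv` (true generative parameters),
`exp1_trials.csv` (200 staircase trials per condition per participant) and
`exp2_trials.csv` (216 paddle settings per participant). `analyze` fits
every psychometric function, summarizes tilts, and runs the test battery.
With the config above it prints/writes, among others:

```
mean FPI 1.566   mean static threshold 0.144   moving 0.223  (cm/s)
tilt means: full 73.3  same 73.4  opposite 68.3  local 5.1   (deg)
moving vs static threshold   t = +10.95   p = 8.0e-12   BF10 = 1.1e+09
age vs FPI                   r = +0.236   p = 0.21      BF10 = 0.48
age vs Global relative tilt  r = +0.849   p = 3.0e-09   BF10 = 4.1e+06
```

Read: thresholds are reliably elevated during simulated self-movement
(FPI ≈ 1.5, matching the generating noise ratio), the flow-parsing index
does **not** correlate with age (BF below 1 — evidence for the null, as
built into the generator), while the global tilt component correlates
strongly with age (it inherits the age-sloped gain). The regression table
(`regression_table.csv`) gives the same age effect as an OLS ladder with
standardized betas.

`flowparse recover --seed 1 --out recover.json` reruns the three
parameter-recovery suites (staircase convergence, threshold/FPI recovery,
gain recovery) and reports pass/fail against fixed tolerances.

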