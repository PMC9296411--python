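# Methods

This note documents the models, defaults and numerical choices behind
`prosodim`, what the synthetic data do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The adaptive threshold procedure

Pitch-direction thresholds are measured with a transformed up-down
(2-down-1-up) staircase over glide excursion in semitones: the excursion
decreases by the current step after two consecutive correct odd-one-out
responses and increases after every error. Defaults follow the task the
package models: start at 6 st; step 1 st, shrinking to 0.1 st once four
reversals have occurred and to 0.02 st once eight have; the run ends at 14
reversals and the threshold is the arithmetic mean of the excursions at
the last six reversal trials. Such a rule converges on the excursion where
the psychometric function passes 2^(−1/2) ≈ 0.7071 proportion correct.

Conventions the procedure itself does not pin down were fixed as follows:

- *Reversal*: a trial whose excursion-change direction differs from the
  previous change (the standard transformed up-down definition).
- *Counter reset*: the correct-pair counter resets after each decrease
  and after any error, so an isolated correct response interrupted by an
  error never contributes to a later pair.
- *Step transition*: the change that completes the 4th (8th) reversal
  still uses the old step; the new step applies from the first change
  after it — the most literal reading of "reduced after four reversals".
- *Floor*: excursions never fall below 0.02 st (the smallest step). A
  clamped decrease is the only change whose magnitude may differ from the
  active step.
- *Incomplete runs*: if `max_trials` (default 1000) is exhausted first,
  the track is marked incomplete and the estimate uses the reversals
  available; incomplete tracks are always flagged non-compliant.

Simulated listeners are Weibull 3AFC observers
`p(x) = 1/3 + (2/3 − λ)(1 − exp(−(x/α)^β))` with slope β = 3 by default, a
typical psychometric steepness for pitch-direction discrimination. The
convergence point has the closed form
`x* = α·(−ln(1 − (2^(−1/2) − 1/3)/(2/3 − λ)))^(1/β)`, which exists only
while the asymptote 1 − λ exceeds 0.7071 (λ ≲ 0.2929). The test suite
verifies by simulation that mean staircase estimates over 500 seeded runs
track `x*` within 25 % for α ∈ {0.2, 0.5, 1, 2} st; the residual downward
bias of a few percent is the usual consequence of the asymmetric large
steps early in the run.

Thresholds are log-transformed (base 10) for parametric analysis; the
choice of base only rescales, so invariant checks are base-agnostic.

### Compliance screening

Visual inspection of individual tracks is replaced by a two-rule
heuristic: a track is flagged when (a) the coefficient of variation of the
last six reversal excursions exceeds 0.5, or (b) any excursion from the
first of those reversals onward exceeds 50 % of the start excursion (a
late jump back toward the start). Both cutoffs are configuration knobs.
The screen is a surrogate for human judgement: it catches high-lapse
observers (verified by simulation) but also flags genuinely poor
listeners whose thresholds sit near the start excursion. Excluding
flagged tracks therefore biases the worst cells of a cohort slightly
downward — the same selection effect that excluding "non-compliant"
children produces in real datasets — and the recovery report inherits it.

## Stimuli

Glide stimuli are log-linear in frequency and geometrically centred: an
excursion of `e` semitones runs from `center·2^(−e/24)` to
`center·2^(+e/24)` (500 Hz centre, 600 ms by default), which keeps upward
and downward glides mirror images in log-frequency. A knob switches to
Hz-linear glides; nothing downstream depends on the choice at these
excursions.

Pseudo-utterances are parametric: a stem of 3–5 syllables (250 ms each)
declining linearly from 220 Hz at −16 Hz/s, then a final word carrying a
linear glide of ±30–80 Hz. Statement and question members of a pair share
the identical stem, emulating cross-spliced natural pairs. Rendering is
additive synthesis — harmonics 1..15 at amplitudes 1/n for the speech
proxy; components at F0·{1,3,5,7,9,11,13,15} (the fundamental plus its
seven odd harmonics), one discrete tone per syllable, for the musical
analogue — with raised-cosine onset/offset ramps (15 ms) per syllable and
phase accumulated from the instantaneous F0. Gain is a fixed worst-case
bound rather than per-signal peak scaling so that pair members remain
sample-identical over the stem; `normalize_peak` provides explicit
amplitude matching where needed. The default sample rate is 22 050 Hz and
every component frequency is validated against Nyquist.

Only the F0 trajectory of these stimuli is meaningful. The speech proxy
has none of the spectral, temporal or segmental structure of natural
speech, so passing the acoustic round-trip tests shows that the *pitch*
pipeline is sound, not that the tracker would be robust to real voices.

Trial lists: the discrimination block pairs each statement–question pair
once as a "different" trial and once as a "same" trial (one member
repeated); which member repeats is balanced 9/9 across the 18 pairs so
response type is not confounded with sentence type. The identification
block presents all 36 members once. Order is shuffled under a seeded
generator; inter-stimulus and inter-trial intervals (750 ms / 2 s) are
carried as metadata.

## Acoustic scoring

F0 is tracked by frame-wise normalized autocorrelation (40 ms frames,
10 ms hop, 75–600 Hz search band, voicing threshold 0.5 on the peak,
silence gate at RMS 0.01) with parabolic interpolation of the peak lag;
the biased autocorrelation estimator is used deliberately because it
penalises double-period (sub-octave) candidates.

The signed final-word glide is the OLS slope of frame F0 on time over the
voiced frames of the final-word interval, multiplied by the interval
duration. Regression was preferred over last-minus-first frame because it
is robust to single-frame errors; for a linear glide the two coincide.
Frames within 20 ms of the interval edges are excluded — their analysis
windows straddle the boundary and mix stem F0 into the final word. A
dead zone of ±1 Hz maps near-zero glides to "ambiguous"; otherwise the
sign gives the label (rise → question, fall → statement), and an
imitation is correct iff its glide sign matches its model's. Ambiguous
imitations score as incorrect with a diagnostic. Final-word intervals
come from the stimulus specification for synthetic audio and from a
user-supplied annotation CSV for external recordings; there is no
automatic segmentation.

## The synthetic cohort

Each participant carries a latent log2 threshold (semitones) and a latent
intonation sensitivity on the d′ scale. Cell means of the threshold
default to: ASD children 1.0 (2 st), control children 0.0 (1 st), both
adolescent cells −1.0 (0.5 st), ASD adults −1.2, control adults −1.3
(≈ 0.43/0.41 st), with a between-subject SD of 0.8 log2 units — children
worse than adolescents/adults, and ASD children worse than control
children, the only group effect the package's recovery checks are
expected to find. Sensitivity is normal with mean 2.0 and SD 0.8; the
music condition adds a fixed d′ offset (default 0.3) and identification,
discrimination and imitation all share the same latent.

The two latents are coupled by a Gaussian copula on the threshold's
*population-wide* quantile (its CDF under the equal-weight mixture of the
six cell normals) with correlation `r = sin(π·τ/2)`, so the pooled-cohort
Kendall tau equals `tau_target` (default −0.4) exactly, cell effects
included. Coupling only the within-cell variation would dilute the pooled
tau, because between-cell threshold differences would then carry no
sensitivity information; the chosen construction also makes
worse-threshold cells somewhat less sensitive, which is the age-effect
direction expected of such data.

Trial behaviour is equal-variance signal detection: signal trials
("different"/"question") draw evidence from N(d, 1), noise trials from
N(0, 1), with the decision cut at d/2 (criterion 0: no response bias, the
null the bias analysis should recover; a config knob introduces bias for
testing). A per-participant lapse rate, uniform on [0, 0.04], mixes in
uniformly random responses, giving the compliance screen true positives
when raised. Imitations reproduce the model's glide sign with probability
Φ(d/√2) — chance at d = 0, saturating for large d — and a log-normal
magnitude (log-SD 0.3) around the model magnitude. None of this is a
claim about human choice processes; it is the simplest generator with the
monotone structure the analyses assume.

The staircase observer for a participant is the Weibull observer whose
convergence point equals the participant's latent threshold (α is solved
from the closed form, using the participant's own lapse), so threshold
recovery is unbiased by construction up to the staircase's own error.

## Scoring and statistics

d′ uses the log-linear correction — `H = (hits+0.5)/(n_signal+1)`,
`F = (FA+0.5)/(n_noise+1)`, `d′ = z(H) − z(F)`, `c = −(z(H)+z(F))/2` —
which keeps every contingency finite. The per-individual chance test is
the exact one-sided upper binomial tail P(X ≥ k) at p = 0.5 (both
response sets are binary), with scores classified "chance" when the tail
exceeds 0.05; a two-sided variant is available since the original
analyses do not state sidedness.

Interaction power uses the noncentral F distribution. Two formulations
are implemented: the fixed-effects "special effects and interactions"
form (λ = f²N, df1 = effect df, df2 = N − cells), and the
repeated-measures within-between form
(λ = f²Nm/(1+(m−1)ρ), df1 = (k−1)(m−1)ε, df2 = (N−k)(m−1)ε). The package
default for the study design is the fixed-effects form with df1 = 2 and
12 cells — the 2 (group) × 2 (condition) × 3 (age) three-way interaction —
because it is the only standard formulation that reproduces both planning
numbers the design is calibrated to (minimum N = 64 for power 0.80 at
f = 0.40, and power 0.91 at N = 84); the repeated-measures form with its
default k = 6, m = 2, ρ = 0.5 gives 66 and 0.90 instead. Note that in the
implemented repeated-measures noncentrality convention λ shrinks as ρ
grows, so power *declines* with the repeated-measures correlation.
Kendall tau is tau-b (tie-corrected), appropriate because simulated d′
values can tie; it is checked against an O(n²) concordance count.

## The recovery report

`run_experiment` ends by comparing estimates with generating values:
per-cell mean log2 threshold (compliant tracks only; tolerance = the
larger of 0.5 log2 units and 3 standard errors), the music − speech d′
difference (flagged if not positive when an advantage was generated), the
identification–imitation Kendall tau (positive expected, as the tasks
share a latent), and the threshold–sensitivity Kendall tau.

The last targets the *latent* correlation, and the raw tau between
staircase estimates and d′ is attenuated by measurement error in both
variables. The report therefore also applies a Spearman-style
disattenuation through the copula relation: observed tau → r, divided by
the square root of the product of the two reliabilities, → corrected tau.
Reliabilities are estimated from the run itself — a parametric bootstrap
of the staircase (15 replicate runs at each participant's estimated
threshold) for the log-threshold error variance, and the delta-method
(Gourevitch–Galanter) variance for each d′ — with no reference to the
generating values. Both the observed and the corrected tau are reported;
the tolerance flag (±0.15) applies to the corrected one. The correction
assumes roughly homoscedastic noise, which the staircase violates at very
small thresholds (additive steps mean larger log-scale error there), so
the corrected tau remains a mildly conservative estimate.

Problem sizes used by the checks: tau and music-advantage recovery run on
a 60-participant cohort (10 per cell); staircase convergence uses 500
runs per observer scale; the acoustic round-trip uses 200 synthesized
utterances with glides of 10–100 Hz. These sizes make the Monte-Carlo
error comfortably smaller than the stated tolerances.

## Known limitations

- The compliance screen confounds inattention with genuinely poor
  thresholds near the start excursion (see above).
- The F0 tracker is tuned to clean harmonic synthesis; it has no
  protection against octave errors in noisy or breathy natural voices.
- The response generator has a fixed criterion per participant; it cannot
  produce trial-order effects, learning, or fatigue.
- Bayes-factor analyses (ANCOVAs, Bayesian Kendall correlations) are out
  of scope: the package exports the tables such analyses would consume
  (per-type accuracy proportions, d′ per cell) but computes only the
  frequentist/point quantities.
- The original sentence texts and natural recordings are not modelled;
  pair identity is abstract and the speech proxy's timbre is synthetic.
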