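# Methods

Models, conventions, parameter defaults and known limitations of
`cogniphys`, in the package's own words. Units are degrees (gaze angle),
milliseconds (RR intervals), millilitres (respiratory volume),
beats/min and breaths/min unless stated.

## Gaze event detection

**Blinks** are maximal runs of invalid samples (or non-finite pupil
radius). A run's duration is `t[last] + dt - t[first]`, i.e. each sample
owns one sample period; 15 lost samples at 100 Hz are a 0.15 s blink.
Runs longer than `blink_max_gap` (default 0.5 s) are classified as
tracking loss and are not blinks.

**Fixations** use dispersion-threshold identification (I-DT) on valid
samples only: a window is grown while its dispersion
`sqrt((x_max-x_min)^2 + (y_max-y_min)^2)` stays below `d_max`
(default 1 degree); windows shorter than `min_fix_duration`
(default 0.1 s) are discarded. Because invalid samples are excluded
before windowing, a blink inside a steady fixation does not split it.
Event duration uses the same one-period-per-sample convention.

**Saccades** are maximal runs of filtered angular speed at or above
`v_threshold` (default 30 deg/s; central differences followed by a
3-point median filter) whose span lies within physiological duration
bounds (default 30-80 ms). Amplitude is the start-to-end angular
distance, mean velocity is amplitude/duration (a chord-based definition
that is robust to how the run boundaries cut into the velocity ramp),
and runs touching invalid samples are dropped. Below 60 Hz sampling,
velocity estimates are logged as low-confidence.

**Scan-path statistics.** Dwells merge consecutive fixations whose
centroids fall in the same rectangular ROI (closed minimum edges, open
maximum edges; overlapping ROIs are rejected at construction). The
transition matrix counts one-way dwell-to-dwell transitions, giving a
zero diagonal by construction; visual entropy is
`H = -sum_i p(X_i) sum_j P_ij log2 P_ij` in bits, where `p(X_i)` weights
each ROI by its fixation share. The nearest-neighbour index divides the
observed mean nearest-neighbour distance of fixation centroids by the
complete-spatial-randomness expectation `0.5*sqrt(area/N)`. Pupil band
power integrates a Welch density of the blink-interpolated pupil trace
over 2-6 Hz by default.

## Cardiac metrics

Cleaning rejects intervals outside 300-2000 ms or deviating more than
30% from the median of their five nearest neighbours; a rejection
fraction above 20% is logged. SDRR/SDNN use the sample (n-1) standard
deviation, RMSSD averages the squared successive differences, and pNN50
counts strictly greater-than-50 ms successive differences. Dispersion
metrics of a single interval are NaN, not zero.

Band powers over ULF (<=0.003 Hz), VLF (0.003-0.04), LF (0.04-0.15) and
HF (0.15-0.4) come from either a Lomb-Scargle periodogram on the
beat-stamped tachogram or cubic-spline resampling at 4 Hz followed by a
Welch periodogram. Both estimators are normalised so the full-spectrum
integral equals the variance of the original beat-stamped series
(Parseval convention). That normalisation matters for the Welch path:
spline interpolation of a ~1.25 Hz beat-sampled series slightly
attenuates 0.3 Hz content, and without the correction the two methods
disagreed by just over 2% on stationary tones. LF/HF requires a 2-minute
record; ULF/VLF require 5 minutes and are NaN below that, with a note.
`lf_pct`/`hf_pct` are taken against total 0-0.4 Hz power and the LF/HF
ratio is expressed in percent.

Poincaré `SD1 = sqrt(0.5*Var(RR_i - RR_{i+1}))` and the SD2 analogue use
the sample (n-1) variance; the ellipse is the pi/4-rotated
`(2*SD2, 2*SD1)` body centred at the scatter mean. Two identities pin
the implementation: `SD1 ~ RMSSD/sqrt(2)` and
`SD1^2 + SD2^2 ~ 2*SDRR^2` (both within 2% on long stationary series).

## Respiration

Cycles are found by alternating peak/trough detection on the 1 Hz
low-pass-filtered volume trace (minimum 1 s spacing, prominence 10% of
range). Each peak is paired with the most recent preceding trough;
tidal volume is the filtered peak-to-trough excursion. Breathing rate is
the reciprocal mean peak-to-peak period — exact for periodic traces and
unbiased by partial cycles at the record edges. Minute ventilation is
`BR * mean(TV) / 1000` litres/min. Fewer than two full cycles is an
error, not a guess.

## Filtering

`butterworth_chain` applies notch, high-pass and low-pass stages in that
order, each zero-phase (forward-backward). Because filtering twice
squares the magnitude response, the -3 dB point of a naive two-pass
Butterworth sits below the design cutoff; the cutoffs are pre-warped by
the factor `(sqrt(2)-1)^(1/(2n))` so the two-pass response keeps passband
tones (e.g. 10 Hz through a 30 Hz low-pass) within 1% of unity gain.

## Sugeno fuzzy engine

A model is an ordered list of named inputs, each with a labelled
membership inventory (trapezoid, Gaussian or sigmoid, all with analytic
derivatives and JSON round-trip serialisation), plus rules whose
antecedents reference those labels (missing input = don't care) and
whose consequents are polynomials `f_k = p_k0 + sum_i p_ki x_i`.
Inference is the classic five-layer computation: product-AND firing
strengths, normalisation, weighted-average defuzzification. A point
where every rule's firing strength is zero raises `RuleCoverageError`
rather than returning an arbitrary value.

**Calibration** (`fit`) solves the consequents by linear least squares
on the normalised-firing design matrix (columns `wbar_k`, or
`wbar_k*[1, x]` for first order), reporting estimates, standard errors,
RMSE and R^2 in a results object with `summary()`, `params_frame()` and
`predict()`. Rules that never fire above a small floor make the problem
singular and are named in the error. Optional premise refinement wraps
the linear solve in a Nelder-Mead search over membership parameters.

**Reference workload model.** The bundled three-rule system maps heart
rate and breathing rate to mental workload with rule outputs 1, 0.5 and
0.1. Membership spreads follow a half-nearest-neighbour rule: each
fuzzy set's width is half the distance to the nearest other cluster
centre along that axis, which gives Gaussian sets moderate overlap and
trapezoid sets disjoint compact supports (so exactly one rule fires at
each anchor point — the configuration the acceptance targets use). Two
rule alignments are provided: `"printed"` follows the published rule
table (high HR + low BR -> high workload), `"clusters"` ties each rule
to one empirical cluster centre.

**Uncertainty propagation** maps input sigmas to an output sigma by the
delta method. The gradient of the output includes the derivative of the
normalised weights (computed analytically from the membership
derivatives), and the default combines the full gradient *before*
squaring. A per-rule decomposition that treats the normalised weights of
different rules as independent is also available (`sigma_wbar`
argument), but it is not the default because the normalised weights sum
to one and are therefore strongly anti-correlated; treating them as
independent misstates the sigma even in the small-sigma limit.

**Validity of the first-order sigma.** The expansion is accurate when
input sigmas are small against the membership spreads (verified against
Monte-Carlo within ~6% at sigma ~0.05 of the spread, converging as
sigmas shrink). At the headline input sigmas of 5.5 beats/min and
1.6 breaths/min the inputs range across several membership widths and
the first-order sigma deviates from Monte-Carlo by order 100%; in that
regime the sigma surface is a qualitative conflict indicator — it peaks
between clusters, never at a cluster centre — not a calibrated error
bar. This is why one acceptance test is intentionally left failing.

## Characterisation

Precision is the RMS angular distance of cluster samples about their own
mean; accuracy is the angular distance between the cluster mean and the
target. Two-sigma dynamic accuracy fits a lognormal by maximum
likelihood to strictly positive errors (n >= 20) and reports
`exp(mu + 2*sigma)`; non-positive errors are rejected with their
indices. Field-of-view uncertainty evaluates its closed form literally
and raises on a negative radicand. Validity reports
`RMS = sqrt(mean((ref - meas)^2))` and the standard product-moment
correlation; zero-variance inputs give `cc = None` with a note rather
than NaN. Pair alignment joins on nearest timestamps within a 0.5 s lag,
counting dropped samples.

## Synthetic data

Generators are deterministic per seed and return ground truth alongside
the signal, and their defaults *are* the study conditions — they are not
tuned to the detectors.

- Gaze: a continuous event timeline (fixation, saccade, fixation, ...)
  sampled onto the clock grid; fixation durations 0.3 +/- 0.1 s, ROI
  targets follow a transition matrix (uniform off-diagonal by default),
  saccades have a 300 deg/s peak-velocity profile, blinks arrive as a
  Poisson process (10/min) thinned against saccades, gaze jitter is
  0.05 degrees, pupil baseline 3 mm. With jitter and duration spread set
  to zero the event sequence is fully deterministic and detector round
  trips are exact; with the stochastic defaults, fixation counts round-trip
  within ~2% (jitter can split an occasional long fixation).
- Cardiac: RR intervals accumulate beat by beat with sinusoidal LF/HF
  modulation (25 ms at 0.1/0.3 Hz) plus white jitter; truth includes the
  closed-form band powers `amp^2/2`. Optional ectopic beats.
- Respiration: sinusoidal volume with configurable rate, depth, drift
  and noise.
- Workload sessions: three labelled 200 s segments at 1 Hz whose HR/BR
  samples scatter (sd 1.5 / 0.5) around the low/mid/high cluster
  centres.

Realism limits: the generators produce stationary, piecewise-ideal
signals. There is no respiratory sinus arrhythmia coupling, no pupil
light reflex, no smooth pursuit, no sensor drift beyond the linear term,
and saccade kinematics ignore the main-sequence amplitude-velocity
relation. They are designed for detector verification, not for training
models intended to transfer to human data.

## Pipeline

`run_pipeline` extracts whole-record features per modality, then cuts
the session into sliding epochs (60 s window, 10 s step by default),
computes epoch HR from the mean RR and epoch BR from the respiration
trace, and runs uncertainty-aware inference per epoch. Epochs outside
rule coverage report a null state rather than failing the run. The
report embeds a manifest (config hash, seed, package/python/numpy
versions) so a rerun with the same manifest is identical. Configuration
is a typed, YAML-round-trippable object that rejects unknown keys.

## Open design decisions

- ROI membership at edges: closed minimum, open maximum; lowest-indexed
  ROI wins (layouts with overlapping ROIs are rejected anyway).
- Mean heart rate comes from the raw RR mean; SDNN/pNN50 from the
  cleaned NN series; SDRR/RMSSD from the raw series — the names state
  the series they use.
- `explore_exploit_ratio` with no long fixation raises
  `ZeroDivisionError` instead of returning infinity.
- The CLI exits with code 2 on validation errors (bad headers, bad
  values, malformed parameters) and lets genuine bugs surface as
  tracebacks.
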