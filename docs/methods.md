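# Methods

`eegoverlap` studies one confound and one cure. The confound: stimulus-locked
and response-locked ERP components superpose in continuous EEG, and because
their relative timing varies with response time, response-locked *averages* of
a purely stimulus-evoked transient can look exactly like an
evidence-accumulation ramp (a centro-parietal positivity building to the
response, steeper for fast trials). The cure: joint FIR deconvolution of
stimulus and response events, which attributes the variance to the event each
component is actually locked to. Everything here runs on synthetic data whose
generative decomposition is stored exactly, so every analysis stage can be
validated against ground truth.

## Behavioural generator

Eight per-trial measures arise from two latent constructs: appraisal `a` (how
positively the choice set is evaluated) and choice difficulty `c`. `(a, c)`
are standard bivariate normal with correlation ρ (default 0.2). Writing
`ease = −c`:

- overall value `OV = 0.5 + 0.15·a + ε`, value difference
  `VD = max(0, 0.5 + 0.15·ease + ε)` with value-noise sd 0.06;
- liking = `a + ε`, anxiety = `−ease + ε`, confidence = `ease + ε` with
  rating-noise sd 0.4, clipped at ±1.5 (rating scales are bounded; see
  "Numerical notes" for why saturation matters);
- item values `v± = OV ± VD/2`; the chosen item is the better one with
  probability `σ(5·VD)` (softmax), giving chosen/unchosen value;
- set salience = |OV − mean(OV)| (computed, like VD and OV, from the same
  item values — the derived quartet is deterministic given `OV, VD` and the
  choice).

RTs follow a shifted lognormal, `rt = s + exp(µ₀ + β_VD·VD + β_OV·OV + σ·ε)`
with `β_VD, β_OV ≤ 0` enforced (faster decisions for easier and better sets),
truncated at a 4 s deadline; truncated trials carry no response event.
Defaults: s = 0.3, µ₀ = 0.1, σ = 0.4, β_VD = −0.4, β_OV = −0.3 (mean RT
≈ 1.15 s). The EEG experiments use a faster parameterization
(`fast_rt_behaviour`: s = 0.15, µ₀ = −0.25, σ = 0.35, mean RT ≈ 0.75 s),
matching the short-RT regime in which the overlap artefact is most deceptive.

The default trial count is 4,637, the size at which the construct PCA is
routinely reported in this literature.

## EEG generator

Trials are laid out sequentially (stimulus → response after RT → next
stimulus after a 1.8 s inter-trial interval). Components, each placed per
trial and projected through a spatial-Gaussian topography on template 10-20
coordinates (σ = 0.07 m):

- **stimulus transient**: raised-cosine bump over [0, 0.7) s post-stimulus,
  peaking at 350 ms, base amplitude 5 µV at the topography centre (Pz),
  amplitude `5 + g_A·a` per trial;
- **response component** (optional): biphasic full sine cycle over ±150 ms
  around the response, centred on Cz, amplitude modulated by `g_C·ease`;
- **accumulation ramp** (optional): linear rise from stimulus + 200 ms to a
  peak at the response, then a 150 ms fall, centred on Pz;
- **noise**: white Gaussian (default sd 2 µV per sample) plus optional 1/f^α.

The generator returns the recording, the event table, and a `GroundTruth`
holding every placed waveform and the exact noise realization; the identity
`recording = Σ placements + noise` holds to machine precision and is asserted
in tests. Working rate is 250 Hz with 8 channels (Fz, Cz, CP1, CP2, Pz, P3,
P4, Oz); the sizes (120–400 trials, 6–8 participants per experiment) were
chosen as desk-scale defaults that keep each experiment in the seconds-to-
minutes range while leaving the tested effects far from their decision
thresholds.

What the generator does *not* emulate: realistic head-model mixing (the
Gaussian topography has no dipolar structure), ocular/muscle artefacts,
trial-to-trial latency jitter of the stimulus transient, and autocorrelated
measurement noise beyond 1/f. Passing tests therefore show that the analysis
chain behaves correctly when its assumptions hold, not that real data meet
those assumptions.

## Construct scoring

Measures are min–max normalized to [0, 1]. The number of retained components
comes from a permutation test: 1,000 null datasets, each shuffling every
column independently (destroying cross-column structure, preserving
marginals); component k is retained iff its observed eigenvalue exceeds the
95th percentile of the null distribution of eigenvalue k. PCA is computed on
the covariance of the normalized data (correlation is available as an
option); the retained loadings are rotated with Kaiser-normalized varimax
(tolerance 1e−8, cap 1,000 iterations; checked against R's
`stats::varimax(normalize=TRUE)` in the tests), and trial scores are the
normalized indicators times the rotated loadings. Components are labelled by
convention — appraisal is the component loading most strongly on liking,
sign-fixed positive on liking; choice is oriented so larger = more difficult
(negative on confidence and value difference, positive on anxiety).

Recovery is quantified by Tucker congruence against reference loadings from
one large-sample (n = 50,000) run of the generator rather than against a
"true" loading matrix: three measures (salience, chosen/unchosen value) are
deterministic nonlinear functions of the latents and have no generative
linear loading.

## Regression ERPs

First-level inference is mass-univariate OLS: voltage at each channel × time
point regressed on trial predictors plus an intercept, fit independently per
point using only trials unmasked there (listwise at that point only; points
with fewer than p + 2 usable trials or a rank-deficient design are marked
missing). Betas divided by their standard errors give t-maps, shrinking
unreliable estimates toward zero before group statistics. Samples outside a
trial's [stimulus, response] span are invalidated at epoching to prevent
spill-over. Descriptive views: predicted ERPs at within-tercile predictor
means, RT-sorted ERP images with per-row counterpart-event markers, and
fast/slow median-split averages (ties to fast) with an optional RT ceiling
(e.g. 1.25 s) for short-RT subsets.

In the overlap-artefact report, "ramp steepness" is the slope of each
median-split group's **own rising flank** — a 0.35 s window ending at that
group's peak — because the slow group's smeared transient peaks earlier, and
a fixed pre-response window would measure its decay instead of its rise.

## Cluster-mass permutation statistics

Group inference is a one-sample t across participants at each point, a
two-tailed cluster-forming threshold of P = 0.005, and connected components
over channel adjacency at a fixed time ± temporal contiguity (±1 sample;
diagonal links off by default; opposite polarities never merge). Cluster mass
is Σ|t|. The null is built by sign-flipping whole participants' maps (the
standard one-sample scheme; the flip is the package's choice where the
resampling unit was ambiguous), recording the maximum mass per polarity over
1,000 permutations. A cluster is significant when its mass exceeds the top
2.5% of its polarity's max-mass null; reported p is twice the exceedance
fraction, floored at 2/n_perm and clipped to 1. Channel adjacency is
distance-thresholded Euclidean distance on the montage (default threshold
0.065 m, giving ~4–8 neighbours on a dense 10-20 layout); zero-variance
points are excluded from clustering rather than set to ±∞. Calibration is
checked empirically: across 200 null experiments (20 participants, 8 × 100
maps) the family-wise positive rate must sit in the 95% binomial interval
around 0.05.

## FIR deconvolution

The time-expanded design has one column per (event type × predictor ×
latency bin), one bin per sample (stick basis), windows configurable per
event type (±2 s is the conventional choice for slow paradigms; the
experiments here use tighter windows that cover the kernels and the overlap
range, e.g. stimulus [−0.2, 1.0) s and response [−1.0, 0.4) s). Continuous
covariates are mean-centred within event type so intercept kernels read as
average waveforms; trials without a response contribute stimulus events
only, and events with missing covariates are modelled intercept-only.
Samples where any channel exceeds ±250 µV are dropped from the fit (rows
removed, optional guard margin, error if > 90% excluded). Each channel is
solved by LSMR to relative tolerance 1e−10 (minimum-norm least squares; no
regularization by default, ridge available), making solutions deterministic
to ~1e−10 across runs. `correct_overlap` subtracts any event type's
reconstructed contribution from the recording — e.g. removing the stimulus
contribution before response-locked epoching, after which the spurious
fast/slow ordering of overlap-only data collapses (> 80% shrinkage of the
pre-response gap in tests).

In the no-overlap limit (all events separated by more than the FIR window)
the design is block-orthogonal and deconvolution reproduces event-locked
averages to 1e−6, which the tests assert as a closed-form limit.

## Drift-diffusion traces

The accumulator starts at a/2 between absorbing bounds 0 and a and follows
Euler–Maruyama with a Brownian-bridge crossing test each step (crossing
probability `exp(−2(b−x_t)(b−x_{t+dt})/(s²dt))`), which removes the O(√dt)
first-passage bias of naive stepping; the crossing time is linearly
interpolated inside the final step, so with s = 0 the decision time is
(a/2)/v exactly. Non-decision time splits into `t_s ~ U(0, stim_jitter)`
before accumulation and `t_m ~ U(0, motor_jitter)` after threshold;
RT = t_s + DT + t_m. The three scenarios fix (stim, motor) jitter at
(0.2, 0.1), (0.2, 0.2) and (0.1, 0.2) s. The closed-form mean decision time
for symmetric start, `(a/(2v))·tanh(av/(2s²))`, is the simulation's
independent oracle.

Traces are the evidence accumulated toward the chosen bound (0 at onset, a/2
at threshold). For the credit-assignment analysis traces end at threshold
crossing (`hold_during_motor=False`): holding the bound through the motor
time would add a motor-locked plateau whose duration grows with
motor_jitter and contaminate the accumulation-energy bookkeeping. The
assignment statistic is `E_stim / (E_stim + E_resp)` with `E` the summed
squared intercept kernel per event type. Defaults for this analysis are
drift 1.0 (strong) / 0.5 (weak), bound 1.0, diffusion sd 0.15 — a
jitter-dominated regime: when the diffusion-induced decision-time spread
(≈ 0.3 s at s = 0.5) swamps the 0.1–0.2 s jitters, neither event predicts
the accumulation epoch and the ratio manipulation has nothing left to
redistribute. This regime dependence is a real property of the method, and a
known limitation of the energy-share readout.

## Numerical notes and edge cases

- Time is sample-indexed internally; seconds→samples rounds to nearest;
  all windows are half-open [start, end).
- Rating saturation matters for component counting: an unbounded-normal
  rating has var/range² ≈ 0.02 after min–max scaling while the half-normal
  salience column sits near 0.03, and the positional eigenvalue-vs-null
  comparison then flags salience as a third "component". Bounded scales
  (clip ±1.5) put the ratings' normalized variances above salience's and the
  two-construct spectrum is recovered — a caveat worth remembering whenever
  parallel-analysis-style criteria meet derived magnitude variables.
- The gradient rejection criterion is interpreted as the maximum absolute
  successive-sample difference; white noise makes it fire constantly, so
  artefact-rejection tests use smooth (random-walk) signals with injected
  jumps.
- Baseline correction uses only unmasked samples and flags (never zeroes)
  trials with an empty baseline; statistics over windows always report the
  sample count used.
- Resampling is integer-factor polyphase decimation (`padtype="line"`,
  constants preserved to 1e−9); for epochs, masked samples propagate as NaN
  through the filter and the output is conservatively masked wherever the
  filter support touched one.
- The pre-response amplitude contrast uses the [−0.7, −0.2) s window.
- EDF recordings can be read (via MNE); on-disk round-tripping uses a raw
  float32 binary + JSON sidecar bundle. EDF writing is not provided.

## Known limitations

- The energy-share statistic depends on the kernel windows; very long
  windows accumulate noise energy far from the event.
- The cluster permutation scheme resamples participants, not trials;
  within-participant exchangeability is never invoked, but n_participants
  must be large enough for 2^n sign patterns to support the tail (n ≥ 8
  recommended).
- Min–max normalization ties construct scores to sample extremes; scores
  are comparable within a dataset, not across datasets.
- The deconvolution model is linear and time-invariant per event type;
  genuinely duration-varying components (ramps) are captured only in the
  mean, which is precisely why the rescue analysis reports them at the
  event they are time-locked to rather than reconstructing single trials.
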