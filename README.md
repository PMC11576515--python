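# eegoverlap

Tools for studying — and correcting — **component overlap** in event-related
EEG. When a stimulus-evoked transient and a response are separated by a
response time that varies from trial to trial, response-locked averages of
purely stimulus-locked activity can reproduce every classic signature of an
evidence-accumulation signal: a centro-parietal ramp peaking near the
response, steeper for fast trials, with larger pre-response amplitude for
slow ones. This package simulates continuous EEG with known ground truth,
exposes the artefact with standard analyses, and removes it with linear
deconvolution.

It is written for EEG researchers working on decision signals (CPP/LPP-style
analyses) who want a tested, ground-truth-validated reference implementation
of the full chain:

- **simulation** — behavioural measures from two latent constructs
  (appraisal, choice difficulty), RTs decreasing with value difference and
  overall value, continuous EEG as a sum of placed components plus noise,
  and drift-diffusion accumulator traces with uniform stimulus/motor
  non-decision jitter;
- **construct scoring** — min–max normalization, permutation-tested PCA
  dimensionality (95th percentile of 1,000 column-shuffled nulls),
  Kaiser-normalized varimax, score projection;
- **regression ERPs** — mass-univariate OLS per channel × time with
  missing-data masking, t-maps, tercile-predicted ERPs, RT-sorted ERP
  images, median-split averages;
- **cluster statistics** — group-level spatiotemporal cluster-mass
  permutation tests (cluster-forming P = 0.005, participant sign-flipping,
  two-sided 2.5% max-mass tails);
- **deconvolution** — FIR/stick time expansion per event type, sparse
  minimum-norm least squares (LSMR), artefact-interval exclusion, RT
  modulation of stimulus regressors, and overlap-corrected residuals.

## The model in brief

Observed EEG is modelled as a linear superposition of event-locked kernels:

    y(t) = Σ_e Σ_i Σ_τ  x_i^e · β^e(τ) · 1[t = t_i^e + τ] + ε(t)

where `e` indexes event types (stimulus, response), `i` events, `τ` latency
bins, and `x_i^e` per-event predictor values (intercept, appraisal score,
choice score, RT). Event-locked averaging estimates `β` correctly only when
events of different types do not overlap within the kernel window; joint
least squares on the time-expanded design estimates all kernels
simultaneously and remains unbiased under overlap. First-level t-maps
(β/SE) feed a cluster-mass permutation test: clusters of |t| above the
two-tailed P = 0.005 threshold, mass Σ|t|, compared against the per-polarity
maximum-mass distribution over 1,000 participant sign-flips.

## Worked example

```python
from eegoverlap.experiments import OverlapArtefactConfig, run_overlap_artefact

report = run_overlap_artefact(OverlapArtefactConfig(seed=31))
print(report["peaks"])
print(report["checks"])
```

The simulated EEG contains **only** a stimulus transient (raised-cosine bump
peaking 350 ms post-stimulus, plus noise) — no response component, no ramp.
Yet the response-locked RT-bin averages print:

```
 bin  mean_rt  peak_time  peak_amp
   0    0.509     -0.160     4.923
   1    0.647     -0.296     5.116
   2    0.775     -0.396     5.417
   3    1.052     -0.636     3.701
```

The "component" peaks 160 ms before the response for the fastest quartile
and drifts out to −636 ms as mean RT grows — the stimulus bump, riding at
−RT + 0.35 s in the response-locked frame. The fast/slow median split of
short-RT trials rises at 13.1 vs 6.8 µV/s: the full evidence-accumulation
phenotype, from data that contain no accumulation signal. Running the same
config with `ramp_truth=True` (a genuine ramp, no stimulus transient) pins
every bin's peak to the response (|peak| ≤ 40 ms), which is how a real
accumulation signal behaves under the same analysis.

The companion experiment `run_deconv_rescue` analyses overlap-only data both
ways and prints (seed 41):

```
naive response-locked RT contrast: 7 significant cluster(s), min p = 0.006
after deconvolution: 0 significant cluster(s), min p = 1.000
stimulus-kernel nRMSE: 0.128 (default noise), 0.032 (high SNR)
```

— the spurious RT effect is significant in the naive analysis, vanishes
after joint stimulus+response deconvolution, and the deconvolved stimulus
kernel matches the generative one to 3% at high SNR.

## Analysis scripts

The `analysis/` directory holds the narrative drivers, each writing tables
under `results/`:

| script | what it shows |
| --- | --- |
| `01_simulate_dataset.py` | reference behavioural + EEG dataset; RT falls across value-difference and overall-value terciles |
| `02_score_constructs.py` | permutation PCA finds 2 components; rotated loadings separate appraisal from choice |
| `03_overlap_artefact.py` | overlap-only vs genuine-ramp response-locked morphology |
| `04_deconv_rescue.py` | spurious RT contrast before, none after deconvolution |
| `05_ddm_credit_assignment.py` | accumulation energy shifts toward the stimulus kernel as motor jitter grows (ratios 2/1 → 1/1 → 1/2) |
| `06_full_pipeline.py` | end-to-end positive control: PCA scores → stimulus-locked appraisal cluster |

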