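# Methods

## Model

Gait EMG envelopes are modelled as a non-negative mixture
`M ≈ W H`, with `M` the muscles × time matrix of per-stride envelopes
(time-normalized to 100 points per gait cycle, 20 strides concatenated →
muscles × 2000), `W ≥ 0` the muscle weightings of each synergy and `H ≥ 0`
their activation profiles. The assumptions are the standard ones of
synergy analysis: muscle coordination is low-dimensional, additive and
non-negative, and the spatial structure (`W`) is stable across strides while
timing (`H`) varies stride to stride.

Both the free factorization and the fixed-component reconstructions use
multiplicative updates,

```
H ← H ∘ (Wᵀ M) / (Wᵀ W H)        W ← W ∘ (M Hᵀ) / (W H Hᵀ)
```

which preserve non-negativity and never increase the squared Frobenius
error; a 1e-12 epsilon guards 0/0 without affecting float64 results. Frozen
factors are returned bit-identical. The free fit runs seeded uniform-random
restarts (default 20, max 1000 iterations, relative-error tolerance 1e-6)
and keeps the lowest-error run; fixed seeds give bit-reproducible output.

Reconstruction quality is VAF = 1 − SSE/SST with *uncentered* SST (sum of
squared entries), totalled and per muscle; rows with zero SST report NaN
rather than a silent 0. The model order is the smallest J whose total VAF
exceeds 0.90, or past which adding a synergy improves no single muscle's VAF
by more than 0.05; if no J up to the muscle count satisfies either clause
the cap is returned with a warning flag.

## Patient assessment

The patient's envelope matrix is reconstructed twice against a healthy
template whose weight columns are unit-normalized: once with `W` frozen
(recovering per-stride activation profiles, averaged to a mean cycle) and
once with the healthy mean profiles frozen and tiled across the patient's
strides (recovering weights). Four metrics per synergy compare patient and
template, all in [0, 1] with 1 = healthy-like:

* **similarity** — cosine between weight vectors (from the fixed-H fit);
* **correlation** — maximum of the centered, normalized circular
  cross-correlation between mean activation profiles (from the fixed-W fit);
* **t_lag** — `1 − |lag|/100`, lag the argmax of the cross-correlation in
  percent of the gait cycle, in [−50, 49]; the sign convention is positive =
  patient delayed relative to the template, ties broken toward smaller |lag|;
* **activation** — `1 − |d_p − d_h|/100`, where durations count the samples
  strictly above the profile minimum plus 20 % of peak-to-peak amplitude.
  The count is total supra-threshold time, so two-burst profiles are handled
  without an onset/offset pairing; flat profiles get duration 0 with a
  warning.

Normative thresholds are pooled across the healthy cohort's subjects *and*
synergies (each subject assessed against the group template with the same
two reconstructions), one threshold per metric at mean − 2·SD (sample SD,
ddof 1). A synergy is impaired when at least one metric is *strictly* below
its threshold: equality passes, which is required to reproduce the published
worked example where a timing score of 0.96 meets a 0.96 threshold and is
not flagged.

## Stimulation strategy

Per-muscle drives are `W[:, impaired] · H[impaired, :]`. A muscle whose peak
drive is below 10 % of the strongest muscle's is treated as not recruited
and silenced — cohort-averaged templates carry a small positive noise floor
on every weight (truncated-Gaussian bias), and the per-muscle rescale to
peak intensity 1 would otherwise amplify that floor to full stimulation.
Profiles are gated to zero below baseline + 20 % of peak-to-peak (fatigue
rule, applied before grouping), rescaled per muscle to [0, 1] with the scale
factor stored for inversion, and grouped: muscles whose gated profiles have
cosine ≥ 0.99 share one channel (greedy single linkage in muscle order).
The 0.99 default separates *identical-shape* profiles — muscles driven by
the same single synergy, like the two hamstrings or the two calf muscles —
from merely similar ones; muscles sharing a dominant synergy plus small
cross-talk correlate at ~0.97 and stay on separate channels, reproducing the
6-channel layout for an 8-muscle montage. Intensity maps linearly to pulse
width (0–400 µs, nearest µs) at a common 20 Hz; per-channel current
amplitude is clinical calibration input, never computed.

## Gait phases and warping

Six phases are decoded from IC/EC/MS events of both legs (paretic double
support → non-paretic initial swing → non-paretic terminal swing →
non-paretic double support → paretic initial swing → paretic terminal
swing); this boundary table is the unique assignment consistent with the
phase names and the three event types per leg. Any out-of-order event raises
a sequence violation naming the expected event. Each phase's duration
estimate is the mean of its last five observed durations. Warping splits the
100-point template at the phase fractions (default 12/19/19/12/19/19 %, the
synthetic cohort's timing), linearly resamples segment p to
`round(duration_p × rate)` samples and concatenates, so changing one phase's
duration changes only that segment. The offline simulator replays this
causally: stride k is warped with estimates from completed strides only; the
first stride, with no history, uses the template proportions scaled to its
observed cycle time. Phases mapping to zero samples are skipped with a
warning.

## Synthetic data

The generator emulates the statistical structure of healthy gait EMG, not
its biophysics. The canonical template has four unit-norm synergies with
raised-cosine activation bursts: WA (gluteus maximus + vastus medialis,
burst center 14 % width 26), PO (gastrocnemius + soleus, 47/28), FC (rectus
femoris + tibialis anterior, two bursts 4/12 and 66/24) and LD (both
hamstrings, 92/24, wrapping the cycle boundary), with cross-talk weights
≤ 0.15. Burst geometry was chosen so each synergy carries enough distinct
signal energy that the VAF order rule resolves all four at the default noise
(a noiseless 3-synergy fit reaches only ~0.80 total VAF).

Cohort conditions (defaults, chosen once as realistic for a young healthy
cohort): 13 subjects × 20 strides; between-subject weight noise SD 0.10
(truncated at zero, columns renormalized); per-subject systematic timing
offset SD 2 points and burst-width scale SD 0.10 (clipped to [0.7, 1.3]);
per-stride timing jitter SD 2 points and synergy gain SD 0.10; additive
Gaussian envelope noise with SD 5 % of the clean peak, clipped at zero.
Width scaling operates per burst about each burst's own center, so widening
a two-burst profile changes durations without moving the second burst.

Stroke-like patients deform the template itself (no between-subject
perturbation): merged pairs sum and renormalize the two weight columns and
drive them with the elementwise maximum of the two profiles; lag shifts
rotate a profile circularly (negative = early recruitment, e.g. the
spastic early plantar-flexor pattern); duration scales widen bursts. With no
deficits the patient is the template plus stride-level noise — the
healthy-like control used for closure testing.

What passing tests show — and what they do not: the synthetic envelopes are
exactly low-rank plus noise, with no motor-unit physiology, crosstalk
between electrodes, movement artifact or non-stationarity across the
session. Closure results (deficits detected, healthy patients passing)
validate the pipeline's logic and calibration under the stated noise model,
not clinical sensitivity or specificity on recorded EMG.

## Numerical choices and problem sizes

* Zero-phase (forward-backward) Butterworth filtering, doubling the
  effective order, keeps envelope peaks aligned with gait events.
* Stride windows are half-open `[IC_i, IC_{i+1})`, an exact partition.
* Median over an even stride count is the mean of the two middle values.
* Time normalization is linear interpolation (no overshoot on non-negative
  envelopes); endpoints are preserved.
* "Removing acceleration/deceleration phases" is a configurable trim
  (default 3 strides each end) followed by a centered 20-stride selection.
* Patient envelopes are normalized by the patient's own median maxima,
  mirroring the healthy protocol.
* Assignment between synergy sets maximizes total weight cosine via the
  rectangular Hungarian algorithm; ties resolve by synergy index.
* Test and acceptance runs use 5 NMF restarts, 300 iterations and tolerance
  1e-5 — on 8 × 2000 envelope matrices this sits within ~1e-3 VAF of the
  20-restart default while keeping a full cohort build under two seconds.

## Known limitations

* The generator's raised-cosine bursts are an invented concretization of the
  canonical synergy timings; real activation profiles are asymmetric.
* The grouping threshold and recruitment floor are heuristics exposed as
  configuration; electrode feasibility of a merged channel is not modelled.
* The simulator re-plans only at phase entry (as the duration-averaging rule
  implies) and does not model sensor latency or missed events.
* Muscle sets are configurable but template and patient sets must agree; no
  cross-montage matching is attempted.
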