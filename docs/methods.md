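# Methods

This note documents the models, parameter choices and numerical
conventions behind `bhcvr`, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Physiological trace processing

All processing after extraction runs on a 10 Hz grid; resampling is
linear interpolation. End-tidal and RVT series are themselves
piecewise-linear envelopes through sparse breath-wise points, so linear
resampling introduces no new extrema; no anti-aliasing filter is applied
before downsampling.

**End-tidal P\_ET\_CO2.** Exhalation maxima of the raw CO2 trace are
found with prominence (default 2 mmHg, rejecting cardiogenic ripple) and
minimum-separation (default 2 s) criteria, then linearly interpolated at
the trace's own rate. Extrapolation beyond the first/last peak is
constant, to avoid inventing trends. Deterministic detection parameters
plus an optional JSON peak-edit sidecar (`add`/`remove` index lists)
replace interactive manual verification.

**RVT.** Per breath, `(value at maximum − value at preceding minimum) /
(time to next maximum)`, anchored at the maximum's time and linearly
interpolated; the final breath reuses the preceding period. Belt maxima
must rise above the trace median to count as inhalations. This extra
rule matters during holds: a flat hold plateau flanked by the pre- and
post-hold exhale troughs forms a bump whose peak prominence exactly
equals the shallower trough's, so with a single symmetric prominence
threshold either the plateau would count as a breath or one trough would
be lost. With the midline rule the two troughs appear as consecutive
minima, and the alternation repair keeps only the pre-hold one.

**Trial quality.** The CO2 rise of a hold is `post-hold exhale peak −
pre-hold exhale peak`, read from the raw-trace maxima flanking the hold
window. The threshold is `mean − 1·SD` over the *positive* rises, with
sample SD (n−1); a single positive rise gets SD 0, and an n-denominator
variant is available (`ddof=0`). "Greater than" carries a 1e-9 tolerance
so a degenerate all-equal recording grades every trial high. Skipped
holds are labelled `skipped` and count as eligible for training segments
(the absence of a hold is itself informative to the predictor), but they
break the "sequential high-quality" runs used for rescaling.

**Hold-window delay for peak matching.** CO2 reaches a gas analyzer
several seconds after the breath that produced it. The hold windows are
therefore shifted by a delay estimated by correlating the interpolated
end-tidal trace against a task template (unit CO2 accumulation ramping
over each hold, cleared exponentially with a 15 s time constant) over
candidate delays in [0, 30] s. The P\_ET\_CO2-to-RVT shift is *not* used
for this purpose: that shift also absorbs ~20 s of waveform geometry
(the end-tidal envelope ramps across the hold while RVT dips at the
hold's start), so it systematically overestimates the instrument delay.
A 3 s guard widens the post-hold search so a slightly-large delay
estimate cannot step past the exhalation peak.

**Alignment and normalization.** P\_ET\_CO2 is shifted earlier in time
(exhaustive search over integer 10 Hz lags, bound 30 s) to maximize its
negative correlation with RVT, and both traces are trimmed to common
support. z-normalization uses the population (n) denominator.

## Rescaling to mmHg

`rescale_minmax` maps a regressor's extrema onto `[min, max]` of the
measured P\_ET\_CO2 over the earliest run of k ∈ {1,2,3} consecutive
high-quality blocks. By default the *global* extrema of the target are
mapped (the regressor is used whole for CVR); matching extrema within
the block span only is available behind `within_block_extrema`. The
interval [lo, hi] is non-shrinking in k. RVT keeps its natural
anti-correlated polarity; no sign flip is applied, because the lagged
GLM's beta sign and the bulk alignment handle polarity downstream.

## Response functions

The canonical HRF is the double gamma
`h(t) = g(t; 6, 1) − g(t; 16, 1)/6` (peak ≈ 5 s, undershoot after 10 s);
the respiration response function is
`r(t) = 0.6 t^2.1 e^(−t/1.6) − 0.0023 t^3.54 e^(−t/4.25)`.
Kernels are sampled at the regressor's rate (durations 32 s and 60 s)
and normalized to unit peak, so convolution approximately preserves
mmHg peak-to-peak excursions; exact amplitude semantics live in the GLM
beta, which is invariant to any fixed kernel scale. Unit-area
normalization is available (`normalize="area"`). Convolution is causal,
truncated to the input length, without demeaning.

## The RVT → P\_ET\_CO2 predictor

Input is an N×2 array: column 1 the z-normalized RVT squashed by tanh,
column 2 a one-hot subject code zero-padded to N (all zeros for unknown
subjects). The network has `n_layers/2` stride-2 convolutions followed
by `n_layers/2` stride-2 transposed convolutions; inputs are zero-padded
to a multiple of `2^(n_layers/2)` and the output cropped back, so any
length is preserved. Architecture constants not fixed by the training
recipe: kernel 8 (padding 3, keeping lengths exactly halved/doubled),
channel widths 16 doubling per encoder layer capped at 64 and mirrored
in the decoder, leaky ReLU activations (slope 0.1), a linear 1-channel
output layer, He initialization, no normalization layers.

Training: batch size 1 (one whole segment per step), Adam with initial
learning rate 0.01 reduced ×0.1 after 4 epochs without improvement of
the best epoch-mean training loss, and the loss
`MSE + λ·MSE(peaks)` with peaks auto-detected on the z-scored target
(prominence 0.5, separation 15 s). The reference configuration is 12
layers, 20 epochs, λ = 0.5. Two stabilizers make the prescribed recipe
reliable: gradients are clipped to global norm 1.0 (with batch size 1
and a fixed 0.01 learning rate, whole-segment gradients occasionally
explode), and the activations leak — plain ReLU at this learning rate
collapsed into a dead constant-output basin on roughly half of
initialization seeds, while the leaky variant trained to held-out
median r ≈ 0.95 on every corpus/seed combination tested.
Everything — forward, backward, optimizer, schedule — is implemented in
numpy; the backward pass is verified against numerical differentiation
to ~1e-9 relative error in the test suite.

Hyperparameter search is 5-fold cross-validation over segments with
deterministic fold assignment, ranked by mean RMSE at the target's
peaks — peak height encodes the hypercapnic depth that CVR scaling
depends on, which is also why λ > 0 exists.

## Lagged-GLM CVR mapping

BOLD is converted to percent signal change around each voxel's temporal
mean (non-positive-mean voxels are masked out). A single bulk shift
(±30 s, exhaustive at the regressor rate) aligns the regressor to the
mean gray-matter PSC series by maximizing |r| — absolute value because
an RVT-derived regressor is legitimately anti-correlated; the signed r
is reported. Voxelwise, the regressor is shifted over
`{−max_lag, …, +max_lag}` in 0.3 s steps (61 lags at ±9 s, 101 at
±15 s), resampled to the TR grid with edge-value padding, and fit by OLS
together with Legendre polynomials through order 4. The implementation
residualizes Y and all lag columns against the nuisance basis once (QR)
and selects the lag maximizing R² per voxel — algebraically identical to
full OLS per lag (Frisch–Waugh), verified against a brute-force
`lstsq`-per-lag oracle to 1e-8. Exact R² ties break toward the smallest
|lag| (stability on flat profiles). Delay = bulk shift + selected lag;
positive delay means the voxel responds later. `delay_normalized`
subtracts the gray-matter median. Voxels selecting one of the two
outermost lags per side are flagged and, outside pathology mode,
blanked in the delay maps — in pathology mode (±15 s) they are kept,
since steno-occlusive disease produces genuinely long delays.
Extreme-delay masks threshold the raw delay map at ≥10 s and keep
face-connected (6-neighborhood, switchable to 18/26) clusters of ≥15
voxels.

## Evaluation metrics

"Normalized correlation" means Fisher's z = atanh(r) throughout; r is
capped at 1−1e-12 so identical traces stay finite. RMSE-at-peaks uses
peaks of the reference (measured) trace. Gray-matter map metrics exclude
voxels whose *truth*-map amplitude exceeds the truth map's 98th
percentile within the mask, so every test map faces the same exclusion
set. Dice of two empty masks is defined as 1 (agreement on absence),
with a warning. Paired t-test and Spearman helpers are thin wrappers
over scipy.

## Synthetic data

The generator emulates one breath-hold session: paced breathing at 6 s
per breath, 4 paced breaths per trial, holds drawn U(10, 24) s (or
fixed), a 3 s exhalation and 15 s recovery, a 10% chance a hold is
skipped (breathing continues), and mouth-breathing trials whose
end-tidal rise is attenuated to 15%. The belt signal is a raised-cosine
breath train, flat during holds, with exhale troughs just before and
after each hold and two slightly deeper recovery breaths. The CO2
channel is the product of an end-tidal envelope and a per-breath
exhalation bump train: the envelope ramps up linearly over each apnea to
`baseline + delta` at the post-hold exhale and decays back with a 15 s
time constant (recovery breathing clears CO2 quickly). Per-trial deltas
are `hold duration × subject accumulation rate × trial jitter`, with the
rate drawn around 7 mmHg / 17 s: CO2 accumulates roughly linearly over
an apnea, and this coupling is what makes P\_ET\_CO2 predictable from
the belt trace at all — with deltas independent of hold duration the
prediction problem would be ill-posed by construction. Realized deltas
are ~6–7 ± 3 mmHg. The CO2 trace is delayed by a 4 s sampling-line lag;
together with the ~20 s geometric lag of end-tidal interpolation across
a hold this puts the recovered P\_ET\_CO2-to-RVT shifts at 21–26 s,
inside the 30 s search bound. Ground-truth labels apply the mean−1SD
rule to the generator's own envelope values, so pipeline recovery is
judged against the same definition it implements; trials whose rise
falls within peak-reading noise (~0.2 mmHg) of the threshold are
intrinsically ambiguous, which is why label-recovery checks require 20
of 30 recordings exact rather than all.

The BOLD phantom synthesizes
`y_v(t) = B·(1 + a_v/100 · x̃(t − d_v)) + drift(t) + ε`, with B = 1000,
x̃ the HRF-convolved, demeaned end-tidal trace re-centered within each
voxel's sampled window (so B is exactly the temporal-mean baseline that
percent-signal-change analysis assumes — without re-centering the
recovered amplitude is biased by `a·mean(x̃_window)/100`), polynomial
drift absorbed exactly by the Legendre nuisance, and Gaussian noise
σ = 0.05% of B by default. Default fields: amplitude 0.1–0.5 %BOLD/mmHg
on a smooth gradient, delays −6…+6 s quantized to the lag grid.

**What passing these benchmarks shows — and does not.** The phantom
validates the estimator (the lagged GLM inverts its own generative
family exactly and degrades gracefully with noise); it does not emulate
motion, multi-echo combination, spatially-correlated physiological
noise, or HRF variability. The physiology generator produces an
idealized, noise-light capnograph trace; real traces carry drift,
cardiogenic oscillations and irregular breathing that make peak
detection and the quality threshold less clean than here. The predictor
benchmark shows the architecture + recipe learn the hold-driven
RVT→CO2 structure from ~40 segments; real between-subject variability is
far richer than the generator's rate jitter, and the held-out r here
(~0.9) should not be read as a claim about real-data performance.
Held-out evaluation uses fully compliant recordings only, mirroring the
convention that a measured P\_ET\_CO2 trace corrupted by mouth breathing
is not a valid ground truth.

## Problem sizes

Test and acceptance runs use 8-trial (~9 min) recordings, 40 training
segments from ~15 recordings, 10 held-out recordings, and 12×12×4×200
phantoms at TR 1.5 s — small enough that the whole suite runs in well
under a minute plus ~15 s per network training, while every stage still
operates in its intended regime.

## Known limitations

- The original model's exact layer widths and kernel sizes are not
  recoverable from the published description; results are matched in
  recipe and architecture family, not weight-for-weight.
- Whether the original rescaling matched global or within-block extrema
  is unstated; both are implemented, global is the default.
- The RVT anchor point (maximum vs mid-breath) is a convention; it is
  configurable in effect through the extrema passed to `compute_rvt`.
- No early stopping; the epoch count is the stopping rule by design.
- Motion regressors can be passed as extra nuisance columns to
  `map_cvr`, but no motion simulation exists in the phantom.
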