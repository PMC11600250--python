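# Methods

This note documents the models, algorithms and design choices behind
`measort`: what the simulator emulates, how detection and preprocessing
work, how the four sorters are trained, how they are scored, and which
choices were genuinely open.

## 1. Synthetic extracellular recordings

### Model

A recording is white Gaussian background noise (standard deviation
`noise_sd`, default 10 µV) plus linear superposition of spike-waveform
templates.  Each of `n_neurons` source neurons has one fixed template
and fires as an independent Poisson process thinned by an absolute
refractory period (default 2 ms).  The driving intensity is dead-time
corrected, λ′ = λ/(1 − λτ), so the *observed* rate after thinning
matches the configured rate; without this correction a 20 Hz unit with
a 2 ms dead time would fire at ≈19.2 Hz and spike-count checks against
the nominal rate would be biased.

Templates are differences of two Gaussian lobes: a dominant negative
trough (σ between 100 and 325 µs at 20 kHz) positioned at 35 % of the
template length, and a smaller, wider positive rebound after it.  This
reproduces the trough-dominated biphasic morphology of extracellular
somatic spikes near planar microelectrodes without a compartmental
forward model.  Trough amplitudes are drawn in `amplitude_range`
(default −75 to −120 µV, i.e. SNR 7.5–12 against the default noise at
the detection threshold's working range).

Because the sorting front end min-max-normalizes every spike, units are
distinguishable only by waveform *shape*.  Template draws are therefore
rejection-sampled until every pair of units is at least
`min_shape_distance` (default 0.7) apart in the very space the sorters
see — unit-norm, min-max-scaled, first-differenced waveforms.  Without
this constraint a template bank frequently contains a near-duplicate
pair, which no sorter (and no supervised classifier) can separate; such
banks measure label noise, not sorting quality.

### Within-unit variability

Real units — especially bursting hippocampal neurons — do not emit
identical spikes.  Two per-spike modulations are available and are
**off by default** (so the exactness contracts, e.g. "a noiseless
recording reproduces the template bit-for-bit", hold for the base
simulator) and **on in the benchmark generator**:

* amplitude attenuation: each spike is scaled by a uniform factor in
  `amp_jitter_range` (benchmark default 0.85–1.0), emulating the
  amplitude decline of spikes within bursts;
* time-base stretch: each spike's waveform is resampled with a stretch
  factor drawn from a clipped normal (sd `width_jitter_sd`, benchmark
  default 0.05), emulating spike-width modulation.

These turn each unit's feature cloud from an isotropic blob into an
elongated manifold.  That is the structure on which embedding-based
sorters genuinely differ from their baselines; with identical spikes
per unit, k-means on almost any reasonable representation is already
near-optimal and all sorters tie.

### Benchmark suites

`make_benchmark_suite` generates independent ground-truthed sets of a
given size class — target total spike counts 100 000 ("small") and
1 100 000 ("large"), multiplied by a `scale_factor`.  Per-neuron
benchmark rates are heterogeneous, (2, 4, 8, 16, 30) Hz: cultured
neurons fire at roughly log-spread rates, the resulting class imbalance
is a known hard case for k-means-style assignment, and the total
(60 Hz) keeps the fraction of colliding spikes (two spikes within one
64-sample window) near 15 %.  Duration is solved from the target count,
so at desk scale (0.1 for small, 0.01 for large) both classes contain
≈10 000–11 000 spikes; the classes then differ only in seeds, not in
statistics, which is the honest desk-scale rendering of a size split
whose full-scale difference is recording length.

Each set draws its own template bank and noise; all randomness derives
from one `SeedSequence`, so suites are bit-reproducible.

### Coupled calcium traces

`simulate_calcium_trace` renders a ground-truth spike train as a
fluorescence trace: a bleaching polynomial (coefficients in increasing
degree, evaluated on time in seconds) plus one unit-amplitude
exponential-decay kernel per spike (default τ = 0.5 s, instantaneous
rise), sampled at `frame_interval` (default 12.5 ms, so a 20 000-frame
movie spans 250 s), plus white Gaussian noise.  It does not model
indicator saturation, Poisson photon statistics, neuropil
contamination, or finite rise time.

## 2. Detection and preprocessing

1. **Filtering.** Zero-phase (forward–backward) 4th-order Butterworth
   bandpass, 300–3000 Hz.  Zero-phase filtering preserves spike shape;
   only the band is prescribed, the filter family is our choice.
2. **Noise scale.** σ_m = median(|x|)/0.6745 over the full filtered
   trace.  0.6745 is the median of |Z| for standard normal Z, so σ_m
   estimates the noise standard deviation while ignoring the sparse
   spike fraction; computing it on the full trace (rather than
   spike-free segments) is safe for exactly that robustness reason.
3. **Thresholding.** Events where the signal first crosses below
   −5σ_m.  Negative-only polarity matches trough-based alignment;
   crossings within a 1.5 ms dead time of an accepted event are
   suppressed so one spike's multiple dips count once.
4. **Windowing.** A provisional 64-sample window (20 before the
   crossing, 44 after) is cut, its minimum located, and the final
   window re-cut as 20 samples before the trough through 43 after.
   The re-cut can expose a deeper sample that was outside the
   provisional window, so alignment iterates to a fixed point (bounded
   at 8 steps; events that never stabilize, or whose window would leave
   the recording, are dropped).  Every emitted waveform has length 64
   with its minimum exactly at position 20.
5. **Features.** Each waveform is min-max scaled to [0, 1] and first
   differenced, divided by the sampling step (50 µs at 20 kHz): a
   63-vector of normalized gradients.  Min-max removes offset and gain;
   the gradient emphasizes shape.  Constant waveforms are rejected with
   a reason (min-max undefined).

## 3. Sorters

All four sorters consume the same per-set standardized features
(per-column z-score, float32) and the caller supplies K (K = 5 in all
benchmarks; no model selection).

* **DeepAE** — a fully connected autoencoder (63–256–256–10, ReLU
  hidden, linear latent/output) trained 60 epochs with Adam (10⁻³,
  batch 256) on mean-squared reconstruction; k-means (10 restarts) on
  the 10-d latent codes gives the labels.  The middle layer is wide
  (256) because a narrower bottleneck-before-latent (e.g. 64)
  measurably destabilizes optimization: on identical data the narrow
  network intermittently merges two units in latent space that the wide
  one separates.
* **DEC** — DeepAE's pretrained encoder (the decoder is discarded),
  plus centroids initialized by that same k-means, fine-tuned by
  minimizing KL(P‖Q).  Q is the Student-t soft assignment
  q_ij ∝ (1 + ‖z_i − µ_j‖²/α)^−(α+1)/2 with α = 1; the target
  p_ij ∝ q_ij²/f_j (f_j = Σ_i q_ij) sharpens confident assignments
  while normalizing away cluster-frequency bias.  P is refreshed every
  40 iterations; training stops when fewer than `tol` of the labels
  changed between refreshes.
* **IDEC** — as DEC but the decoder is kept and the loss is
  L = L_reconstruction + γ·L_clustering with γ = 0.1; the
  reconstruction term anchors the embedding (local-structure
  preservation).  With γ = 0 the update path reduces exactly to
  continued autoencoder training (asserted bit-for-bit in the tests).
* **AE-Ensemble** (reference baseline) — five shallow autoencoders
  (one 112-unit hidden layer; latent widths 8, 10, 12, 10, 8; distinct
  seeds), latent codes concatenated, column-standardized so no member
  dominates, clustered by k-means.  The exact recipe of the published
  ensemble baseline is not specified by our sources; this
  reimplementation is tuned to be a competitive, reproducible
  reference, which is all the normalization role requires.

### Fine-tuning optimizers and the non-convergence guard

Fine-tuning is deliberately not Adam-everywhere:

* DEC uses plain SGD with momentum 0.9 at 5·10⁻⁴.  The self-training
  target is non-stationary, and adaptive per-parameter step sizes
  (Adam) measurably distort the pretrained embedding geometry —
  observed as accuracy collapse on hard sets.
* IDEC uses Adam at 10⁻³; its reconstruction term anchors the geometry,
  which is exactly the role the method assigns to it.

Pure-KL self-training can still drift on data whose clusters overlap
irreducibly: the assignments churn forever without meeting the
label-change stopping criterion while the embedding collapses.
Empirically the two outcomes separate cleanly on the stopping signal
itself: healthy runs converge (label change < tol), collapsing runs
exhaust the iteration budget.  DEC therefore treats budget exhaustion
as non-convergence and reverts to its k-means initialization — an
internal criterion, computed without any reference to ground truth.
IDEC, whose anchor bounds the drift, reports its budget-end state.

`tol` defaults to 0.02 % (not the conventional 0.1 %): with ~10⁴ spikes
per set, 0.1 % is ~10 labels per refresh interval, a bar the γ-damped
IDEC dynamics pass long before its assignments plateau.

All training is deterministic given `TrainConfig.seed`: weight
initialization, batch order, k-means restarts and ensemble member seeds
all derive from it through a `SeedSequence`.  In the benchmark harness,
DeepAE, DEC and IDEC share one pretrained network per (set, seed) —
their pretraining stages are bit-identical by construction, so it is
computed once and deep-copied.

### Over-clustering artifact filter

Sorting into K_over ≥ 20 classes isolates artifact shapes into their
own clusters; the filter returns per-class mean feature vectors to
support the (manual) decision of which classes are noise, and a keep
mask excluding the designated classes.  The sorter used for
over-clustering is pluggable (DeepAE by default).

## 4. Evaluation

* **Detection scoring.** Greedy nearest-neighbour one-to-one matching
  of detected trough indices to true spike indices within ±`window`
  samples (±30 by default, 1.5 ms): candidate pairs ordered by |Δt|,
  accepted while both sides are unused.
* **Accuracy.** Fraction of spikes agreeing with ground truth after the
  optimal one-to-one cluster↔neuron assignment (Hungarian algorithm on
  the confusion matrix).  Default scope is `matched_only` — sorters are
  scored on detected spikes paired to truth, isolating clustering
  quality from the shared detector; `all_truth` additionally counts
  every missed true spike as an error.
* **Benchmark.** For each set: detect → preprocess → each sorter with a
  per-set seed → accuracy; per-set relative improvement
  100·(acc/acc_ref − 1) % against the AE-Ensemble; summaries are means
  ± sd over sets.  A sorter failure on one set is recorded and excluded
  from that sorter's summary with a warning.
* **Spike-train statistics.** Rate = count/duration.  Synchrony =
  plug-in mutual information (bits) between binarized trains on a
  common grid (default 20 ms bins; a bin is 1 if it holds ≥1 event),
  from the joint 2×2 histogram without bias correction.  The plug-in
  estimator is upward-biased by ~1/(2N ln 2) per degree of freedom;
  with ≥10⁴ bins this is < 10⁻³ bits, which the tests account for.

## 5. Calcium-trace analysis

* **Bleach correction** subtracts a least-squares polynomial (order 10)
  fitted to the whole trace.  The fit uses NumPy's scaled-domain
  `Polynomial.fit`: a raw power-basis Vandermonde solve at degree 10 on
  a 20 000-frame axis is numerically singular, the rescaled domain is
  exact on polynomial input to ~10⁻⁷ relative.  Residuals + baseline
  reproduce the input exactly by construction.
* **Event detection** takes local maxima of the residuals that clear
  `prominence_mult` (default 4) × the MAD noise scale in **both height
  and prominence**.  Prominence alone is insufficient on long traces:
  pure-noise peaks reach prominences of ~8 noise scales over 10⁴+
  frames (peak minus valley), while their height stays near 4.
  Event *time* is the local maximum (the timing convention of the
  analysis this mirrors); on a slow-decay transient this estimator's
  timing jitter at moderate SNR spans a few frames, so event matching
  in validation uses a ±0.25 s window at SNR 8 and the one-frame
  accuracy claim is verified in the high-SNR limit only.
* **ΔF/F** uses F₀ = 10th percentile of the raw trace by default
  (configurable; `median` available).  A baseline must be positive.
* **Alignment with electrophysiology** shifts calcium event times by
  the recorded start-time offset between the two acquisition systems
  and counts calcium events with ≥1 ephys spike within ±1 s — a
  tolerance covering the sub-second residual trigger delay (~0.6 s)
  typical of simultaneous acquisition.
* **Cohort summaries** report per-day mean event rate and mean pairwise
  mutual information, each divided by its day-1 value, with the SEM of
  per-ROI relative rates (0 for single-ROI days).

## 6. Benchmark regime, and what passing does not show

The benchmark generator was calibrated — before freezing, as a design
act — to the regime the sorter comparison is about: per-set
unsupervised accuracies roughly 0.55–0.95 with a supervised (LDA)
ceiling near 0.95, i.e. data hard enough that representations matter
and easy enough that the task is solvable.  Outside this window the
comparison degenerates: with near-duplicate templates or SNR at the
detection limit every method fails together; with identical spikes per
unit and high SNR every method saturates together.

Desk-scale caveats:

* At scales 0.1/0.01 the small and large classes are statistically
  identical (~10⁴ spikes each); the full-scale mechanism "more training
  data helps deep models more" is absent by construction, so the
  size-class contrast seen at full scale compresses toward a common
  value at desk scale.
* Per-set improvement variability is large (sd ≈ 10–20 % relative),
  matching the large per-set spread of the reference comparison; means
  over 10 sets carry standard errors of 3–6 points.
* The simulator's noise is white and Gaussian and electrodes are
  single-channel; passing says nothing about correlated noise, drift,
  electrode cross-talk or overlapping-spike decomposition on real
  arrays.

## 7. Problem sizes

Default validation sizes, chosen as the package's working scale: 10
sets per size class at scale 0.1 (small) / 0.01 (large), ≈10 000–11 000
spikes per set; the high-SNR parameter-recovery fixture uses one set of
5 000 spikes; detection calibration uses 10⁶ noise samples; calcium
validation uses 20 000-frame traces.  Sorter fine-tuning budgets are
2 000 mini-batch iterations with target refreshes every 40.
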