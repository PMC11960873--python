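# Methods

## Problem setting

Goat vocalizations recorded on farms are labeled with the context in which
they were emitted (the 8-class dictionary: heat, feed distribution,
parturition, injury/death, social isolation, mother–kid reunion, unknown
visitors, mother–kid separation).  The package classifies 2-second labeled
clips into these contexts and explains each prediction in terms of the
time–frequency content that drove it.

## Frontend

Audio is channel-averaged, polyphase-resampled to 22 050 Hz and
peak-limited to [−1, 1].  Clips shorter than 2 s are zero-padded at the
tail (trailing rather than centered padding keeps the call onset position
stable); longer clips pass through unchanged and are handled by the
sliding window, so no audio is truncated.  Segmentation uses 1-s windows
with 50 % overlap (hop 11 025 samples): window starts are multiples of the
hop as long as a full window fits, and one zero-padded window is appended
only when samples would otherwise be uncovered — a 2-s clip yields exactly
3 segments at samples 0, 11 025 and 22 050.

Each segment maps to a 128-band log-Mel matrix: magnitude STFT with a
1024-sample periodic Hann window and hop 512 (centered frames, so a 1-s
segment gives 1 + ⌊22050/512⌋ = 44 frames), triangular mel filters
spanning 0 to Nyquist (Slaney scale and area normalization by default; HTK
selectable), then natural-log compression of mel power with an additive
floor of ε² = 10⁻²⁰ (ε = 10⁻¹⁰ in amplitude).  Digital silence therefore
maps to a uniform, finite floor value, and scaling a signal up can never
decrease any cell.  A dB-scaled variant is a config switch.

## Augmentation

Training segments are expanded by a 15-variant grid: time stretches
{0.8, 1.0, 1.2} crossed with pitch shifts {−2, −1, 0, +1, +2} semitones,
stretch applied first, the result refit to exactly 1 s (tail trim or
zero-pad) so feature shapes stay constant, then the shift.  Both
transforms run through a phase vocoder (FFT 2048, hop 512) that linearly
interpolates frame magnitudes and accumulates wrapped per-bin phase
deviations; pitch shifting composes a stretch at rate 2^(−s/12) with
resampling back to the original length.  The intermediate stretch length
is snapped to an FFT-fast size, perturbing the pitch ratio by under 0.1 %
(≈2 cents) — negligible against the 100-cent grid spacing.  The identity
variant (1.0, 0) reproduces the input with correlation ≥ 0.99.
Augmentation is restricted to training folds; validation and test sets
always consist of original audio.

## Architecture

A VGG-style stack on the 128×44×1 input: four blocks of two 3×3
same-padding convolutions with ReLU (nominal filters 64, 128, 256, 512)
each followed by 2×2/stride-2 max pooling (floor semantics on odd
dimensions: 128→8, 44→2), flatten, two 4096-unit ReLU dense layers,
dropout 0.5, and an 8-unit softmax output.  Kernel size, pooling geometry,
padding, dropout rate and placement follow standard VGG practice.  A width
multiplier w ∈ (0, 1] scales all filter counts and dense widths jointly
(effective = max(1, round(w·nominal))); desk-scale experiments use
w = 0.125 (≈ 865 k parameters).  Initialization is He-normal from a seeded
generator, so identical seeds give identical networks.

The layers are implemented directly on numpy (im2col convolutions with a
single BLAS matmul per layer; the adjoint convolution reuses the same
kernel with channel-swapped, spatially flipped weights).  This makes every
activation available to the relevance pass and keeps training, inference
and explanation in one consistent numerical stack.

## Training and evaluation

Adam with learning rate 10⁻⁴ and batch size 12, cross-entropy loss, up to
14 epochs with early stopping (default monitor: validation loss, patience
3, best weights restored).  The validation set is a stratified 10 % of the
training fold's *sources*, evaluated on original (un-augmented) segments
so the monitored metric matches test conditions.  Inputs are standardized
by the training set's global mean/std, stored with the network.

Cross-validation is stratified 5-fold at the source-recording level: a
clip's segments and all its augmented variants share a fold, which is the
leakage-control reason for grouping by source.  Stratification keeps each
class's per-fold test counts within one sample of each other and refuses
classes with fewer sources than folds.  Evaluation is clip-level: the
segment softmax rows are averaged arithmetically and the argmax taken;
confusion matrices are row-normalized so the diagonal is per-class recall,
and fold matrices are averaged for the headline mean per-class recall.

## Relevance propagation

Relevance is seeded at the output layer with the target class's
pre-softmax score and propagated with the standard composite for VGG-like
networks: α₁β₀ (z⁺) for convolutions, ε-rule (ε = 10⁻⁶) for dense layers,
winner-takes-all routing through max pooling (ties share equally), and
shape-preserving pass-through for flatten and inference-mode dropout.
Conditions (per-layer allowed channel subsets) zero relevance outside the
subset before propagation continues through that layer.  Because every
rule's redistribution coefficients depend only on forward activations, the
backward map is linear in relevance; singleton-channel conditional
heatmaps of any layer therefore sum exactly to the unconditional heatmap,
and on zero-bias dense networks the ε-rule conserves the seeded score to
first order in ε.

Channel rankings sum a layer's output relevance over all positions per
channel, sorted descending with ties broken by ascending index.  Sample
reports render the top-k (default 6) channels' conditional heatmaps per
analyzed layer; "analyzed layers" means convolutional and dense layers and
is always an explicit argument.  Class-wise average heatmaps select the n
most central spectrograms of a class (distance to the flattened-feature
centroid, the k-means k=1 solution), compute the top-g conditional
heatmaps per analyzed layer for each, and average arithmetically.  The
bookkeeping object records the nominal count formula
M̄ = |D|·n·g (with the corpus-scale parameters |D| = 8, n = 100, g = 20
this evaluates to 16 000) exactly as specified *and* separately reports
the actually aggregated contributor count n·g·(number of layers), since
the formula's |D| factor does not enter a single class's average; the
discrepancy is documented rather than silently resolved.

## Interaction layer

*Influence*: the clip's class is predicted by mean-softmax aggregation;
the relevance map is computed on the segment with the highest predicted
probability, the high-relevance region is the set of positive cells at or
above the 90th percentile (configurable) of positive relevance, extents
are reported in seconds (frame × hop/rate) and Hz (mel-band center
frequencies), and the region is sonified.  *Sonification* lifts the
mel-plane mask to the linear STFT plane through the pseudo-inverse of the
mel filterbank clipped to [0, 1], multiplies the segment's magnitude STFT,
and resynthesizes with the original phase (deterministic, unlike iterative
phase reconstruction); an all-ones mask reconstructs the segment with
correlation ≥ 0.95 and masks in [0, 1] can never raise the RMS.
*Retrieval*: clip embeddings are the mean over segments of the second
dense layer's post-ReLU activation (configurable); cosine distances on
these non-negative vectors lie in [0, 1], and similar/dissimilar are
ascending/descending orderings of the same distance vector.  *Difference*:
each clip's map (own predicted class, most confident segment) is min-max
normalized to [0, 1] before subtraction so recordings of different energy
are comparable; the masked regions of both clips are sonified.  Using each
clip's own prediction (rather than one clip's class for both maps) is a
deliberate choice; the alternative is a one-line change at the call site.

## Synthetic corpus

Each class renders harmonic calls: fundamental drawn from a class band,
linear FM sweep, sinusoidal AM, 1–3 harmonics with 1/h falloff
additionally weighted by a Gaussian spectral envelope centered on the
class's discriminative band, 20-ms raised-cosine fades, a random onset
inside the 2-s window, and pink (1/f) noise at 20 dB SNR — pink rather
than white as the closer match to farm soundscapes.  The eight
discriminative bands are pairwise disjoint with margin, and each class's
fundamental stays inside its band over the whole FM sweep, so band energy
is a faithful ground truth for scoring explanation heatmaps; rendered
in-band energy exceeds out-of-band energy by ≥ 6 dB on average.  Random
onsets force the classifier to rely on pooling translation tolerance.
Durations, counts and seeds are all explicit; regeneration from the same
seed is bit-identical, and class imbalance is an explicit option so the
stratification code paths are exercised.

What the generator does *not* emulate: real goat-call spectro-temporal
detail, reverberation, overlapping callers, farm machinery, or
between-farm channel differences.  Passing tests on this corpus
demonstrates that the pipeline, training loop and explanation machinery
behave correctly and that explanations recover planted structure — not
that field recordings would reach the same rates.

## Desk-scale experiment sizes

The reference experiment uses 40 clips per class (320 sources, 960
segments, 14 400 augmented training spectrograms), width 0.125, and one
training epoch per fold — the cleanly separable synthetic classes converge
within a single epoch (typical fold recall 1.0) and the full 5-fold run
completes in roughly 10–15 minutes on one CPU core.  Class-heatmap
aggregation defaults to n = 8 central samples and g = 2 channels over two
late layers; corpus-scale values (n = 100, g = 20) are plain parameters.

## Numerical choices and degenerate inputs

- log floor 10⁻²⁰ in power; ε-rule stabilizer 10⁻⁶ with sign(z).
- Phase-vocoder arithmetic in float32 with float64 phase accumulation
  (wrapped radians accumulate over frames); features stored float32.
- Max-pool ties share gradient and relevance equally (deterministic).
- Channel-ranking ties break by ascending channel index.
- Empty masks (no positive relevance) sonify to silence; constant heatmaps
  min-max normalize to zero; zero embeddings get cosine distance 1.
- Degenerate inputs fail loudly: empty WAVs, wrong segment lengths,
  out-of-range conditions, k > layer width, fewer class sources than
  folds (the offending class is named).

## Known limitations

- No voice-activity detection or denoising: clips are assumed
  pre-segmented and labeled.
- Transfer-learning baselines (MobileNetV2 / EfficientNetB0) are out of
  scope; the checkpoint format leaves room for external backbones but no
  hooks are implemented.
- Single-threaded CPU training bounds practical corpus sizes; the width
  multiplier is the intended scaling knob.
- Mean-softmax clip aggregation is one reasonable choice; max- or
  confidence-weighted aggregation are not implemented.
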