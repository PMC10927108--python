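# Methods

## Problem

A cell passing through mitosis visits a fixed sequence of morphological
states: interphase chromatin decondenses into a large soft nucleus;
prophase condensation produces bright speckled chromatin; prometaphase a
compact mass; metaphase a plate-like bar; anaphase two separating masses;
telophase two decondensing daughter nuclei that drift apart and regain an
interphase-like appearance.  Given a 2D+t crop that tracks a single cell
through division (one cell centered per frame), the task is per-frame
classification of the stage — a temporal segmentation of the movie.  Two
annotation schemes are supported: a 3-class scheme (interphase, mitosis,
post-mitosis) over 90-frame sequences and a 6-class scheme (interphase
plus the five mitotic phases) over 40-frame sequences.

The central difficulty is that single frames are ambiguous: early
condensation is barely distinguishable from interphase, and a recovered
post-mitotic daughter is, by definition, indistinguishable from an
interphase cell.  Because the stages always occur in the same order, the
ambiguity resolves once temporal context is available.  The package
implements and compares three models that differ precisely in whether
they carry such context.

## Models

**Time-encoded residual classifier.**  A ResNet18-style backbone (stem
convolution + 2x2 max-pool, four stages of two residual blocks, widths
64/128/256/512, total stride 32) with a convolutional GRU at the output
of each of the three deepest stages (widths 128/256/512, 3x3 gates,
same-padding).  Each ConvGRU carries a hidden feature map across frames:

    z_t = sigmoid(W_xz * x_t + W_hz * h_{t-1} + b_z)
    r_t = sigmoid(W_xr * x_t + W_hr * h_{t-1} + b_r)
    g_t = tanh(W_xh * x_t + W_hh * (r_t . h_{t-1}) + b_h)
    h_t = (1 - z_t) . h_{t-1} + z_t . g_t

with convolutions in place of matrix products, so spatial resolution is
preserved.  Hidden state is zero-initialized at every sequence start and
never crosses sequence boundaries.  Two heads read the final feature map:

* a *tracking decoder* — four 3x3 stride-2 transpose convolutions
  (256/128/64/3) followed by a fixed bilinear x2 (bridging the x16
  decoder upsampling to the x32 backbone stride) and a sigmoid — trained
  to reconstruct the input image masked to the center cell.  The stack
  is linear up to the output sigmoid (no intermediate activations): the
  backbone ahead of it supplies the nonlinearity, and reconstruction
  logits then grow through all four layers simultaneously, which
  converges several times faster under a small iteration budget.  The
  target is the masked input rescaled per frame by its own maximum, so
  the cell body sits near 1 regardless of stage-dependent brightness —
  the property that makes the reconstruction segmentable by a fixed
  0.5 intensity threshold.  This auxiliary task forces the features to
  describe the tracked cell and to suppress the surrounding clutter;
* a *classification head* — 3x3 convolution (1024 filters), 2x2
  max-pool, flatten, two fully-connected layers with sigmoid per-class
  outputs.  The flattened post-pool activation is the embedding used for
  PCA visualization.  Scores are per-class probabilities (sigmoid, not
  softmax); prediction is the argmax, ties broken toward the lower stage
  index.

**Base model.**  A shallow variant with three stride-2 conv blocks, one
ConvGRU per scale, and a three-layer transpose-conv decoder; same head
and I/O contracts.

**Frame classifier (baseline).**  A standard 18-layer residual
classifier (global average pool + fully-connected + sigmoid) that
processes every frame independently.  It is the no-time-information
control.

A note on normalization: the source protocol never mentions
normalization layers, but its residual blocks are standard, so batch
normalization (conv-BN-ReLU) is used throughout; batch statistics are
computed over all frames of a batch during training and running averages
are used at inference.  With running statistics, per-frame outputs are
causal: they depend only on frames at or before t (property-tested).

All models are implemented on a small numpy reverse-mode autodiff engine
(`mitotime.nn`) with im2col-based convolutions.  Feed-forward layers are
applied to all frames of a batch in one call; only the GRU
hidden-to-hidden path runs sequentially.  A unit test verifies this is
algebraically identical to stepping frame by frame.

## Losses

With predictions clamped to [1e-7, 1 - 1e-7] before logarithms:

* tracking: pixelwise binary cross-entropy between the sigmoid
  reconstruction and the masked input, normalized by pixel count and
  averaged over the three (replicated-grayscale) channels and the batch;
* classification: binary cross-entropy between sigmoid class scores and
  the one-hot target, normalized by the number of classes;
* the frame classifier uses the positive-term cross-entropy, also
  normalized by N_class.  This 1/N_class factor follows the printed
  protocol rather than the softmax convention; it rescales the loss
  without changing the argmax decision;
* total: `L_track + lambda_wt * L_cls` for the recurrent models
  (lambda_wt 0.1 time-encoded, 0.01 base), `L_cls` alone for the
  baseline.

## Training protocol

Recurrent models consume whole sequences (batch = 4 sequences, state
reset per sequence, full-sequence backpropagation — no truncation, which
is affordable at 30-90 frames).  The frame classifier consumes shuffled
pooled frames (batch 64).  Optimizer: SGD with momentum 0.9 (the source
protocol names only learning rates; momentum-SGD makes those rates
meaningful).  The learning rate drops to 10% every 2500 iterations.
Augmentation draws one transform per sequence per epoch from rotations
by multiples of 90 degrees and horizontal/vertical flips, applied
identically to all frames and masks.  10% of the test sequences are
monitored as a validation set (no early stopping).

**Recovery relabeling (3-class scheme).**  Daughter cells recover
interphase appearance roughly 15-20 frames after mitotic exit while the
annotation keeps the post-mitosis label; such frames are unlearnable for
any appearance-based per-frame loss.  During training, frames more than
`relabel_K` frames (default 18) after the first post-mitosis frame are
relabeled as interphase; at inference, interphase predictions after the
last predicted mitosis frame are mapped back to post-mitosis.  For a
perfect predictor of relabeled targets this round trip exactly restores
the original annotation (property-tested over random monotone label
vectors).

**Scale regimes.**  Two configurations are exercised:

* *full*: 96x96 (or 224x224) inputs, published widths — provided and
  shape-tested; training it end-to-end is practical only with
  accelerator hardware;
* *desk*: 64x64 inputs, 30-frame sequences, stage widths 8/16/32/64,
  GRU widths 16/32/64, decoder 32/16/8/3 — small enough that the full
  train/evaluate cycle runs in minutes on one CPU.  This is the regime
  the test suite and the reproduction script use.

At desk scale the published learning rates (tuned for ImageNet-
pretrained weights and ~10,000 iterations) are too small for the few
hundred iterations available, so `TrainConfig.desk` uses
per-architecture rates chosen once by validation monitoring: 0.02 for
the recurrent models, 0.01 for the frame classifier (which destabilizes
at 0.02).  This mirrors the original protocol's own grid search, which
likewise assigned a 10x larger rate to its from-scratch model.  Desk
recurrent batches hold 2 sequences — within the protocol's sanctioned
2-4 range — doubling the optimization steps per epoch on the small
dataset.  `relabel_K` scales to 8 frames to match the shorter
post-mitotic runs (recovery onset 6-9 frames after mitotic exit in
30-frame sequences).

## Synthetic data

The generator renders parametric-geometric movies of one dividing cell:
soft-edged textured ellipses for nuclei, keyframe interpolation through
condensation, metaphase plate, anaphase separation and telophase
recovery; the tracked daughter re-centers over ~3 frames after the
split, emulating centered crops from a tracking pipeline.  Off-center
distractor nuclei (1-3 by default) drift slowly but are clamped away
from the center so the center-cell mask never overlaps them; Gaussian
noise (sd 6 gray levels) is added last.  Stage durations are drawn
uniformly from per-stage ranges and the interphase run absorbs the
remainder so every sequence has the configured length.  Per-sequence
random streams are spawned from the master seed by index, making
datasets bit-reproducible.

Two properties are deliberate and load-bearing for the evaluation:
stage transitions are gradual (boundary frames are genuinely ambiguous),
and frames after the recovery onset are rendered with the *same*
appearance model as interphase while keeping the post-mitosis label —
the ambiguity that only temporal context can resolve.

What the generator does **not** emulate: optics (no PSF, no depth
effects), photobleaching, cell crowding or touching nuclei, apoptotic
and other aberrant morphologies, annotation noise, and tracking errors
in the upstream crop extraction.  Passing tests on synthetic data
therefore demonstrate the correctness and the qualitative behavior of
the method, not its accuracy on real microscopy.

## Evaluation

Frame-to-frame accuracy is pooled over all test frames (trace over total
of the confusion matrix), not averaged per sequence.  The confusion
matrix has true classes on rows and is displayed row-normalized, so the
diagonal reads as per-class recall; precision, recall and F-score use
the 0/0 -> 0 convention.  Tracking quality is measured by thresholding
the channel-mean reconstruction at 0.5 (the protocol's threshold is
unstated; 0.5 is the sigmoid midpoint) and computing IoU against the
center-cell mask, plus a suppression ratio (mean reconstructed intensity
over non-target bright structures / over the center cell).  Embedding
quality is the silhouette score of the first three principal components
of the classification-head embeddings, grouped by true stage.

## Numerical choices and degenerate inputs

* probability clamp 1e-7 before every logarithm; clamped pixels pass no
  gradient;
* argmax ties break toward the lower stage index;
* empty sequences, shape mismatches, non-monotone 3-class annotations
  and out-of-range labels raise `ValueError`/`IndexError`;
* all-zero confusion rows normalize to zero rows; metrics on an empty
  matrix raise;
* He-normal initialization everywhere except GRU gates (unit-gain) and
  final score layers (unit-gain, so initial scores sit near 0.5);
  transpose convolutions divide the He fan-in by stride^2, since with
  stride-s zero-stuffing only ~k^2/s^2 taps see a nonzero input —
  without this the four-layer decoder attenuates its input ~16x;
* float32 parameters and activations; tests that compare against finite
  differences build float64 tensors directly.

## Problem sizes used by the test suite and reproduction script

The desk-scale study runs 70 sequences (60 train / 10 test) of 30 frames
at 64x64 with the reduced widths above, 10 epochs, three fixed seeds for
the multi-seed properties.  These sizes were chosen as the smallest at
which the learning behavior of interest (recurrent advantage on
history-dependent frames, tracker suppression, embedding separation) is
reliably visible.

## Known limitations

* The base model's published internal layer sizes are not public; the
  implementation here matches its structural description (three scales,
  three GRUs, three-layer decoder) with configurable widths.
* The exact insertion points of the GRUs "between residual blocks" are
  ambiguous in the source description; they are placed at the outputs of
  the stages whose widths match the stated GRU widths.
* Four stride-2 transpose convolutions upsample x16 against a x32
  backbone stride; a fixed bilinear x2 bridges the gap.  Whether the
  original used a different stride is unknown.
* ImageNet-pretrained initialization is exposed only as a
  load-from-file hook; random initialization is the tested path.
* The numpy engine is single-threaded BLAS-bound; full-scale training
  (224x224, widths to 512) is out of its practical reach.
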