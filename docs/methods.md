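# Methods

This note documents the model as implemented, the parameter choices that
matter, what the synthetic data does and does not show, and the numerical
decisions taken where the design was genuinely open.

## Signal model and feature extraction

The pipeline assumes multichannel EEG sampled at a known rate, with
class-discriminative information expressed in band power.  Preprocessing is
a zero-phase 4th-order Butterworth bandpass (default 4–60 Hz, applied
forward–backward so no phase distortion) followed by per-channel z-scoring
over the whole selected interval.  Trailing-interval selection (default last
60 s) is an option of the extraction CLI, not hard-coded.

Windows of 1 s advanced by 0.5 s are dropped (never padded) when they would
overrun the record, so the window count is exactly
floor((duration − win)/step) + 1.  Per window and band two features are
computed:

* **PSD** — mean Hann-taper periodogram power inside the band, linear scale.
* **DE** — Gaussian differential entropy ½ln(2πeσ²) with σ² the variance of
  the band-filtered window.  A zero-variance window is clipped at a floor of
  −20 nats and logged; the floor only matters for pathological (constant)
  inputs.

Both estimator choices are conventions, not unique: any consistent band-power
estimator preserves the class ordering the classifier relies on.  PSD and DE
rows are emitted as two contiguous sub-blocks per band (PSD first); either
kind can be disabled.  Band blocks are contiguous and ordered θ, α, β, γ for
4-band extraction; 5-band (δ-inclusive) matrices are *read* and consumed but
not produced by the extractor.

## Attention

Per channel, scaled dot-product self-attention over h head slices of the
feature vector, with the q·kᵀ outer-product read of the score matrix —
under the alternative scalar reading, softmax of a scalar is identically 1
and attention degenerates to a value projection, so the outer-product
reading is the only one in which attention re-weights anything.  No biases.
Initialisation: W_v and W_io near identity with N(0, 0.01) perturbation,
W_q/W_k ~ N(0, 0.1/√d): the module starts close to a pass-through, which
keeps early spiking activity in a trainable regime.  Default h = 1.

## Spiking neurons

Time constants are in channel-steps, not seconds: the recurrence runs along
the electrode axis, treating the channel sequence of each feature as a
signal.  Defaults τ_m = 8, τ_s = 2 (synapse filter), τ_r = 2 (reset decay),
λ = 1 (reset coupling), V_rest = 1 (reset increment), V_thre = 0.  The
threshold sits at zero because features are standardised before the model:
roughly half of all drive values are positive, which keeps spike rates away
from the dead/saturated extremes.  All six are fixed hyperparameters; only
synaptic weight matrices (and attention/head weights) learn.

The printed update equations define r[i] in terms of the current spike while
the potential uses r[i] — circular as written.  The implementation sequences
each channel step as: decay the reset (r̃ = e^(−1/τ_r)·r), compute the
potential (v = −λr̃ + W f), fire (strict v > V_thre, so U(0) = 0), then add
the reset increment (r ← r̃ + V_rest·y).  This honours both equations one
half-step apart and is the order every test and the hand-coded order-2
oracle use.  Filter and reset states are zeroed at every forward pass: the
channel axis restarts with every sample, so no state leaks across trials.

Backward passes substitute a triangular surrogate max(0, 1 − |x|/w)/w
(default width w = 1) for the Heaviside derivative; the Axon backward is the
exact adjoint (time-reversed) filter, and both custom recurrences are
verified against finite differences in the test suite.

## Fractal block and inverted drop-path

The expansion rule F_{c+1} = Sum{F_c ∘ Soma ∘ F_c, Axon} gives 2^c − 1
Axons, 2^(c−1) − 1 Somas and c aligned columns of depth 2^(k−1).  Columns
are defined by the aligned expansion (each Sum's short branch is column 1;
the long branch holds columns 2..c with the choice synchronised in both
F_c copies); mixed-depth path combinations are reachable during drop-path
training but are not enumerated as columns.  Soma weight matrices are
unshared — nothing in the expansion rule suggests tying the two F_c copies —
and initialised N(0, 1/√n).  Default order c = 3: it contains both smaller
structures and adding a fourth column doubles depth and parameters for no
benefit at these problem sizes.

Inverted drop-path (default rate p = 0.15) draws one independent Bernoulli
keep-mask per branch per Sum layer per forward pass; survivors are summed
and rescaled by 1/(1−p) during training, and the plain unscaled sum is used
at test time.  If every branch is dropped the masks are redrawn until one
survives; this guard introduces a small upward bias in the layer's
expectation, so the unbiasedness check (Monte-Carlo mean vs plain sum)
disables it.  The "plain" mode reproduces the original drop-path (masking
without rescaling) and "none" disables masking, for regularization
comparisons.

## Classifier head and training

The readout Soma (default n1 = n neurons, sharing the global neuron
constants) emits a binary spike matrix; per channel a linear layer lifts to
2·n1 (dimension raised before the nonlinearity so the leaky ReLU discards
less information), a leaky ReLU (slope 0.01) and a second linear layer
produce class logits; learnable channel weights (initialised uniform 1/m)
pool them.  Linear layers carry biases; pooling does not.

Training: cross-entropy on softmax outputs, Adam (lr 1e-3, weight decay
1e-4), 100 epochs, full-trial batches.  Features are z-scored per matrix
cell using training-fold statistics only; the fitted scaling is stored in
checkpoints so saved models accept raw feature matrices.  Because the
environment provides no deep-learning framework, gradients run on the
package's own reverse-mode autodiff engine (`autodiff.py`), double
precision throughout; Adam is implemented alongside it.  Training diverging
to a non-finite loss aborts with diagnostics.

Cross-validation: k-fold within subject (folds shuffled with a fixed seed;
fold accuracies averaged within a subject, then across subjects) or
leave-one-subject-out.  Every fold re-initialises the model from one spawned
seed stream, so a fixed seed reproduces fold assignment, weights and metrics
bit-for-bit.  Ratings on continuous affect scales are binarised at the scale
midpoint (high iff rating ≥ midpoint, e.g. 3 on a 1–5 scale, 5 on 1–9).

## Synthetic data: what it shows and what it cannot

The raw generator builds each trial as one sinusoid per band and channel
(frequency uniform in the band, random phase) plus white Gaussian noise;
classes differ by amplitude multipliers on chosen bands/channel subsets.
This matches the feature pipeline's assumptions *by construction* — class
information lives purely in band power — and is deliberately
non-physiological: no 1/f spectrum, artifacts, volume conduction,
nonstationarity or inter-subject variability.  Passing tests therefore
demonstrate that the implementation is correct and that the scheme can learn
band-power contrasts end to end; they say nothing about accuracy on real
EEG, and no claim of that kind is made anywhere in the package.

Reference datasets (fixed, defined once):

* **separable-2class** — 2 classes, 14 channels, 20 trials/class, class 1
  with 3× β amplitude on channels 0–3, noise sd 0.3, generation seed 7.
  Trials are 6 s at 128 Hz — with DE-only extraction that is 11 windows × 4
  bands = 44 features per channel, a desk-scale size at which the full
  9-fold benchmark runs in about a minute on one CPU; the generator default
  of 60 s trials emulates full-length recordings when shape fidelity
  matters.
* **noisy-2class** — the regularization study variant: 1.5× β contrast,
  noise sd 1.5, 10 trials/class, 6 s trials.  Small training sets plus heavy
  noise create the overfitting regime in which drop-path can matter; the
  comparison trains both modes on identical datasets across 5 seeds and
  checks only the ordering (inverted ≥ none).

The feature-matrix generator emits 5-band (δ..γ) matrices — by default
100 features × 62 channels, the shape convention of feature-level EEG
databases — with a class-1 mean shift confined to one band block and channel
subset.  With effect size 0 it is an exact null (verified by repeated
two-sample tests in the suite).

## Numerical choices and degenerate inputs

* Strict firing inequality: v = V_thre exactly produces no spike.
* Equal synapse time constants make β = 0 (a dead filter) and are rejected
  at configuration time, as are non-positive time constants and p ≥ 1.
* Constant (zero-variance) channels are a degenerate-input error in
  preprocessing; zero-variance band windows clip DE at the floor.
* The generic fractal forward and the hand-coded order-2 recurrences share
  the same numpy kernels and summation order, so their equivalence holds
  bit-for-bit, not merely to tolerance.
* Loss-curve monotonicity is judged on a median-filtered (window 5) then
  moving-averaged (window 15) curve: drop-path training makes per-epoch
  losses stochastic, and isolated one-epoch spikes after convergence are
  expected rather than pathological.
* Saliency uses the pre-softmax logit of the target class and the absolute
  gradient, min-max normalised; an all-zero gradient yields an all-zero map
  with a warning.  Reliability bins are per class ([0,.25), [.25,.5),
  [.5,.75), [.75,1]); empty bins are flagged with NaN statistics.

## Known limitations

* No GPU path and no minibatch parallelism beyond numpy vectorisation; the
  intended scale is hundreds of trials with tens-to-hundreds of features.
* The attention memory footprint grows as (n/h)² per channel; for n in the
  hundreds (e.g. 500×62 feature matrices) single-sample forwards are fine
  but large batches are memory-hungry.
* EDF files are read (via mne) but not written; the text format plus JSON
  sidecar is the native raw interchange.
* Artifact rejection, re-referencing, ICA and domain adaptation are out of
  scope; LOSO splitting is provided but no transfer technique beyond it.
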