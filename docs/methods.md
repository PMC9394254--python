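# Methods

`cceeg` implements a cross-connected convolutional network (C-c CNN) for
nine-class emotion recognition from multichannel EEG, together with the
signal-conditioning chain, label mapping, evaluation battery and experiment
harnesses needed to exercise it end to end. This note records the model,
its assumptions, the numerical choices, and what the synthetic data can and
cannot show.

## The classification problem

Each trial is a `channels x time` epoch (default 40 channels x 8064 samples
at 128 Hz, matching the preprocessed-trial geometry of the DEAP benchmark:
32 named 10-20 EEG electrodes plus 8 peripheral channels) with a
Self-Assessment Manikin rating of valence and arousal, each on a 1-9 scale.
Both axes are binned into three levels — boundaries at 4 and 7, half-open
intervals `[1,4)`, `[4,7)`, `[7,9]`, so real-valued ratings are handled —
and the 3x3 grid gives nine emotion classes. Ordinals
(`3*arousal_index + valence_index`) drive all computation; the display
names (depressed ... happy) are a configurable table, because the canonical
assignment of names to off-axis cells is convention, not data.

## The cross-connected CNN

Three branches process the raw epoch in parallel:

| branch | conv/pool pairs | pre-dense length (L=8064) |
|--------|-----------------|---------------------------|
| bottom | 1               | 4031                      |
| middle | 2               | 2015                      |
| top    | 3               | 1007                      |

Every convolution is a width-3 kernel with stride 1 and valid (no-padding)
cross-correlation. The branch-initial kernel spans the full channel axis
(`40 x 1 x 3`) and collapses it into a single feature map, so all deeper
layers operate on one `(batch, length)` map. Pooling is non-overlapping
max-pooling with window 2 and stride 2, **keeping a trailing partial
window** (`ceil(n/2)`): this is the only convention that reproduces the
printed pooled lengths 4031, 2015 and 1007 simultaneously, and it is why
`core_shapes` exists as an analytic oracle independent of the network code.
Each branch ends in a dense layer of 100 units (ReLU); the three 100-wide
features are concatenated into a 300-wide fused feature, and a final dense
+ softmax maps it onto the nine classes. Batch normalization follows each
convolution (before the activation) and dropout (rate 0.5) precedes each
dense layer; both are configurable and the placement/rate are package
choices, since only their presence is canonical.

Two topologies are available. `parallel` (default) gives each branch its
own first convolution, which is how the branch tables read. `shared_stem`
computes the first conv feature map once and feeds it to all branches,
which is how the narrative description reads. Both produce identical shape
traces; the switch exists because both readings are defensible.

Layer-depth variants append one or two additional conv/pool blocks beyond
the top branch, each with its own 100-wide feature tap, widening the fused
feature to 400 or 500.

The network is implemented as a small NumPy layer engine (`cceeg.nn`) with
hand-written backpropagation: because every conv layer emits a single
feature map, the whole model is a few hundred thousand parameters and
trains comfortably on one CPU. Gradient correctness is verified against
central finite differences through the full assembled network in the test
suite. Weight initialization is fan-in-scaled Gaussian with an explicit
seed; training uses Adam (lr 1e-4 default), categorical cross-entropy,
batch size 64, and a fixed epoch budget (500 default) — early stopping is
off. Training is bit-reproducible given the seed.

## Preprocessing

Per channel: a 3rd-order Butterworth low-pass at 30 Hz (most task-relevant
EEG power lies below 30 Hz), then wavelet-threshold denoising. Filtering is
zero-phase (`sosfiltfilt`) by default — the analysis is offline, so the
single-pass group delay is pure nuisance; the effective magnitude response
is then the squared single-pass response. Non-finite inputs are rejected,
never repaired.

Denoising uses a multilevel DWT with the universal threshold
`sigma*sqrt(2 ln N)`, `sigma = MAD(finest details)/0.6745`. Defaults are
**sym8, level 4, hard thresholding**. Hard rather than soft: EEG rhythms
are oscillatory and therefore *not sparse* in the wavelet domain, and soft
thresholding biases every large in-band detail coefficient by the full
threshold — on a noisy 10 Hz sinusoid it reliably *increases* the error to
the clean signal, while hard thresholding removes noise-only coefficients
and leaves the oscillation intact (verified as a 100/100-seed Monte-Carlo
property in the tests). All choices are configurable via `WaveletSpec`.

Band power (theta 4-8, alpha 8-13, beta 13-30 Hz) is Welch-estimated and
integrated over the band, per channel.

## Synthetic data

The generator emulates the balanced nine-class study design: 500 epochs per
class (4500 total), 40 channels x 8064 samples at 128 Hz by default. Each
class is a (theta, alpha, beta) amplitude triple; a designated informative
channel group (default a parietal/centro-parietal set: P3, P4, Pz, CP1,
CP2, CP5, CP6) carries class-specific sinusoids (6, 10, 20 Hz) with random
phases over 1/f plus white noise; all other channels carry noise only. The
default amplitude code steps theta with the valence level and beta with the
arousal level (steps of 1.5 against unit-SD noise), so every class has a
unique band-power signature on the informative channels. All randomness
flows through one seed; per-epoch generators are derived via
`SeedSequence` spawn keys, so any epoch regenerates in isolation.

Two named desk-scale configurations exist for cheap experiments: 8 channels
(P3, P4, Pz, F3, F4, Fz, O1, O2) x 512 samples with 10 epochs/class
(`desk_scale_config`), and a "well-separated" variant
(`well_separated_config`: amplitude steps of 4, noise SD 0.5) representing
the maximally separable regime used by the learning-behaviour checks.

What the generator does **not** emulate: volume conduction, artifacts
(EOG/EMG), non-stationarity, inter-subject variability, or DEAP's actual
spectra. Consequently, passing tests show that the pipeline learns,
evaluates and ablates correctly on controlled band-power structure — they
say nothing about accuracy on real EEG, and the published full-scale
accuracies are deliberately out of scope here.

## Evaluation

Accuracy, macro-averaged precision/recall/F1 (the averaging scheme is
recorded in every report, since a scalar over nine classes is otherwise
ambiguous), a 9x9 confusion matrix, and a micro-averaged multiclass
ROC/AUC: labels are one-hot encoded, the label and probability matrices are
flattened row-wise into one binary-truth/score pair, and a standard
trapezoidal ROC is computed on it. Cross-validation is stratified k-fold
(k=10 default; the balanced design makes stratification the natural
choice), with a fresh model per fold and the across-fold accuracy SD
reported. The experiment harnesses use a single stratified holdout fold
(fraction 1/k) per run so that multi-seed replication stays affordable;
full CV is available via `cross_validate`.

## Experiments

**Channel ablation** removes a named electrode group before training.
Preset groups follow the printed parietal (P3, P4, PZ, CPZ, CP3, CP4) and
frontal (F3, F4, FZ, FP1, FP2, FCZ) lists; names resolve case-insensitively
against the montage, and names absent from it (CPZ and FCZ are not among
the 32 montage electrodes) are skipped with a warning so the presets stay
runnable. Surviving channel order is never permuted. On the well-separated
synthetic configuration, removing the planted parietal group collapses
accuracy to chance while removing the frontal group does not (10/10 seeded
replicates in the acceptance suite).

**Layer depth** trains the base model and the +1/+2-layer variants on
identical data and seeds, logging the appended layers' parameter-gradient
norms each epoch. The acceptance check asserts the weaker, testable form of
the depth claim: variant mean accuracy does not exceed the base mean by
more than the across-seed SD (8 seeds x 150 training epochs at desk scale).
A caveat this data exposes honestly: the deeper taps gain extra pooling
stages, i.e. more phase invariance, which the generator's random-phase
sinusoids mildly reward — the two-extra-layer variant trends a few points
above the base model (within one seed-SD). The synthetic conditions
therefore reproduce "no gain beyond seed noise" but not a literal
performance plateau; claims about gradient magnitudes of redundant layers
are logged as traces, not asserted.

**Feature separability** reports a silhouette score and a deterministic
2-D PCA projection (the method is recorded in every output). On synthetic
data the planted band-power features are the generative oracle and
upper-bound any learned representation's silhouette (~0.96); the meaningful
trained-model comparison is therefore against the raw-signal
representation, which fused features consistently beat.

## Problem sizes and numerical choices

Scaled-down studies run at 8 channels x 512 samples with 10-20 epochs per
class, 3-fold CV, learning rate 1e-3 and 60-200 training epochs — sizes
chosen so the full acceptance battery is a desk-scale computation. The
capacity (overfit) check disables dropout, as a pure memorization probe.
The 4500-epoch sizing check runs with 256-sample epochs; class counts,
balance and montage follow the defaults exactly. Degenerate inputs are
errors, not warnings: epochs shorter than the wavelet support, cutoffs at
or above Nyquist, all-channel ablations, single-class silhouettes and
out-of-range ratings all raise with the offending quantity named.
ROC ties are handled by the trapezoidal rule over unique thresholds.
Softmax is computed with max-subtraction; cross-entropy clamps
probabilities at 1e-12. Batch-norm inference uses running statistics
(momentum 0.9).
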