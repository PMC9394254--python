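# cceeg — cross-connected CNN for EEG emotion recognition

`cceeg` is a toolkit for nine-class emotion recognition from multichannel
EEG with a **cross-connected convolutional network** (C-c CNN): three
parallel convolutional branches of depth one, two and three extract bottom-,
middle- and top-level features from the raw epoch, each branch is compressed
to a 100-wide dense feature, the features are concatenated into a 300-wide
fused representation, and a softmax layer classifies it. It is aimed at
researchers who want to study multi-scale feature fusion on EEG — on the
restricted-access DEAP trials if they have them, or on the included
synthetic generator if not.

The pieces, usable as a library or through the `cceeg` command line:

- **Shape calculus** (`core_shapes`) — analytic output-size arithmetic for
  the branches (valid width-3 convolutions; window-2/stride-2 max pooling
  that keeps a trailing partial window, i.e. `ceil(n/2)`), reproducing the
  canonical branch geometry 8064 → 8062 → 4031 → 4029 → 2015 → 2013 → 1007
  exactly.
- **Preprocessing** (`preprocessing`) — per-channel 3rd-order Butterworth
  low-pass (30 Hz, zero-phase) followed by universal-threshold wavelet
  denoising, plus Welch band power (theta/alpha/beta).
- **Labeling** (`labeling`) — SAM valence/arousal ratings on the 1-9 scale
  binned 3x3 (boundaries at 4 and 7) into nine emotion classes.
- **Synthetic data** (`synthetic_data`) — balanced labeled EEG-like epochs
  (default 4500 epochs, 500 per class, 40 channels x 8064 samples at
  128 Hz) with class-dependent theta/alpha/beta power planted on a named
  informative channel group.
- **Model and training** (`ccnn_model`, `nn`, `train_eval`) — the C-c CNN
  on a compact NumPy layer engine (Adam, categorical cross-entropy,
  batch norm, dropout), stratified k-fold cross-validation, and the metric
  battery: accuracy, macro precision/recall/F1, confusion matrix, and
  micro-averaged multiclass ROC/AUC built by one-hot flattening.
- **Experiments** (`experiments`) — channel-ablation and layer-depth
  harnesses and feature-separability scoring.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

Train and cross-validate on a small, well-separated synthetic dataset
(8 channels x 512 samples, 10 epochs per class):

```python
import numpy as np
from cceeg.synthetic_data import well_separated_config, generate_dataset
from cceeg.ccnn_model import default_architecture, build_model, extract_features
from cceeg.train_eval import TrainConfig, cross_validate

config = well_separated_config(epochs_per_class=10, seed=42)
dataset = generate_dataset(config)
print(f"dataset: {len(dataset)} epochs, "
      f"{dataset.epochs[0].n_channels} channels x {dataset.epochs[0].n_samples} samples")

spec = default_architecture()
train_cfg = TrainConfig(epochs=200, batch_size=32, learning_rate=1e-3,
                        k_folds=3, seed=0)
report = cross_validate(spec, dataset.signal_array(np.float64),
                        dataset.labels, train_cfg)
print(f"CV accuracy {report.accuracy:.3f} +- {report.accuracy_sd:.3f} "
      f"(chance 0.111), macro F1 {report.f1:.3f}, micro AUC {report.auc:.3f}")

model = build_model(spec, 8, 512, seed=0)
fused = extract_features(model, dataset.signal_array(np.float64), "fused")
print(f"fused feature matrix: {fused.shape}")
```

Output:

```
dataset: 90 epochs, 8 channels x 512 samples
CV accuracy 0.400 +- 0.047 (chance 0.111), macro F1 0.370, micro AUC 0.772
fused feature matrix: (90, 300)
```

The cross-validated accuracy is ~3.6x chance on 90 epochs of planted
band-power structure — the network recovers the class code from raw
signals — and the fused feature is the 300-wide concatenation of the three
100-wide branch features. At full scale the same `spec` builds the
40-channel x 8064-sample network unchanged.

The same pipeline from the shell:

```sh
cceeg generate --config run.yaml --out data/
cceeg preprocess --in data/epochs.h5 --out data/clean.h5
cceeg train --config run.yaml --data data/clean.h5 --out fit/ --cv
cceeg experiment ablation --config run.yaml --out ablation/
```

Users with DEAP access can convert a preprocessed per-subject file with
`cceeg import-deap --in s01.dat --out s01.h5`; the dataset is
restricted-access and is never downloaded by this package. The published
full-scale DEAP accuracies are documented in `docs/methods.md` as out of
scope for the bundled synthetic-data studies.

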