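# harformer

A sequence-to-sequence transformer for **wearable-sensor human activity
recognition (HAR)**, for researchers and engineers working with smartphone
inertial signals (3-axis accelerometer in m/s², 3-axis gyroscope in rad/s).
The package provides the full pipeline: a windowed-signal data model with a
flat CSV dialect, an activity-pair data-augmentation algorithm, the
transformer classifier itself (implemented in NumPy, including training),
evaluation reports, and attention/position-embedding interpretability
artifacts — plus a seeded synthetic-signal generator so everything runs
end-to-end without any external download.

## The model

A window is a `T × C` signal matrix (default `T = 300` steps = 3 s at
100 Hz, `C = 6` channels) and the model emits one class prediction per
timestep (`T × K` logits), so windows containing a transition between two
activities are labelled correctly on both sides.

The pipeline is

```
x → (x − μ_c)/(σ_c + ε) → x W_in + b_in + P → L × encoder block → LN → W_out
```

with per-channel calibration `μ_c, σ_c` stored from the training data, a
learned position embedding `P ∈ R^{T×d}`, and pre-norm encoder blocks

```
u = x + Dropout(MHA(LN(x))),   y = u + Dropout(FFN(LN(u)))
```

where multi-head self-attention follows
`Attention(Q,K,V) = softmax(QKᵀ/√d_k) V` with per-head projections
`head_i = Attention(xW_i^Q, xW_i^K, xW_i^V)` combined by `W^O`, and
`FFN(x) = act(xW₁+b₁)W₂+b₂` (GELU by default, ReLU available) acts
per timestep. Defaults: `d = 128`, FFN width 256, 6 heads, 3 layers,
dropout 0.1, truncated-normal init (sd 0.02, ±2 sd).

Training uses Adam with a 10-step linear warmup to lr 1e-3 followed by
cosine decay to zero, global gradient-norm clipping at 3.0, label smoothing
0.1, batch size 64, 50 epochs, keeping the parameters with the best
validation per-timestep accuracy.

**Data augmentation.** New two-activity examples are built by concatenating
two windows of logically successive activities into a `2T` window and
keeping every second timestep (even indices), giving a `T`-step window
whose label track switches exactly at `T/2`. Per ordered activity pair the
number of generated windows is `min(n_a, n_b)` so no example of the rarer
class is duplicated; the shipped pair table covers 100 ordered pairs and
excludes transition activities (Lay-stand, Stand-sit) and Push-up.

## Worked example

```python
import numpy as np
from harformer import (
    TransformerSequenceClassifier, desk_preset, generate_dataset,
    stratified_split, PairRule, plan_counts, build_augmented_dataset,
)

dataset = generate_dataset(desk_preset(seed=3))          # 4 classes, 800 windows
train, val, test = stratified_split(dataset, (0.70, 0.15, 0.15), seed=3)

clf = TransformerSequenceClassifier(
    d_model=32, d_ff=64, n_heads=2, n_layers=2, epochs=30, random_state=3,
)
clf.fit(*train.to_arrays(), validation_data=val.to_arrays())
print(f"best validation accuracy: {clf.best_validation_accuracy_:.3f}")
print(f"held-out accuracy:        {clf.score(*test.to_arrays()):.3f}")
```

prints

```
best validation accuracy: 1.000
held-out accuracy:        1.000
```

i.e. on the desk-scale synthetic study (4 well-separated activity classes,
50-step windows) the small model classifies every held-out timestep
correctly. `clf.predict(X)` returns one label per timestep;
`clf.attention_records(window)` exposes the per-layer/per-head `T × T`
attention matrices behind a prediction.

The same pipeline is scriptable from the shell:

```bash
harformer synth --out data.csv --seed 3
harformer augment --dataset data.csv --out aug.csv --rules my_rules.csv
harformer split --dataset aug.csv --timestep-labels --out-prefix part
harformer train --train-csv part.train.csv --val-csv part.val.csv --out model.npz
harformer evaluate --checkpoint model.npz --dataset part.test.csv --out report.json
harformer inspect-attention --checkpoint model.npz --dataset part.test.csv --out-prefix viz
```

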