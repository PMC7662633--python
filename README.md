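# emdhar

Multi-modal recognition of everyday activities — watching TV, playing with
toys, eating, playing electronic games, doing online exercises,
reading/writing, drawing — from three simultaneously recorded streams: a
single-channel EEG (512 Hz), a head-mounted camera's image sequence
(0.1 Hz) and a 3-axis motion signal (31 Hz). It is aimed at researchers in
wearable/biomedical signal processing who need a reproducible reference
pipeline for EMD-based EEG features and multi-modal sensor fusion.

## Method

**EEG via empirical mode decomposition.** Each EEG epoch x(t) is sifted
into intrinsic mode functions (IMFs): starting from d₀ = x, the mean m(t)
of the cubic-spline envelopes through the maxima and minima is subtracted,
d_j = d_{j−1} − m, until

    SD = Σ|m(t)|² / Σ|d_{j−1}(t)|² ≤ 0.3,

giving one IMF c_i; the residue r_i = r_{i−1} − c_i is sifted again until
it is monotonic or itself an IMF, so that x = Σᵢ cᵢ + r. Because EEG
epochs typically produce 4–8 IMFs, the IMFs are merged into exactly four
grouped signals I1–I4 (high → low frequency) by a fixed rule table, and
11 statistics — entropy, mean, IQR, mean absolute deviation, range,
variance, skewness, kurtosis, L2, L1 and L∞ norm — are computed per group:
a 44-dimensional EEG feature vector. A conventional baseline replaces EMD
with FFT masking into nine brain-wave bands (δ, θ, α, SMR, mid-β, high-β,
low-β, whole-β, γ; 99 dimensions).

**Images.** Between consecutive frames, the object's bounding box yields
7 displacement features (edge deltas, absolute-centre changes and their
magnitude), and the difference of the two patches' orthonormal 2-D DCT
coefficient matrices — zero-filled to a common shape, which resizes
without injecting high frequencies — yields 5 statistics: 12 dimensions.

**Motion.** Per-axis mean and population variance of (x, y, z): 6
dimensions.

**Fusion and classification.** Concatenation gives 62-dimensional fused
vectors (44 + 12 + 6). A random forest of 100 trees, each grown on a
bootstrap resample with 5 candidate features per split and combined by
majority vote, is trained on a random 30% of the data and tested on the
remaining 70%; accuracy and macro F1 are reported.

Because the original volunteer recordings are not public, the package
ships a synthetic generator (`emdhar.synthetic`) producing activity-
dependent EEG band-power profiles, object-motion rates and motion-signal
moments, on which the whole pipeline is exercised and benchmarked.

## Worked example

```python
import numpy as np
from emdhar import (TimeSeries, decompose, gen_dataset,
                    split_dataset, train_forest, evaluate)

# EMD of a two-scale signal: 2 Hz + 40 Hz tones at 512 Hz
t = np.arange(512 * 4) / 512
x = TimeSeries(np.sin(2*np.pi*2*t) + 0.5*np.sin(2*np.pi*40*t), rate_hz=512)
dec = decompose(x)
print("n_imfs:", dec.n_imfs)
print("max recon err:", float(np.max(np.abs(dec.reconstruct() - x.samples))))

# end-to-end synthetic benchmark: 20 epochs per activity
X, y, names = gen_dataset(n_per_class=20, seed=0)
print("X shape:", X.shape)
Xtr, ytr, Xte, yte = split_dataset(X, y, train_frac=0.30, seed=0)
model = train_forest(Xtr, ytr, n_trees=100, m_features=5, seed=0)
res = evaluate(model, Xte, yte)
print(f"accuracy={res.accuracy:.4f} macro_f1={res.macro_f1:.4f}")
```

prints

```
n_imfs: 2
max recon err: 2.220446049250313e-16
X shape: (140, 62)
accuracy=0.8265 macro_f1=0.8030
```

The two tones come back as two IMFs and the decomposition reconstructs
the input to machine precision; 140 fused 62-dim epochs split 42/98, and
the forest recognises the seven activities well above the 1/7 ≈ 0.14
chance level even at this small sample size.

## Command line

```bash
emdhar simulate --n-per-class 50 --seed 7 --out data/
emdhar decompose --input data/eeg/epoch_00000.csv --rate 512 --out imfs.csv
emdhar extract-bands --input data/eeg/epoch_00000.csv --rate 512 --out bands.csv
emdhar extract-features --data-dir data/ --out features.csv
emdhar train --features features.csv --trees 100 --mtry 5 --seed 7 --out model.bin
emdhar evaluate --model model.bin --features features.csv --report report.json
emdhar run --data-dir data/ --report report.json
emdhar compare --data-dir data/ --out comparison.csv   # 7 modality subsets × EMD/filter
```

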