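# Methods

## Empirical mode decomposition

The sifting loop follows the classical scheme: locate strict interior
extrema, interpolate natural cubic splines through the maxima and the
minima, subtract the envelope mean, and stop when the envelope-mean
energy ratio SD = Σ m² / Σ d² drops to the threshold (default 0.3) or
below. The IMF returned is the iterate *after* the final subtraction.
Choices the classical description leaves open are pinned as follows.

* **Envelope boundaries.** The two extrema nearest each end are mirrored
  across the signal boundary before spline fitting, and the envelope is
  evaluated only on the original support. This standard end-effect
  mitigation is fixed (not configurable) so decompositions are
  bit-reproducible. An extremum sitting exactly on the boundary would
  duplicate its mirrored knot; duplicates are dropped to keep knots
  strictly increasing.
* **Spline type.** Natural cubic splines (zero second derivative at the
  end knots), the common default where "cubic spline" is unqualified.
* **Plateaus.** A flat run that is a local extremum is represented by its
  first index — a deterministic tie-break.
* **IMF property test.** A signal counts as an IMF when its extrema and
  zero-crossing counts differ by at most one *and* its envelope-mean
  energy ratio is within the sifting threshold. The residue check uses
  this test: a residue that is already an IMF is taken as the final IMF
  (zero residue), otherwise decomposition ends when the residue is
  monotonic or has too few extrema to envelope.
* **Termination guards.** Sifting caps at 100 iterations per IMF
  (practically, band-limited signals converge in 1–3) and decomposition
  at 12 IMFs; both only guard pathological inputs and emit warnings when
  hit.
* **Reconstruction.** Every stage is an exact subtraction, so
  Σ IMFs + residue equals the input to floating-point round-off; the test
  suite enforces 1e−8·‖x‖∞ per sample.

### IMF grouping

4–8 IMFs map onto the four groups I1–I4 by the fixed table
{(1),(2),(3),(4)}, {(1),(2),(3,4),(5)}, {(1),(2,3),(4,5),(6)},
{(1,2),(3,4),(5,6),(7)}, {(1,2),(3,4),(5,6),(7,8)}. Outside that range
the behaviour is this package's own convention: with fewer than four
IMFs the leading groups take one IMF each and the rest are all-zero
signals (a warning is emitted; the zero groups produce the degenerate
constant-signal statistics row, keeping the 44-dim contract), and with
more than eight every IMF from index 7 on joins I4 — the natural
extension of the 8-IMF rule.

## FFT band baseline

Band signals are produced by zeroing real-FFT bins outside the band and
inverting; using the real FFT keeps the conjugate-symmetric half
consistent automatically, so outputs are exactly real and a pass-band
on-bin tone returns with zero phase shift. Band edges are treated as
closed intervals: the printed 14.99/19.99 upper edges of SMR and mid-β
make the non-overlapping quintet disjoint at 0.01 Hz resolution while
low-β and whole-β remain overlapping views. A bin falling exactly on a
shared edge (e.g. 4 Hz when the epoch length makes it a bin) is kept by
both adjacent bands; energy-partition tests therefore use epoch lengths
whose bins avoid the edges.

## Statistic conventions

The 11 statistics are computed identically wherever they appear
(IMF groups, bands, DCT differences):

* entropy — Shannon entropy in nats of the empirical histogram over 64
  equal-width bins spanning [min, max]; a constant signal has entropy 0.
  64 bins is a fixed compromise between resolution and estimation noise
  at the epoch lengths used (≥ ~300 samples).
* variance — population (divide by n); MAD — mean absolute deviation
  from the mean; skewness — m₃/m₂^{3/2}; kurtosis — m₄/m₂² (non-excess);
  both defined as 0 for zero-variance input.
* IQR — linear-interpolation ("type 7") quantiles.
* norms — unnormalised: L2 = √Σx², L1 = Σ|x|, L∞ = max|x|.

## Image features

Boxes are pixel-coordinate, origin top-left, inclusive on both edges.
The seventh spatial feature combines the changes of the absolute
box-centre coordinates; its printed form is a sum of squares, but since
it describes a positional change the Euclidean root is taken by default,
with the raw squared sum available via `sqrt_distance=False`. The
centre features use |x_mean| as given, so they are not invariant under
translations that cross zero — the test suite pins this distinction
feature by feature. DCT coefficients are type-II orthonormal (making the
1×1 transform the identity and the constant-patch DC term n·v);
difference statistics are computed on raw coefficients with no
normalisation, after zero-filling the smaller matrix into the
low-frequency corner of the common shape.

## Classification

The forest is assembled from scikit-learn `DecisionTreeClassifier`
instances: each of the 100 trees grows on an explicit bootstrap resample
(n draws with replacement) with 5 random candidate features per split
(Gini by default, information gain selectable), to purity unless a
minimum impurity decrease is configured; depth is otherwise automatic.
Prediction is a hard majority vote with ties resolved to the smallest
class index in the sorted label order. Doing the bagging and voting in
this package (rather than delegating to `RandomForestClassifier`, which
soft-votes averaged probabilities) keeps the resampling and vote
contract explicit and lets a single-tree forest be checked exactly
against one bagged tree; an accuracy cross-check against the library
forest is part of the test suite. The 30/70 train/test split takes
⌊0.3 N⌋ training rows uniformly without replacement — no stratification,
no cross-validation. Macro F1 averages per-class F1 over all seven
activities, scoring 0 for a class absent from both truth and
predictions.

## Synthetic data

The generator emulates the three properties the method exploits, not the
physiology of EEG or the optics of a camera:

* EEG epochs are sums of five band-limited sinusoids (δ, θ, α, β, γ) with
  activity-specific amplitudes, epoch-random in-band frequency and phase,
  plus white Gaussian noise (σ = 1 against dominant amplitudes of ~2.5).
  The overlapping β sub-bands of the analysis side are views, not
  generative components. Real EEG's 1/f background, artifacts and
  nonstationarity are absent, so passing benchmarks demonstrate the
  pipeline's mechanics and the value of fusion on band-structured
  signals, not clinical-grade recognition accuracy.
* Motion windows are per-axis Gaussian with activity-specific mean
  (head orientation) and variance (movement intensity).
* Image sequences are a textured rectangle random-walking (clamped) over
  a smooth random background with ±2 px size jitter; the step scale is
  activity-specific, and patches are crops of the texture so DCT
  differences respond to genuine content change.

The default epoch is 10 s — one image-frame interval at the 0.1 Hz
camera rate — so each sample fuses one EEG epoch (5120 samples), one
motion window (310 samples) and one frame pair; epoch length is
configurable.

The seven shipped profiles are deliberately *partially* redundant across
modalities: playing-with-toys and electronic-games share a motion
signature, reading/writing and drawing share another, and several EEG
profiles are close while the image step scales differ. No single
modality separates all seven activities, but the fused vector does —
this is the structure behind the benchmark's multi-modal ordering. A
`separation` dial interpolates all profiles toward their common mean:
at 0 the activities are indistinguishable and accuracy falls to 1/7.

## Benchmark sizes

The shipped benchmark uses 50 epochs per class (350 samples), 100 trees,
and averages over 5 seeds; the chance-level control uses the same sizes
with separation 0. These sizes give stable seed-averaged accuracies
(fused ≈ 0.94, single modalities 0.3–0.75, degenerate ≈ 0.14) while a
full benchmark run stays around a minute on one core.

## Known limitations

* EMD end effects are mitigated, not eliminated; envelopes within one
  oscillation of the boundary are extrapolations.
* The grouping convention outside 4–8 IMFs, and the zero-group rows it
  produces, are this package's choices; extremely short or pure-tone
  epochs (< 4 IMFs) yield partially degenerate EEG features.
* The generator's activity profiles are plausible but invented; absolute
  benchmark accuracies characterise the pipeline on this generator only.
* Object segmentation is out of scope: bounding boxes and patches are
  accepted as input (the generator provides them directly).
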