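# Methods

This note documents the models, numerical choices and limitations behind
`fplselect`, in the package's own terms.

## Feature extraction

Segments are fixed-length multichannel EEG arrays (default geometry 3 s at
128 Hz, 30 channels after excluding the two reference electrodes A1/A2 from
a 32-electrode 10–20-style cap). Per channel the PSD is estimated with
Welch's method using a single Hann-tapered window equal to the full segment
(384 samples, no overlap) — with one window the estimate is a modified
periodogram; the `window_seconds` argument generalises to shorter, averaged
windows. Frequency bands are half-open intervals `[lo, hi)` evaluated on
bin *center* frequencies, which prevents double counting at shared edges
(θ [4,8), α [8,12), β [12,30)). Band power is the rectangle-rule integral
(bin sum × bin width) of the density; a `relative=True` switch divides the
three power columns by total power (the seven ratios are scale-invariant
and unaffected). Absolute powers are the default.

Ratio denominators carry an additive guard of 1e-12 so silent channels
yield zeros rather than NaN. Group columns (frontal, temporal, all) are
arithmetic means of the member channels' already-computed feature values,
not features of averaged signals. Frontal = {Fp1, Fp2, F7, F3, Fz, F4,
F8} and temporal = {FT7, FT8, T3, T4, TP7, TP8, T5, T6} are
montage-conventional defaults; the exact membership (e.g. whether the
fronto-central FC row counts as frontal) is a genuinely open convention,
so groups are fully configurable.

Parseval calibration: a single Hann-windowed estimate of total power has a
relative standard deviation of about 7% on 3-s white noise, so calibration
is asserted in aggregate (mean absolute relative error ≤ 15%, bias ≤ 5%
over 100 draws), not per draw.

## Classifier and Feature Prune Layer

The classifier is a small fully connected ReLU network (default hidden
sizes 256/128/64, two output classes, no dropout — the architecture that
won the architecture-comparison protocol; dropout layers with p = 0.5 are
available for the variants that use them). It is implemented directly in
NumPy with a hand-written backward pass and Adam (lr 1e-3, batch 64): the
pruning contract below requires byte-level control over optimizer state,
and the networks are small enough that this is also the simplest fully
deterministic route. Linear layers are initialised with the uniform
fan-in scheme U(±1/√fan_in); the FPL weights start at exactly 1.

The FPL computes the Hadamard product `x · W · m`. Pruning is realised
through the binary mask `m`, never by editing `W`: the mask factor makes
the gradient of every masked weight identically zero, and after each
optimizer step (and each prune event) the Adam moment buffers of masked
entries are cleared, because an adaptive optimizer would otherwise keep
moving a zero-gradient parameter through stale momentum. The guaranteed
invariant, exercised by tests, is **bitwise constancy** of masked weights
under continued training. The FPL shares the network's optimizer and
learning rate and carries no weight decay (decay would bias the magnitude
ranking toward uniform shrinkage).

Ties in |W| at a prune step are broken by lowest column index (stable
sort). A mask-equivalence construction (`reduce_network`) folds surviving
FPL weights into the first linear layer over the surviving columns; its
forward pass matches the masked network to float precision at every
pruning stage, which is both a correctness oracle and the deployment path
for a selected subset.

Inputs are z-scored with training-split statistics before entering the
FPL. Raw band powers span orders of magnitude across channels and would
otherwise dominate the magnitude ranking regardless of relevance; whether
the original protocol normalised its inputs is unstated, so this is a
design choice of this package.

## Selection loop

Pruning triggers are evaluated once per epoch, in the fixed order
precision → epochs → overfitting; "precision" is the **validation** macro
precision (a held-out 10% of the training pool — using the final test set
here would leak it into selection). Pseudo-overfitting is the signed
difference train − validation precision. The deletion schedule
`⌊f·d/n⌋` is clamped to `[1, d − des_feat_num]`: the lower clamp
guarantees progress when the floor reaches zero late in training, the
upper clamp makes the loop land exactly on the target count. The prune
counter n starts at 1 and counts prune events, not epochs.

The loop terminates when the active count reaches `des_feat_num`, or after
`max_epochs_final` total epochs (default 500 — no canonical value exists,
so it is a configuration knob); in the budget-exhausted case the
top-`des_feat_num` active features by |W| are returned and the truncation
is flagged on the result. Target counts for "top X%" requests use
round-half-up (5% of 330 → 17). A requested size equal to the full set is
a no-op selection returning all features.

Subset evaluation retrains the base architecture without the FPL from
scratch, `repeats` times (default 4) with seeds derived as master + run
index, and reports macro accuracy/precision/recall/F1 on the test split
plus pseudo-overfitting, with per-metric standard deviations. Splitting is
stratified 70/30 with a 10% validation carve-out of the training pool and
rejects any split whose class-count gap exceeds 20. The hyperparameter
grid crosses f ∈ {0.1,…,0.4} with final_prec ∈ {0.60,…,0.95 step 0.05}
(32 cells) and ranks cells by retrained-subset macro precision.

Macro metrics are computed from the confusion matrix in-package (they run
in the inner training loop); a class with no predicted positives
contributes 0 to macro precision, with a warning. Tests cross-check them
against scikit-learn and a brute-force enumeration.

## Synthetic data

The tabular generator plants `k_informative` columns as class-conditional
Gaussians with a standardized mean shift (`effect_size`), optional
redundant columns as noisy copies (σ = 0.3) of informative ones —
mimicking the near-duplicate signals of adjacent electrodes and enabling
the observation that subset *identity* varies across seeds while subset
*performance* does not — and pure N(0,1) noise elsewhere. The default
sample size is 2000, matching the scale of the motivating balanced EEG
corpus (~2022 segments). Column positions are randomised.

The signal generator emulates geometry and band structure only: per band a
sinusoid with per-segment random frequency and phase (and small
per-channel jitter), scaled by class multipliers — drowsy θ × 1.8,
alert β × 1.4 by default — over 1/f background noise synthesised by
spectral shaping of white noise, shared across channels with weight
√ρ (ρ = 0.3). It is *not* a physiological simulation: no dipole/forward
modelling, no artifacts, no non-stationarity, no inter-subject
variability. Passing tests on it demonstrate the machinery (extraction
correctness, selection recovering planted band signal), not real-world
drowsiness detection performance.

Both generators are pure functions of (spec, seed).

## Problem sizes in tests and the acceptance script

The planted-recovery benchmark runs the spec'd conditions — 10 informative
of 100 columns, effect size 2.0, f = 0.2, final_prec = 0.75, 20 seeds —
at the default 2000-sample size; its downstream comparison against random
selection uses 2 retraining repeats of 40 epochs per arm, sizes chosen so
the whole battery completes in minutes on one CPU. Subset-landing runs use
240 synthetic segments and a 64/32 hidden architecture for the same
reason; landing counts are architecture-independent. Unit tests use
further-reduced tables (400–600 samples, 30–50 columns) and a 32/16
network.

## Known limitations

- Feature scoring inherits the selection method's documented sensitivity
  to network initialisation: different seeds can select different (equally
  performing) subsets, especially under redundancy.
- Binary labels only (macro averaging would extend to more classes, but
  the balanced-split and trigger logic are exercised for two).
- The NumPy implementation is CPU-bound and single-threaded apart from
  BLAS; it is sized for feature vectors of order 10²–10³, not images.
- The epoch-budget fallback returns a |W|-ranked truncation, which is a
  heuristic rather than a converged selection; the result flags it.
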