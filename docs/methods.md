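# Methods

This note records the scientific and numerical choices behind
`noduleboost`: what each stage models, the parameters that matter, and what
the synthetic bench does and does not establish.

## Phantom generator

The generator emulates the data regime of false-positive reduction in
pulmonary-nodule CAD: balanced sets of nodule and nonnodule candidate
positions in a 3D grayscale volume. It is a geometric phantom, not a CT
simulator — no beam hardening, dose, or reconstruction kernels — because the
classifier standardizes each patch, so only contrast ratios and shapes
carry information. Intensities are in arbitrary units.

- **Nodules** are isotropic Gaussian blobs, amplitude = `nodule_contrast`
  (default 60) over a background of level 100 with additive Gaussian noise
  (sd 10), σ = diameter/4 with diameter drawn uniformly from 8–18 voxels.
  The σ = diameter/4 convention puts the full drawn diameter at ≈ e^{−2} of
  peak amplitude, a reasonable reading of "a blob this size".
- **Vessels**, the confuser class, are random-orientation cylinders of
  radius 1–2 voxels rendered by marching unit steps along a line and adding
  a Gaussian cross-section per step, normalized by the line-integral factor
  `radius·√(2π)` so the on-axis peak equals the intended amplitude —
  without that factor overlapping stamps sum to several times the nominal
  contrast. Vessel peak intensity is 0.6× nodule contrast (thin vessels
  dim by partial volume), which keeps them bright enough to confuse an
  intensity-only rule while leaving nodule-vs-nonnodule local intensity
  correctly ordered for ≳ 95 % of cross-class pairs, a property the test
  suite checks directly.
- **Candidates.** Nodule candidates sit at blob centers; nonnodules
  alternate between vessel voxels and plain background. All centers are
  rejection-sampled at ≥ 40 voxels pairwise separation (the largest view
  crop), so no two patches share a center region. This hard-sphere packing
  is what forces the default volume to 160×384×384 for the standard
  100-candidate bench; the generator raises an explicit placement error
  rather than silently degrading when a volume is too small.
- **Determinism.** One `numpy` generator seeded from the config drives
  every draw; identical config ⇒ bit-identical volume and candidate list.
- The difficulty knob is `nodule_contrast`: at 0, vessels (scaled to it)
  vanish too and the volume is pure noise, making label and local intensity
  statistically independent — the suite verifies this with a permutation
  test.

What passing phantom tests shows: the pipeline's mechanics (geometry,
normalization, optimization, boosting, evaluation) are correct and the
classifier can exploit blob-vs-tube shape and contrast. What it does not
show: performance on real CT, where nodule morphology, spacing anisotropy,
reconstruction texture and annotation noise are all harder. A z-axis-aligned
vessel is nearly indistinguishable from a small nodule in purely axial
views — the same limitation 2D-view methods face on real scans.

## Multiview extraction

Views are axial (fixed-z) crops at sizes 20/30/40 px centered on the
candidate, each spline-resized (order 3 by default; `scipy.ndimage.zoom`,
endpoint-aligned so equal sizes are an exact identity) to the common input
side, stacked smallest-first as channels. Conventions fixed for
bit-reproducibility: 0-based (z,y,x) coordinates; the candidate voxel
occupies index `size//2` of the crop (for even sizes, `size/2`);
out-of-volume pixels are filled by edge replication, which avoids
injecting artificial dark structure at volume borders. Each view is
z-scored last (zero mean, variance floor 1e−8; a constant view is defined
as all-zeros) because self-normalizing networks assume standardized inputs.
Per-candidate 3D cubes at the same side lengths can be emitted to the
archive for bookkeeping; the classifier consumes only the 2D stacks.

## SNMV-CNN base learner

A compact CNN engine written on NumPy (im2col convolutions, 2×2 max-pool,
dense layers, reverse-mode gradients, Adam): at desk scale (32×32×3 inputs,
two conv blocks of 8 and 16 3×3 filters, one 32-unit hidden layer, ~10⁴
parameters) training takes fractions of a second per epoch, and a pure-NumPy
stack keeps the whole package light and deterministic.

- **SELU.** `λx` for x > 0, `λα(eˣ−1)` for x ≤ 0, α = 1.6733, λ = 1.0507;
  x = 0 is assigned to the (vanishing) negative branch. Verified against an
  extended-precision oracle at 1e−10 and by the depth-10 self-normalization
  smoke test (activation mean within ±0.2, variance within [0.5, 2]).
- **Initialization** is zero-mean normal with variance 1/fan-in — the
  variance-preserving scheme SELU's fixed point assumes. Biases start at 0,
  so a zero input provably yields P = 0.5.
- **Alpha-dropout** (rate 0.05) drops units to the SELU saturation value
  −λα with the affine mean/variance correction, keeping standardized
  activations standardized under dropout.
- **Training** minimizes per-sample-weighted binary cross-entropy from the
  logit (numerically stable form) with Adam (β₁ = 0.9, β₂ = 0.999).
  Boosting weights enter as loss weights rescaled to mean 1 — not by
  resampling — so a fit is a deterministic function of (seed, data order)
  and scale-invariant in the weights; a zero-weight sample is provably
  inert in full-batch training.
- **Profiles.** Desk scale: lr 3e−3, batch 4, 3 epochs — sized so the
  M = 3 × 3-epoch bench (~60 Adam steps per learner) reliably fits its
  training set; early runs at batch 8 underfit (train accuracy 0.94–0.99),
  and halving the batch fixed that across seeds. The full-scale profile
  (224×224 inputs, lr 1e−4, momentum 0.9, batch 128, binary cross-entropy)
  is exposed as `paper_profile()` / `--profile paper`; it is supported
  configuration, not exercised by the test suite.
- Hard labels use P ≥ 0.5 → +1 (ties positive, documented).

## Boosting

Discrete AdaBoost over ±1 labels, base-learner-agnostic (anything with
`fit(x, labels, sample_weights)` / `predict_hard`). Numerical choices:

- ε is clamped symmetrically to [1e−10, 1−1e−10] before the log-odds vote,
  since d is undefined at ε ∈ {0, 1}; a perfect learner thus gets a large
  (~11.5) but finite vote.
- A round with ε ≥ 0.5 gets a non-positive vote and, by default
  (`epsilon_policy="continue"`), the loop runs its fixed M rounds —
  matching fixed-iteration boosting; `"stop"` truncates instead. Default
  M = 3 at desk scale.
- `update_weights` short-circuits d = 0 to an exact identity (exp(0) = 1,
  Z = 1).
- Per-round learner seeds derive from the master seed via `SeedSequence`,
  so a fit replays exactly.
- Inference: weighted margin Σ dₘfₘ(x) (or unweighted majority under the
  simple scheme); margin 0 maps to +1; the margin is the ROC score. Reading
  fₘ(x) as a hard ±1 vote (not a probability) is deliberate: it matches the
  sign-vote combination rule, and probabilities remain available from the
  base learners directly.

Correctness is established against independent oracles rather than by
spot values alone: a looped scalar AdaBoost transcript must agree with the
engine's ε/d/weight sequence to 1e−10 on random stump problems; the exact
update must leave exactly half the mass on the mistake set; and the
training error must respect Πₘ 2√(εₘ(1−εₘ)) on every run. Decision stumps
(exhaustive threshold/polarity search, deterministic tie-break) are part of
the package for exactly this purpose.

## Evaluation

Positive class = nodule throughout. Accuracy, sensitivity and specificity
are exact count ratios; an empty denominator raises rather than returning
0, because silent zeros would corrupt cross-validation averages. The ROC
sweeps thresholds over unique scores descending (ties grouped, one point
per unique value), prepends (0,0), and integrates by trapezoid — which
makes AUC equal the Mann–Whitney statistic P(s₊ > s₋) + ½P(tie), the
property the suite checks against brute force and against scikit-learn.
The 80/20 split and the 10-fold harness are stratified by label
(largest-remainder apportionment; round-robin dealing), deterministic per
seed; the k-fold harness treats each fold as the test set exactly once.

## Reproducibility

Every stochastic stage's seed derives from one master seed; all arrays are
float64 through the network; runs on the same platform reproduce
`metrics.json` byte for byte (asserted in the suite by rerunning the full
pipeline). Problem sizes in the test suite and acceptance script — the
100-candidate bench, 32×32 inputs, M = 3, 3 epochs, stump oracles at
n ≤ 20 — are the package's standard desk-scale conditions, chosen so the
entire suite runs in well under a minute on one CPU while still exercising
every stage at full fidelity.

## Known limitations

- Axial-only 2D views cannot disambiguate z-aligned vessels from small
  nodules; 3D context is deliberately out of scope (cubes are archived,
  not consumed).
- The phantom's difficulty is set by a single contrast knob; it has no
  anatomy (lung boundaries, pleura, fissures) and no spacing anisotropy.
- The NumPy engine is single-threaded-deterministic but not fast enough
  for the 224×224 full-scale profile at realistic dataset sizes; that
  profile exists for configuration parity, and a GPU framework port would
  be needed to train it seriously.
- Boosting with strong CNN base learners often yields near-zero ε and
  hence near-equal large votes; the ensemble then behaves close to an
  average of independently-seeded learners. This matches the method's
  design; the exactly-verifiable regime is exercised with stumps.
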