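# Methods

This note documents the models, conventions and numerical choices behind
`pbdkit`, and what the synthetic experiments do and do not demonstrate.

## Wavelet packet features

The packet transform is separable: at every node the 2D block is filtered
along rows and columns with the quadrature-mirror pair and downsampled by
two per axis, yielding four children per node — LL, LH, HL, HH — and
4^d terminal subbands at depth d. Channels are kept in natural (Paley)
order, i.e. channel m at depth d reads as a base-4 number whose digits
are the split choices from the root. The order itself is arbitrary but
must be fixed: feature coordinates are only comparable across images and
runs if channel m always means the same filter path. The naming treats
the second channel of a split as high-pass along the row axis; this
matches the underlying filter bank and matters only for labels, not for
the feature values as a set.

Defaults are Haar filters at level 2 (16 features). Boundary handling is
periodic by default because it makes the transform exactly orthonormal on
dyadic sizes — perfect reconstruction to machine precision and exact
energy conservation, both of which the test suite asserts at 1e-8.
Symmetric extension is available by configuration for users who prefer it
on strongly non-periodic images; it sacrifices exact Parseval equality.
Non-dyadic inputs are padded to the next multiple of 2^level with the
chosen extension and cropped back on reconstruction.

Filtering is delegated to PyWavelets; this package owns tree indexing,
ordering, padding and validation. The tests verify the coefficients
against an independent dense-matrix implementation of the Haar filter
bank on 8×8 inputs (1e-10), so the dependency is cross-checked rather
than trusted.

## From coefficients to entropy

A subband is converted to a discrete distribution by normalized energy,
p_k = c_k² / Σ_j c_j² — the convention of the wavelet-entropy literature,
which makes the features invariant to global intensity offsets on every
detail channel (high-pass stages annihilate constants). A histogram
estimator (default 256 bins over the subband's value range) is available
as an alternative for users who want greylevel-style probabilities; the
two give different absolute feature values but the same pipeline
structure. An all-zero subband gets the degenerate distribution and hence
entropy 0: a constant block carries no texture information, and the
convention avoids 0/0.

Entropy conventions: standalone Shannon entropy is reported in bits
(base-2 log). The Tsallis entropy at q = 1 takes the analytic limit,
which is Shannon entropy in *natural-log* units; the q = 1 column of any
q grid therefore uses nats, keeping the feature family continuous in q
(tested at q = 1 ± 1e-6). Images are scaled to [0, 1] by their integer
bit depth before decomposition so 8- and 16-bit encodings of the same
image give identical features.

The entropic index q shapes sensitivity to the tail of the coefficient
distribution: q < 1 (sub-extensive) amplifies rare high-energy
coefficients — lesion-induced texture — while q > 1 suppresses them. The
default q = 0.8 is the pipeline's standard operating point; the grid
search (`grid_search_q`, default grid 0.1…1.0 in steps of 0.1, ties to
the smaller q) re-derives a data-specific optimum and shares one
decomposition per image across the grid since only the entropy step
depends on q.

## Fuzzy SVM

Memberships use the radius/centre rule: with class mean x_c and radius
r_c = max distance of a class member to its mean,
s = 1 − |x − x_c|/(r_c + δ). On training data this is positive by
construction; query points beyond the training radius (possible only
outside training) are clamped to a 1e-6 floor. δ defaults to
1e-3 · max(r₊, r₋) with an absolute fallback of 1e-3 when both radii
vanish; it only needs to keep the most distant point's membership
positive. A consequence worth knowing: the radius-defining sample of each
class always receives s ≈ δ/(r+δ) ≈ 1e-3, i.e. the fuzzy machine
effectively sacrifices the most eccentric training point per class. On
very small classes this can cost a training point's correct
classification; it is the intended behaviour of the rule, not a defect.
Memberships are computed in feature space, on training folds only.

The dual

    max_α Σα_n − ½ ΣΣ α_m α_n y_m y_n k(x_m, x_n)
    s.t. 0 ≤ α_n ≤ s_n C,  Σ α_n y_n = 0

is solved by sequential minimal optimisation. The first working-set index
is the maximal KKT violator; the second is chosen by the second-order
rule (maximal guaranteed objective decrease), which converges far faster
than the maximal-violating-pair rule on ill-conditioned Gram matrices.
The per-sample upper bounds s_n·C enter only in the clipping step of the
two-variable update. Stopping: KKT violation below 1e-8 *relative to the
scale C_max · max_n K_nn* — the dual gradient grows linearly with that
product, and on entropy-scale features (K_nn ≈ 2·10³) an absolute 1e-8
test sits below attainable double precision. Iteration budget 10⁵;
exceeding it raises an error carrying the residual violation. Iteration
counts grow roughly linearly with C; fits at C ≤ 10³ on ≤ 200 samples
take milliseconds to a fraction of a second.

The bias b is the mean of y_n − Σ_m α_m y_m K(x_m, x_n) over free support
vectors (0 < α_n < s_nC); when no multiplier is free it is the midpoint
of the KKT-feasible interval. A decision value of exactly 0 predicts +1
(pathological) — for a screening task the tie goes to the costly class.
Kernels: RBF (default, γ = 1/(p·var X) unless given), linear, polynomial.
Default C = 10. With all s_n = 1 the solver reproduces the plain SVM
exactly (tested to 1e-6 in α, b and decision values), and on problems
with n ≤ 8 the dual optimum matches a generic QP solver to 1e-6.

## Evaluation protocol

`stratified_kfold` shuffles each class with the given seed and deals
round-robin, so per-class counts across folds differ by at most one and
are exact when the class size divides K (e.g. 18 healthy + 48
pathological at K = 6 gives 3 + 8 per fold). A class smaller than K
triggers a warning and best-effort allocation rather than an error.

`run_cv` repeats K-fold CV R times with folds reshuffled per run
(seed + run). Within a run the confusion counts of the K test folds are
pooled, then percentages are averaged across runs — pooling first is the
lowest-variance aggregation when folds are small. Everything fitted from
data (memberships, optional z-scoring, nested C selection) is fitted on
the K−1 training folds only; the suite verifies this by spying on the
fitting calls. Metrics with zero denominators are reported as missing,
never as 0. Feature z-scoring is off by default — the entropy features
share a common scale — and can be enabled when kernels sensitive to
per-coordinate scale are used.

C selection is nested by default (inner CV inside each training
partition, most-frequently-chosen candidate wins, ties to the smallest
C) to avoid optimistic bias; an `outer` mode (one full CV per candidate,
argmax of mean accuracy) is available as the simpler convention.

## The phantom generator

`generate_phantom` draws an elliptical brain with a radial intensity
falloff, a brighter cortical rim, two ventricle-like dark ellipses with
per-subject jitter, and lightly smoothed Gaussian tissue texture
(sd 0.03). Pathological phantoms add 3–5 lesions: harmonically perturbed
ellipses (radius 3.5–9 % of image side) with ±0.25 intensity contrast,
soft edges, and locally raised texture variance (sd 0.08). Defaults
produce 66 images at 256×256 with an 18:48 healthy:pathological split,
mirroring a small imbalanced screening set; everything is deterministic
given the seed, down to byte-identical PNGs.

The multifocal default (3–5 lesions) reflects the disease spectrum such
sets represent — multiple sclerosis, metastases, toxoplasmosis are
multifocal — and makes the class signal robust across generator seeds;
solitary small lesions produce images whose texture signature genuinely
overlaps the healthy class and are deliberately not part of the default
conditions.

Three named presets define the study conditions:

- **easy** — the defaults above; the separable condition under which the
  pipeline is expected to reach ≥ 95 % mean accuracy.
- **null** — lesion intensity and lesion texture set to 0: the two class
  generators are statistically identical, so any honest pipeline must
  score at the majority-class rate (72.7 %) within binomial error. This
  guards against information leaking through the protocol.
- **outlier** — easy images with 8 % of labels flipped after generation
  (the images keep their true appearance; the labels lie). This is the
  robustness condition: mislabeled points sit far from their recorded
  class's mean in feature space, receive low memberships, and are
  disarmed by the fuzzy machine.

The robustness comparison is run with a linear kernel at C = 100: an RBF
machine isolates mislabeled points in small local islands and barely
moves its global boundary, so fuzzy and plain machines tie there; the
large-C linear machine is the classic regime where label noise drags the
max-margin hyperplane, and it is where the membership weighting shows its
effect. Accuracy is scored against the recorded (noisy) labels, which
penalises both machines identically on flipped test samples and caps
attainable accuracy at ~92 %; the comparison between the machines is
unaffected.

The phantom is a texture phantom, not an MR simulator: no bias field, no
partial-volume or k-space effects, no anatomical variety beyond ellipse
jitter, and lesion/background contrast is the only class signal. Passing
the synthetic studies therefore shows that the pipeline detects localized
texture anomalies under class imbalance and label noise — not that it
reaches any particular accuracy on clinical MR data.

## Known limitations

- Features are translation-sensitive (the decimated transform is not
  shift-invariant); a one-pixel shift measurably changes the vector. The
  packet tree mitigates but does not remove this.
- The membership rule is isotropic in feature space and contaminated-mean
  sensitive: heavy label noise inflates class radii and flattens the
  membership profile.
- The SMO solver targets the small-n regime of this application (tens to
  hundreds of samples); it precomputes the full Gram matrix and is not
  intended for large training sets.
- Binary classification only; no probability calibration, no multi-class
  extension, no DICOM/NIfTI ingestion (convert to PNG/TIFF first).
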