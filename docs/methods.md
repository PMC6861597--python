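# Methods

## The model

`segae` segments brain tissues and white-matter hyperintensities (WMHs) from
co-registered, skull-stripped multi-sequence MRI (FLAIR, T1-w, T2-w,
optionally PD-w) without any manual labels.  The central assumption is a
linear unmixing model: each observed channel is approximately a non-negative
weighted sum of the soft segmentations of the M materials present in the
images,

    Y_c = sum_i  w_{i,c} * S_i ,      w_{i,c} >= 0,
    S_i >= 0,  sum_i S_i = B          (B = binary brain mask),

where `S_i` is the soft (per-voxel fractional) segmentation of material `i`
(WMH, WM, GM, CSF, optionally meninges) and `w_{i,c}` its intensity in
channel `c`.  A three-scale fully-convolutional encoder-decoder estimates
`S` through a Softmax head (which enforces non-negativity and sum-to-one);
the brain mask, obtained by binarizing the input patch (any channel
non-zero), is applied after the Softmax.  A final 1x1x1 convolution with
non-negative weights and no bias implements the weighted sum, so training to
reconstruct the inputs forces the Softmax maps toward a material
decomposition.  After training only `S` is kept; the reconstruction is
discarded.

### Loss

Reconstruction quality is measured per channel by cosine proximity

    f(y, yhat) = y . yhat / (max(||y||, eps) * max(||yhat||, eps)),

summed over the raw channel and its response to the 3D discrete Laplacian
(6-neighbor stencil, zero padding):

    L(Y, Yhat) = -(1/C) * sum_c [ f(Y_c, Yhat_c) + f(K*Y_c, K*Yhat_c) ].

Cosine proximity makes the objective invariant to per-channel intensity
scale — the mixing weights absorb the scale — and the Laplacian term, which
annihilates constant and affine trends, makes it robust to slowly varying
intensity inhomogeneity.  Because C < M the decomposition is ill-posed, so
an activity regularizer penalizes overlap between material maps:

    Omega(S) = (alpha / M) * sum_{i,j} f(vec(S_i), vec(S_j)),

written exactly as stated, including the M diagonal terms (gradient-free
constants equal to 1 for non-empty maps).  `alpha` trades reconstruction
against separation; the calibration rule is the method's own: increase it
when materials mix, decrease it when segmentations become too coarse.

### Numerical choices

- `eps = 1e-8` floors the norms in the cosine so all-zero vectors (empty
  materials, all-background patches) yield 0 rather than NaN.
- The Laplacian uses zero padding, consistent with the zero background of
  skull-stripped images; identities (annihilation of constants and ramps)
  hold at interior voxels.
- The binarization threshold for lesion masks is strict (`S > t`).
- Connected components default to 26-connectivity, shared between
  post-processing and the lesion-wise metrics so counting is coherent.
- Percentiles (intensity normalization, H95) use numpy's linear
  interpolation between order statistics.

## Architecture and initialization

Each scale applies two blocks of conv(3x3x3) -> LReLU(slope 0.1) ->
batch-norm; downsampling is a 2x2x2 strided convolution, upsampling is 2x
nearest-neighbor followed by a 3x3x3 convolution (avoiding checkerboard
artifacts), and encoder activations are concatenated into the decoder at
matching resolution.  Filters double per scale from `base_filters`
(default 16; the tests and phantom studies use 8).  Convolution weights are
Glorot-uniform; batch-norm uses per-batch statistics during training (the
batch is a single patch, so statistics are spatial) and running averages at
inference.

The network and its training loop are implemented on a small reverse-mode
autodiff engine over numpy (`segae.autograd`) written for exactly the
operation set this architecture needs; its operators are verified against
scipy reference convolutions and central finite differences in the test
suite.

**Mixing-layer initialization.** The mixing weights move slowly under
Adam-style updates (each step changes a weight by about the learning rate),
so at desk-scale step budgets a random start leaves them far from any
useful unmixing.  By default the mixing layer is therefore initialized from
the data with endmember extraction, the standard practice in linear
spectral unmixing: brain-voxel intensity vectors are over-clustered with
k-means++ (k well above M, so rare materials such as lesions get their own
centroid), the M centroids spanning the largest simplex are selected
(N-FINDR style — partial-volume clusters lie inside the simplex and are
skipped), and each selected spectrum is refined by averaging the voxels
whose non-negative least-squares abundances are dominated by it.  Random
initialization remains available (`mixing_init="keep"`).

**Freeze-then-fine-tune schedule.** At short step budgets, jointly training
S and w admits a degenerate attractor the activity regularizer cannot
penalize: two material rows drift onto one spectrum and split a region
spatially (disjoint supports cost nothing in the pairwise-overlap penalty,
and reconstruction is indifferent to how a region is split among identical
spectra).  The phantom-study protocol therefore keeps the mixing layer
frozen at its endmember initialization for the first three quarters of the
epochs — fixed-endmember abundance estimation, under which the per-voxel
unmixing is well-posed and distinct materials cannot merge — and trains
jointly for the remaining quarter so the weights settle under the
scale-invariant loss (`mixing_freeze_epochs`; the full-scale default is 0,
matching the original joint protocol whose much larger step budget does
not need the anchor).

A masked variant of batch normalization (statistics over brain voxels
only, `masked_norm`) is available but off by default: on the phantom
studies it degraded recovery.

## Optimization

Adam with Nesterov momentum (the Nadam variant with a momentum schedule):
learning rate 0.001, beta1 0.9, beta2 0.999, schedule decay 0.004, batch
size 1, 80 epochs.  The update, following the Keras formulation these
defaults come from, is

    mu_t     = beta1 * (1 - 0.5 * 0.96^(t * psi))
    m_t      = beta1 * m_{t-1} + (1 - beta1) * g_t
    v_t      = beta2 * v_{t-1} + (1 - beta2) * g_t^2
    m_hat    = mu_{t+1} * m_t / (1 - prod_{i<=t+1} mu_i)
               + (1 - mu_t) * g_t / (1 - prod_{i<=t} mu_i)
    v_hat    = v_t / (1 - beta2^t)
    theta   -= lr * m_hat / (sqrt(v_hat) + eps)

with psi the schedule decay.  After every step the mixing weights are
clipped at zero (projected gradient); projection was chosen over softplus or
squaring reparameterizations because it keeps the weights directly
interpretable as material intensities.

Training augmentation follows the stated protocol: i.i.d. Gaussian noise
(sd 0.05) is added to the input patch, then each channel is multiplied by a
scalar drawn from N(1, 0.5), not truncated.  Augmentation applies to the
network input only; the reconstruction target stays clean, and the patch
brainmask is computed from the clean input so background voxels remain
masked despite the added noise.  Patch order is reshuffled every epoch with
a seeded generator; one epoch is one pass over the selected patches.

## Integrated bias correction

MR inhomogeneity is modelled as a smooth strictly-positive multiplicative
field per channel.  Correcting lesion-rich FLAIR images naively flattens
lesion contrast, so correction and segmentation alternate: the current
model segments the volumes; the pure-tissue probability mask CSF+GM+WM
(equivalently `1 - S_WMH - S_MENINGES` under sum-to-one) downweights lesion
and meninges voxels, and is further restricted to near-pure voxels
(`max_i S_i > 0.9`) because partial-volume voxels carry the largest
reconstruction error; one field per channel is estimated under that
weighting; the *targets* are corrected while the *inputs* stay original;
and training continues on the corrected targets.  The final model therefore
segments uncorrected images directly.  Default is `n_rounds = 2` (one
correction pass).

Retraining after correction warm-starts from the previous round's network
by default.  A fresh re-initialization would run a new non-convex fit whose
outcome varies with the restart, drowning the (small, consistent) benefit
of cleaner targets in basin-to-basin variation; continuing from the
current network makes consecutive rounds directly comparable.  A fresh
restart per round remains available (`warm_start=False`).

The default field estimator is a weighted log-domain smooth-field fit
rather than a wrapper around an external tool: the log-ratio of the
observed volume to a reference estimate of the bias-free image (the model's
own linear reconstruction `W^T S`, which the scale-invariant loss makes
robust to smooth fields) is smoothed under the weights, re-centered,
exponentiated, and normalized to weighted mean 1.  The `smoothness`
parameter (default 12 voxels) is the expected correlation length of the
artifact; the internal smoothing kernel uses a third of it, since smoothing
at the artifact's own scale would attenuate the field being estimated, and
the fit runs twice, re-estimating the residual of the corrected volume
(one smoothing pass recovers only part of the field — the same reason
practical correction algorithms iterate).  Any external estimator with the
same signature can be plugged in via the `estimator` argument.

## Preprocessing and inference

Volumes are normalized by the 99th percentile of their non-zero voxels
(per channel, per volume), optionally PD-enhanced
(`I_orig * (max(I_PD) - I_PD)`), cropped to the smallest cuboid containing
the brain, and cut into patches on a regular stride grid whose last origin
is clamped to the boundary so no voxel is unsampled (stride <= patch size).
Volumes smaller than the patch are symmetrically zero-padded.  Half of the
patches — those with the fewest all-channel-zero voxels — are kept for
training, ties broken by origin order for determinism.  Prediction slides
the network over the same clamped grid, averages overlapping Softmax
outputs, re-applies the brain mask and renormalizes to sum-to-one (overlap
averaging can disturb the constraint slightly at patch seams).  The lesion
map is binarized with a strict threshold (default 0.5) and components
smaller than 3 voxels are removed (a 3-voxel component is kept).

## The phantom generator

Every component is testable without data downloads through a synthetic
phantom that realizes the generative model exactly: nested ellipsoids give
a CSF core, WM interior, GM shell and optionally a thin meninges rim, with
smoothed random lesion blobs inside WM; one-hot maps are Gaussian-blurred
(sigma 1 voxel, emulating partial volume) and renormalized so they sum
exactly to the brain mask.  Compartment volumes approximate an elderly
brain with enlarged ventricles (roughly 9% CSF, 40% WM, 50% GM of the
intracranial volume) — material abundances matter for unmixing, because a
material with negligible volume contributes negligibly to a cosine
objective.  Channels are synthesized as `bias * (W^T S) + noise` with a
default mixing matrix whose signatures mimic FLAIR (lesion-bright,
CSF-dark), T1 (WM-bright) and T2 (CSF-bright); any three rows of the
default matrix are linearly independent, so every 3-channel subset is
identifiable.  Bias fields are `exp(g)` with `g` smoothed Gaussian noise
rescaled to a chosen amplitude and mean-normalized over the mask.  Noise is
additive Gaussian before clipping at zero (not Rician) to keep a
closed-form noise model.

What the phantom does *not* emulate: anatomical geometry, MRI physics
(TR/TE/TI), Rician noise statistics, motion or flow artifacts, and the
empirical distribution of real WMH shapes and loads.  Passing phantom tests
demonstrates that the estimator recovers the generative structure it
assumes — mixture weights, material supports, bias fields — not that it
reaches any particular accuracy on clinical data.

## Desk-scale study conditions

The phantom studies run on 48^3 volumes with C=3 channels and M=4 materials
(CSF, GM, WM, WMH), `base_filters = 8`, 24^3 training patches on a stride-8
grid (50% selected, about 32 patches per epoch), 60 epochs with the mixing
layer frozen for the first 45 — sizes chosen so the full suite runs on a
single CPU.  Under these conditions the matched mean material Dice is
0.96-0.97 across optimization seeds.  The bias-correction study uses a
sparser stride-12 grid and 40 epochs per round.  The full-scale profile of
the original protocol (80x80x80 patches, stride 40, base_filters 16, M=5)
is expressible through the same configuration surface but is not exercised
by the tests.

## Known limitations

- With C=3 and M=4 the unmixing is ill-posed by construction; recovery
  depends on the activity regularizer and is stochastic in the optimization
  seed.  The weakest-contrast material is the most fragile.
- Batch-norm statistics at inference come from running averages collected
  over training patches; strong distribution shift between patch sizes can
  move the Softmax outputs slightly.
- The internal bias estimator assumes the artifact's correlation length is
  given approximately; it is not an N4 reimplementation.
- Role assignment on phantoms uses mixing-weight signatures; on real data
  roles are user-assigned in the configuration.
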