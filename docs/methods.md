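# Methods

## The model

`adfuse` classifies subjects as Alzheimer's disease (AD) or cognitively
normal (CN) from a pair of co-registered 3D brain volumes — a structural MRI
(sMRI) channel quantifying atrophy and an FDG-PET channel quantifying glucose
metabolism — both preprocessed upstream to a common grid (canonically
64×64×64) and min–max normalized to [0, 1] per volume:

    z = (x − min x) / (max x − min x)

A pooled-per-subject normalization (one min/max over both modalities) is
available through `normalize_subject(..., pooled=True)`; per-modality is the
default.

**Encoders.** Each modality has its own 3D CNN: five blocks of
(3×3×3 conv, stride 1, same padding → batch norm → ReLU → 2×2×2 max pool)
with channel schedule 15, 30, 60, 120, 160, followed by one standalone
3×3×3 conv to 200 channels (BN + ReLU, no pooling). On a 64³ input this
yields 200 feature maps of extent 2×2×2. The two encoders share architecture
but not parameters. Only the first block's width (15) is canonical; the rest
of the schedule is a conventional doubling-style choice and fully
configurable. Convolution stride is configurable but defaults to 1, because
five stride-2 convolutions combined with five poolings could not produce the
200×2×2×2 output geometry that the rest of the pipeline (token count,
rollout dimension) depends on.

**Tokens and the gated Transformer.** Each feature map is one token; its
eight voxels, flattened, are the embedding (N = 200, d = 8). Two pre-norm
encoder blocks with four heads process the tokens; one Transformer serves
both modality streams. Q/K/V are produced per head by 1×1×1 convolutions
over the channel axis — per-voxel linear mixing of the N token rows by an
N×N matrix — and each head keeps its d/H = 2-wide slice of the mixed,
flattened tokens. No positional embedding is added; the convolutional
stack itself is position-aware. Attention is the standard
softmax(QKᵀ/√d)V with d the per-head key dimension (2); using the full
token dimension instead is a config switch (`scale_dim="token"`).

The attention residual is gated:

    X′ = α·MSA(LN(X)) + X,    α ∈ [0, 1], α = 0 at initialization

with one learnable scalar α per block, projected back into [0, 1] after
every optimizer step. Attention is therefore masked at the start of training
— the CNNs learn local features first — and enters progressively as the gate
opens. The FFN sub-block (d → 4d → d, ReLU) keeps a plain ungated residual.
Because Adam moves a scalar by at most ≈ lr per step, a gate trained at the
base rate of 1e-4 could never cross ~0.1 within a 60-epoch run, let alone
approach 1; the gate therefore carries a learning-rate multiplier (default
100×), which makes a near-saturated gate reachable within the standard
schedule. The multiplier is a package design choice, exposed as
`gate_lr_mult`.

**Fusion head.** The transformed tokens of both modalities are flattened and
concatenated (2 × 200 × 8 = 3200) and classified by a two-layer MLP
(hidden width 256 — unconstrained by the protocol, chosen conventionally)
with dropout 0.1 after each linear layer and a softmax output. Loss is
categorical cross-entropy. Ablations: `typical_transformer` (linear Q/K/V,
learned positional embedding, ungated α ≡ 1) and `cnn_only` (encoder
features straight to the MLP; no attention recorded).

## Training and evaluation protocol

Adam (default moments), lr 1e-4 decayed ×0.1 every 20 epochs, batch size 11,
60 epochs, fixed RNG seed. Cross-validation stratifies subjects into 10
near-equal portions (remainders dealt round-robin with a carrying pointer,
so 210 subjects give ten portions of exactly 21); loop i uses portion i as
test, portion i+1 as validation, the rest (168) as training. The validation
set only monitors training and selects the best-epoch checkpoint (ties go to
the latest epoch); there is no early stopping. Metrics per fold, in percent:
ACC, PRE, SPE, SEN, F1S (harmonic mean of PRE and SEN) and AUC from the
positive-class (AD) probability; summaries are fold-level mean ± sd.
Metrics undefined on a degenerate fold are reported as NaN, never silently 0.

Significance uses a label-permutation test: training labels are permuted
(1000× at protocol scale; configurable, ≤ 20 in the test harness),
the model is retrained per replicate, and test accuracy on untouched labels
gives p = (1 + #{permuted ≥ observed}) / (1 + n_perm).

## Interpretability

Per-layer attention matrices are head-averaged, augmented with the residual
path as A = 0.5·W + 0.5·I (the 0.5 reflecting a late-training gate near 1),
and multiplied through the layers (attention rollout):
Ã(lᵢ) = A(lᵢ)·Ã(lᵢ₋₁). Row-stochasticity is preserved at every step. The
feature-contribution vector is wⱼ = ½(column-mean j + row-mean j) of Ã,
averaged over evaluation subjects (optionally only correctly classified
ones); ties in the argmax resolve to the lowest index.

The selected feature is decoded to image space by a deconvolution network
mirroring the encoder: one conv undoing the standalone conv, then
(nearest-neighbour ×2 upsample → 3×3×3 conv) per encoder block, trained to
reconstruct input volumes under MSE with the encoder frozen (protocol: batch
20, 3000 epochs, lr 1e-4 halved every 500 epochs). Two decoder design
choices matter and are deliberate:

* **Linearity.** By default the decoder has no BN/ReLU and no biases, so the
  decoded volume is an exact sum of per-channel contributions and decoding a
  single zero-masked channel isolates that channel's additive contribution.
  A conventional nonlinear decoder (`linear=False`) is available, but
  zero-masked inputs lie far off its training manifold and its single-channel
  decodes are dominated by artefact.
* **Feature-specific training.** A decoder trained on the full feature set
  splits reconstruction credit among correlated channels in a way that is
  not identified — any mixing of correlated channels leaves the training
  loss unchanged — so a single channel's contribution map carries little
  spatial meaning. `train_deconv(..., feature_index=j)` masks the non-selected
  channels during training as well, making the decoder the best
  reconstruction of the image from feature j alone (a marginal regression),
  which is the quantity the salience analysis actually interprets. An
  optional region-of-interest mask restricts the reconstruction loss (and
  the percentile threshold) to the brain support.

Salience for group comparison is the contrast of class-mean decoded volumes
(CN − AD, `salience_contrast`); with a linear decoder this is the decoded
feature's contribution to the between-group intensity difference, with the
shared anatomical background cancelled. Cluster reporting keeps voxels at or
above the (100 − p)th percentile (default top 1%), labels connected
components (26-connectivity by default, 6 available), drops components not
exceeding the size threshold (default > 100 voxels; a first-class parameter,
scaled down for small grids), and reports peak voxel, peak mm coordinate via
the affine, raw peak intensity, and voxel count, sorted by size. Anatomical
labelling of clusters is out of scope; the mm coordinates are the extension
point for a user-supplied atlas lookup.

### Known limitation: localization resolution

The decoder upsamples from the 2×2×2 token lattice with shared
(translation-invariant) convolution weights, so any decoded bump is
accompanied by translated copies at the lattice spacing (total upsampling
factor; 16 voxels on a 32³ grid). In the scaled synthetic study below, the
planted lesion is reliably recovered as a reported cluster whose peak lies
inside the planted sphere, but the single largest cluster can be such a
translated-copy artefact rather than the lesion itself. At this token
geometry that is a structural property of single-feature deconvolution
decoding, not a training artefact: it persists with converged decoders,
sparsity regularization, masked losses, and variance-standardized contrasts.
The corresponding acceptance check on the largest cluster is expected to
fail for this reason, while the containment check passes.

## Synthetic cohorts

`generate_cohort` emulates the study data: per subject, a smooth ellipsoidal
brain support (axis radii 0.40/0.34/0.38 of the grid, edge smoothed with a
~grid/32-voxel Gaussian), scaled by a per-subject global intensity jitter
(sd 0.1, a global-scaling stand-in for acquisition variability), modality
base levels 0.85 (sMRI) and 0.70 (PET), independent voxel noise per modality
(sd 0.1 by default), min–max normalized. AD subjects get a multiplicative
intensity reduction (default 30%) inside a sphere — radius grid/6, centred
at a medial, slightly anterior–inferior offset, a medial-temporal analogue —
with a 1-voxel Gaussian boundary falloff, applied to both modalities
(atrophy and hypometabolism co-localized). Defaults mirror the study
population: 88 AD and 122 CN subjects on a 64³ grid. Cohorts are pure
functions of the seed.

What the generator does **not** emulate: real anatomy and tissue classes,
registration error, scanner/site effects, partial-volume and smoothing
artefacts, age/sex structure, or AD heterogeneity (multiple lesion sites,
graded severity). Passing tests on these cohorts demonstrate that the
pipeline's machinery — optimization, cross-validation bookkeeping, gating,
rollout, decoding, clustering — behaves as specified on a controlled signal;
they say nothing about classification accuracy on clinical data.

## Scaled problem sizes used by the test harness

The reference protocol (210 subjects at 64³, tenfold CV, 60 epochs, 1000
permutations, 3000-epoch decoders) is far beyond a single-CPU test run, so
the harness exercises reduced-but-structurally-identical problems, chosen
once as the package's own test conditions:

* learning/localization: 60 subjects at 32³ (effect 0.5, noise 0.05),
  encoder 8/16/32/64 + final 64, 15 epochs, 36/24 train/held split;
  decoders train 80 epochs at lr 1e-3 on 16 class-balanced volumes;
* permutation significance: 40 subjects at 16³ (lesion radius 4, so the
  signal stays resolvable at this grid), 25 epochs, 19 permutations;
  null calibration: 10 cohorts of 20 subjects, 3 epochs, 9 permutations;
* determinism and unit checks: 20 subjects at 16³, 2–25 epochs.

## Numerical choices

* Compute backend: a tape-based reverse-mode autodiff engine over NumPy
  (`adfuse._tensor`), with 3D convolution as one GEMM per kernel offset
  (peak memory stays at a few input copies), argmax-routed max-pool
  gradients, and a fused softmax cross-entropy. All ops are verified against
  central finite differences in the test suite.
* float32 throughout; attention row sums hold to 1e-5, block forwards match
  straight-line float64 oracles to 1e-5.
* Min–max normalization of a constant volume raises a degenerate-input error
  rather than producing NaNs; cross-entropy floors probabilities at the
  smallest positive float32.
* Batch-norm running statistics use momentum 0.1; eval mode uses running
  moments, so inference is per-sample pure and batch-order invariant.
* Down-sampling is block-mean (exact for integer factors); requests that
  would upsample raise.
* Tie-breaks: argmax ties (feature weights, predicted class) resolve to the
  lowest index; best-epoch ties resolve to the latest epoch.
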