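# Methods

`gliotype` implements a dual-path attention network that predicts three
binary molecular markers of glioma — IDH mutation, ATRX mutation and 1p/19q
codeletion — from co-registered, skull-stripped multi-modal brain MRI
(T1, T1-ce, T2, FLAIR), together with a synthetic phantom generator that
makes the whole pipeline trainable and testable on a laptop CPU with no
external data.

## Model

**Front end (dual path).** Two parallel 3-D convolutional paths process
(a) the full 4-modality stack and (b) the T2+FLAIR pair only.  The second
path exists because the T2–FLAIR *mismatch sign* — a lesion uniformly bright
on T2 with a FLAIR-bright rim around a FLAIR-dark core — is a known imaging
marker of IDH-mutant glioma, and a dedicated path lets the network learn it
without dilution by the other modalities.  Each path is a 3×3×3 stem (16
channels at full width) followed by three stages of [stride-2 conv
(channels ×2) → two pre-activation residual blocks].  After the stems, a
single low-level exchange concatenates the two 16-channel maps, convolves
back to 16 channels, and adds the fused map residually into both paths.
A 128³ input yields two 128-channel 16³ maps, F3 and F4.  The mid-network
enhancement concatenates them (F5, 256 ch), reduces with a 1×1×1 conv
(F6, 128 ch) and re-injects residually: F7 = F6 + F3 and F8 = F6 + F4.

**High-order branches.** F7 feeds a 3-D vision transformer: a 3×3×3 conv
lifts 128 → 512 channels, each spatial position of the 16³ map becomes one
of 4096 tokens of width 512 (patch size is configurable; the default of 1
follows from projecting a low-resolution map at stride 1), learnable
position embeddings are added, and four pre-norm transformer layers
(8 heads, scaled dot-product attention QKᵀ/√d, 4× MLP, residual around each
sub-block) refine the sequence.  No class token is used; the head pools
tokens instead.  F8 feeds the residual dual-attention tail: two strided
stages (128→256→512 channels) of residual blocks whose convolutional branch
is gated first per channel — σ(MLP(avgpool) + MLP(maxpool)) with a shared
bottleneck MLP (reduction 16) — and then per voxel — σ(7×7×7 conv over the
channel-wise mean and max maps) — before the residual addition.

**Inter-gene head.** Global average and max pooling (parameter-free)
summarize three scales: F6 (128 ch), the dual-attention intermediate
(256 ch) and the average of the pooled final transformer and dual-attention
features (512 ch), giving a 2×(128+256+512) = 1792-dim vector.  IDH and
ATRX each get an independent FC stack 1792→1280→512→32→2 with softmax.  The
1p/19q stack runs to its 32-unit penultimate layer, then concatenates two
scalars — max(P_idh) and max(P_atrx), i.e. the *confidence* of the other
two heads, in [0.5, 1] — before the final linear layer.  This encodes the
clinical dependency structure (IDH-wild-type and ATRX-mutant tumors are
essentially never 1p/19q-codeleted) as a learned conditioning, and the
1p/19q loss back-propagates through the confidences into the IDH/ATRX
heads.  Gradients are deliberately not stopped at the confidence scalars.
Note the scalars carry confidence, not class identity; most of the coupling
therefore acts through the shared features and the gradient path.

## Losses

Per gene the objective is the LMF loss, L = α·L_LDAM + β·L_FL (α = β = 0.5
by default):

* Focal: −α_t (1−p_t)^γ log p_t with γ = 2 and inverse-frequency class
  weights α_t by default; p_t is clamped at 1e-12 before the log.
* LDAM: softmax cross-entropy with the target logit reduced by a per-class
  margin m_j ∝ n_j^(−1/4), scaled so the largest margin equals m (0.5 by
  default) and floored at δ (0 by default).  No logit-scale factor is
  applied, so for equal binary logits with margin m on the target the loss
  is exactly ln(1+e^m).  Class counts come from the training split only and
  are serialized with the checkpoint.

The three gene losses are combined by learnable homoscedastic-uncertainty
weighting, L = Σ_g L_g/(3σ_g²) + log(σ_idh σ_1p19q σ_atrx), with σ
parameterized on the log scale (so positivity is structural) and
initialized to 5.0 (IDH), 6.0 (1p/19q), 6.0 (ATRX).  For frozen sub-losses
the per-task stationary point is σ_g = √(2 L_g/3); the suite verifies
gradient descent recovers it to 1e-3.  At initialization with zero
sub-losses the objective equals ln 180 ≈ 5.1930.

## Preprocessing

Per modality and subject, volumes are z-scored over nonzero (brain) voxels
only; background stays exactly 0.  Missing modalities are zero-filled
*after* normalization, so absent channels are identically zero.  T2 and
FLAIR are required (the second path consumes them); T1/T1-ce may be absent.
Training uses random 128³ crops (uniform over valid offsets; shorter axes
are symmetrically zero-padded first) and independent per-axis flips with
p = 0.5.  Validation and test use a deterministic center crop.

## Training recipe

Adam, lr 1e-4, weight decay 1e-5, batch size 2, up to 1000 epochs, constant
learning rate (none of the published recipe mentions a schedule); model
selection at the epoch of minimum validation loss, where validation loss is
the uncertainty-weighted objective with σ frozen at its current value.
Training is fully deterministic on CPU under a fixed seed.

A single `scale` multiplier shrinks channel widths, the token embedding,
the FC stack and the input resolution jointly; scale 1.0 is the full-size
architecture (128³ inputs, 16-channel stem, 512-dim tokens, 1792-dim pooled
vector), scale 1/8 (16³ inputs, 2-channel stem, 64-dim tokens) trains in
minutes on one CPU core.  Desk-scale experiments in the test suite use
lr 1e-3 and full-batch updates: at 1/8 width with eight-subject cohorts the
full-scale recipe (lr 1e-4, batch 2) is needlessly conservative, and the
width-scaled learning rate is the package's choice for those runs, made
when the experiments were designed.

## Numerical core

No GPU framework is used: the package carries a compact numpy-based
reverse-mode autodiff (`gliotype.nn`) whose op set is exactly what the
model needs.  3-D convolution is im2col + BLAS matmul, chunked along output
depth so the unfolded buffer stays under ~256 MB at 128³; backward passes
loop over the 27 kernel offsets.  Softmax and logsumexp clamp the shifted
exponent at −80 — mathematically negligible (e⁻⁸⁰ ≈ 1.8·10⁻³⁵ against a
max term of 1) but it keeps exp() out of subnormal range, which is orders
of magnitude slower on x86.  Python-scalar arithmetic takes a non-promoting
fast path so float32 inference stays float32.  Every op is verified against
central finite differences; attention, channel/spatial gates and pooling
are additionally checked against brute-force loop oracles at ≤5 tokens /
≤3³ voxels to 1e-6 (float64).  Full-scale shape checks run in float32; a
4×128³ forward pass takes ~1 minute on one CPU core within ~4 GB.

## Synthetic phantom cohorts

Each phantom is a centered "brain" ellipsoid (intensity 1, zero outside —
the skull-stripped convention) with one ellipsoidal lesion (three random
semi-axes) at a random interior position, plus Gaussian noise inside the
brain.  Genotypes condition the appearance:

| status | signature |
|---|---|
| IDH mutant | T2 core+rim uniformly 2.2; FLAIR rim 2.0, core 0.6 (mismatch) |
| IDH wild-type | T1-ce rim 2.4, core 0.5 (annular enhancement + necrosis); T2 heterogeneous (1.5/1.9) |
| ATRX mutant | edema halo probability and thickness both halved |
| 1p/19q codeleted | lesion contrast blurred (σ = 2 voxels): indistinct margins |

Intensities are arbitrary units — downstream z-scoring removes scale, so
only contrast ratios matter; the mismatch magnitude is a parameter, not a
claim about real tissue.  An edema halo (T2/FLAIR 1.5) of thickness 0.6
lesion radii appears with probability 0.85.  Genotype triples honor the
unidirectional dependency rules — wild-type IDH ⇒ non-codeleted, mutant
ATRX ⇒ non-codeleted — with a `rule_adherence` probability (1.0 enforces
them exactly); the codeletion rate is solved analytically so the requested
marginal is met, and infeasible combinations raise a configuration error.
Default class fractions are the clinical cohort's (IDH-mutant 33 %,
ATRX-mutant 20 %, codeleted 11 %) and the missing-modality mix matches the
clinical distribution (16.8 % full, 49.5 % lacking T1-ce, 33.7 % lacking
T1); T2 and FLAIR are never dropped.

What the phantoms deliberately do not model: MRI physics, bias fields,
multi-focal tumors, registration artifacts, real anatomical texture.
Passing tests therefore demonstrate that the implementation learns the
encoded contrast signatures and honors the label structure — not clinical
performance on real MRI.

## Validation experiments

* **Overfit sanity** — eight noise-free phantoms (all five rule-consistent
  genotype patterns represented), scale 1/8, full-batch lr 1e-3 without
  augmentation: training accuracy must reach 100 % on all three genes
  within 200 epochs.
* **Imbalance mitigation** — a 9:1 two-Gaussian linear task with *unequal*
  class covariances (majority elongated oblique to the class-mean axis,
  minority tight along it; with equal covariances every weighting learns
  the same direction and mitigation would be undetectable).  A 2-parameter
  linear model trained with LMF vs unweighted cross-entropy, n = 1000
  training points, sensitivity read at matched 0.9 specificity from the ROC
  on 10 000 held-out points: LMF must win in ≥ 8/10 seeded repeats.
* **Inter-gene paths** — paired runs (same cohort, same seed, only the
  1p/19q head wiring differs) on rule-consistent 24³ cohorts of 34
  subjects, 70 epochs: mean held-out 1p/19q sensitivity with the auxiliary
  paths enabled must not fall below the mean without them, over 5 seeds.
* **σ dynamics, loss closed forms, oracle equivalences, shape contract,
  determinism** — exact checks described above.

Problem sizes (24³ phantoms, 34-subject cohorts, 70 epochs, 1/8 scale) are
the package's desk-scale study conditions; they keep each experiment in the
minutes range on a single core.

## Known limitations

* The printed form of the LDAM loss in the source literature is not
  evaluable as written; the canonical margin-adjusted cross-entropy of the
  method it cites is implemented instead (margins ∝ n^(−1/4)).
* max(P) conditioning passes confidence, not class identity; the 1p/19q
  coupling is correspondingly weak and mostly mediated by shared features
  and gradients.
* The α, β, γ, m, δ loss hyperparameters are not stated in the source
  recipe; defaults (0.5, 0.5, 2, 0.5, 0) are exposed in the config.
* Instance norm (chosen for batch size 2) and ReLU are the package's
  choices where the architecture description is silent.
* Phantom realism is intentionally minimal (see above).
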