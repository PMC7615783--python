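# Methods

## The model

`csagp` implements a dual-branch vision transformer for paired 2-D
neuroimage slices (an "MRI-like" and a "PET-like" modality per subject)
with two mechanisms beyond a stock ViT:

1. **Cross-attention fusion (CAFM).** After each branch's own encoder
   stack, the class token of one branch attends over the *other* branch's
   patch tokens: with `x' = [cls ∥ patches_other]`, the query is built from
   the class token alone, keys and values from `x'`, and the attended class
   token re-enters its own sequence with a residual connection. Because
   there is a single query row per head, the attention map has `h·(N+1)`
   entries — linear rather than quadratic in the token count. The fusion is
   symmetric (one sub-block per direction) and both directions read the
   block-input sequences, so the module has no branch-order dependence.
   The FFN stage after recombination is applied literally as
   `LN(FFN(LN(z)) + z)` (inner pre-norm, outer norm on the residual sum);
   a `conventional_prenorm` switch restores the standard `z + FFN(LN(z))`
   form for comparison runs.

2. **Graph pooling (RPR: reshape–pooling–reshape).** Patch tokens are
   recast as a graph: `dist_ij` is the Euclidean distance between token
   vectors, the threshold `μ` is the mean over all `N²` entries of the
   distance matrix (zero diagonal included), and `A_ij = 1` iff
   `dist_ij < μ` (strict). Since `dist_ii = 0 < μ` whenever `μ > 0`, the
   adjacency carries self-loops by construction; if all tokens are
   identical (`μ = 0`) the adjacency falls back to the identity so every
   stage stays well-defined. Vertices are scored by
   - **SBLM** — `σ(Deg^{-1/2} A Deg^{-1/2} X w)`, a one-layer
     symmetric-normalized graph convolution (degrees of isolated vertices
     clamped to 1 before inversion);
   - **FBLM** — a per-vertex feature scorer: a 1-D convolution over the
     feature axis (one learned D-kernel → scalar), batch-normalized over
     vertices, sigmoid; the `mlp` variant replaces it with a two-layer
     perceptron (the FBLM\* ablation arm);
   - **SFLM** — `BN(Conv(s1 + s2))` with a kernel-size-1 convolution so
     the combined score stays permutation-equivariant; the `linear`
     variant is a learned weighted sum `α·s1 + β·s2` (SFLM\*). No final
     nonlinearity is applied before ranking.

   A multi-head graph-attention layer (GAT, 2 heads by default,
   head-averaged) fuses neighborhood features over the **full** graph
   before any vertex is dropped, so to-be-discarded vertices still
   contribute to their neighbors. The top `k = max(1, ⌊r·N⌋)` vertices by
   combined score survive (ties resolve to the lower original index;
   surviving indices are re-sorted ascending so raster order is stable),
   and `[cls ∥ X'] + PE` reassembles the sequence with a fresh learned
   positional encoding whose size is fixed by the deterministic schedule
   `len_{t+1} = max(1, ⌊r·(len_t − 1)⌋) + 1`.

Each of the K blocks runs: per-branch encoders (MRI depth `N_enc`, PET
depth `M` — the MRI branch is deeper, reflecting its higher information
content), CAFM, then RPR on each branch. The two terminal class tokens are
concatenated, layer-normalized and mapped to class logits (`head_mode:
dual` averages two per-branch linear heads instead). The tokenizer is a
three-convolution stem (7×7/stride 4/pad 3, then two 3×3/stride 2/pad 1,
each followed by ReLU; overall downsampling ×16) whose flattened grid
forms the patch tokens; a 224×224 slice yields 196 patches + 1 class
token.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `K` | 3 | fusion/pooling blocks |
| `M`, `N_enc` | 1, 3 | PET / MRI encoder depth per block |
| `r` | 0.5 | fraction of patch tokens kept per RPR stage |
| `D`, `h` | 192, 4 | embedding width, attention heads |
| `ffn_mult` | 4 | FFN expansion |
| `lr`, `weight_decay` | 1e-5, 5e-4 | reference Adam protocol (batch 128, 300 epochs) |

`D` and `h` are engineering choices (small-ViT conventions; the reference
description does not pin them); everything is configurable. The
desk-scale profile (`configs/desk.yaml`) uses D=32, h=2, K=2, 64×64
input, Adam lr 1e-3, batch 8, 20 epochs — at 40 training subjects a
1e-5 learning rate cannot move a freshly initialized model in 20 epochs,
so the desk profile raises it.

## Numerical core

No GPU tensor framework is used: the package carries a compact
reverse-mode autodiff engine over numpy float64 (`csagp.nn`) with exactly
the primitives the model needs (matmul with broadcasting, conv2d via
im2col with a col2im adjoint, softmax/log-softmax with detached max-shift,
exact-erf GELU, layer/batch norm, fancy-index gather with scatter-add
adjoint). Gradients of every primitive and of the composite layers are
unit-tested against central finite differences. Training processes one
sample at a time and averages gradients over the minibatch; batch
normalization inside RPR therefore runs over the *vertex* axis of one
image (running statistics are used in eval mode and for single-vertex
inputs). Hard top-k selection and the adjacency threshold are
non-differentiable by design; gradients flow through the surviving feature
rows and the GAT attention weights, as in standard hard top-k graph
pooling.

Weight initialization: truncated normal (std 0.02, clipped at 2σ) for
projections, positional encodings and class tokens; He-normal for the
convolutional stem; zero biases. All randomness derives from the config
seed; forward passes and training runs are bit-reproducible.

## Synthetic data: what it does and does not emulate

The generator (`csagp.synthetic`) emulates the *geometry* of paired axial
slices: a smooth elliptical "brain" background (Gaussian-blurred noise,
std 0.05, blur σ=8 px), class-dependent soft elliptical lesion offsets at
fixed class-specific loci (table in `LESION_TABLE`; total lesion mass
grows with class index so the signal is recoverable both locally and in
the image mean), and independent per-modality pixel noise (std 0.1).
`shared_fraction` controls how much of the class signal is common to both
modalities; at 0, each modality carries a disjoint half, making the
modalities strictly complementary. It does **not** model MR contrast
physics, FDG uptake, partial-volume effects, registration error or
scanner variation — passing tests show the mechanisms work and the model
can learn localized multimodal structure, not that clinical accuracy
would be reproduced.

Generator defaults (amplitude 1.0, noise 0.1, shared fraction 0.5) give a
task a two-feature linear oracle solves at ≥95% — strong signal. The
fusion-ablation experiments instead use amplitude 0.6, noise 0.15,
shared fraction 0: chosen so that the task is learnable at desk scale but
far from ceiling for either arm, which is the regime where a fusion
mechanism can show a measurable effect.

## Experiment sizes

Desk-scale experiments (tests and `scripts/acceptance.py`) train on 40
subjects (20 per class) for 16–20 epochs with the D=32/K=2/64×64
architecture and evaluate on 200 freshly generated subjects — the larger
fresh test set cuts the binomial noise of a 13-subject split tail.
The ablation comparison is paired by seed (same data and init seed for
both arms) and summarized by a sign count over seeds.

## Degenerate inputs and tie-breaks

- All tokens identical → `μ = 0` → identity adjacency fallback.
- Isolated vertices → degree clamped to 1 in the GCN normalization; in the
  GAT every vertex always attends at least to itself.
- Score ties in top-k → lower original index wins (deterministic).
- `r = 1` → identity pooling; `k` never falls below 1.
- Batch norm with a single vertex → running statistics.
- A class absent from an evaluation set → its sensitivity/AUC are reported
  as missing and excluded from macro averages, never silently zeroed.
- Binary metrics treat class 1 (the second label) as positive; multiclass
  metrics are macro one-vs-rest, and the report's `aggregation` field
  records the convention.

## Open design choices taken

- The two patch-embed stems are architecturally identical with independent
  weights per branch (`share_stem` ties them).
- The FFN nonlinearity is GELU (configurable to ReLU); the attention scale
  is `1/√(D/h)` (per-head key dimension).
- One CAFM sub-block per direction; heads in MCA are merged by
  concatenation plus output projection.
- The distance-threshold mean is over all `N²` entries including the zero
  diagonal (the off-diagonal alternative is noted in code but not used).
- Class tokens are read after the final RPR stage (the stream's terminal
  state).
- RPR is applied in every block by default (`rpr_blocks` restricts it).

## Known limitations

- Slice-based 2-D analysis only; no 3-D context.
- Single-image batch norm statistics differ from large-batch training;
  at reference scale a cross-image batch axis might behave differently.
- CPU-bound numpy training limits practical problem sizes to the desk
  profile; the reference profile (`configs/reference.yaml`) is provided for
  fidelity, not for local execution.
- No pretraining or transfer learning; no soft/differentiable top-k.
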