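# Methods

This note documents the modelling choices, parameters, and numerical
conventions behind `connfusion`, and what its synthetic benchmarks do and do
not establish.

## Problem setting

Each subject is a matrix `X ∈ R^{T×R}` of band-pass-filtered BOLD signals
averaged within `R` atlas parcels at `T` time points, with a binary
diagnostic label and an acquisition-site identifier. Two derived views are
modelled jointly: the raw series (temporal dynamics) and the Pearson
correlation matrix of its columns (static functional connectivity). The
strict upper triangle of the correlation matrix is flattened row-major —
`(0,1), (0,2), …, (1,2), …` — and this ordering is a package-wide contract:
the connectivity encoder, the simulator's edge set, and the interpretability
module all share one deterministic edge ↔ `(i,j)` mapping. The flattening
order of the triangle is a convention of this package, fixed once so that
edge attributions are unambiguous.

## Encoders

**Temporal encoder.** Per-time-point linear projection `R → d1`, additive
sinusoidal positional encoding (computed analytically per call, so any `T`
is accepted without re-instantiation), a learnable `[CLS]` token, and `L1`
post-LN Transformer blocks (multi-head self-attention, ReLU feed-forward,
residual connections, layer norm). `h1` is the final `[CLS]` state.
Full-scale defaults: `d1 = 512`, `L1 = 6`, 8 heads, feed-forward 2048,
dropout 0.1.

**Masked time-point pretext.** A per-batch ratio is drawn uniformly from
[0.25, 0.5]; that fraction of whole time-point rows is replaced, *before*
the input projection, by a learned `R`-dimensional mask token (zero-filling
available via `mask_token="zero"`). A single linear head `d1 → R` decodes
every non-`[CLS]` token; the MSE runs over masked rows only (all `R` ROI
values of each). Whole-row masking follows the reading that a percentage
of *time points* is masked; `mask_granularity="cell"` implements the
alternative reading (individual `(t, r)` cells at the midpoint ratio). The
lightest possible decoder is deliberate — reconstruction capacity is forced
into the encoder. A consequence worth knowing: the `[CLS]` token receives no
gradient from this pretext (only the shared blocks do), so pre-training
shapes `h1` indirectly. This is measurable: on synthetic cohorts a linear
probe on pre-trained `h1` is at chance for group membership while the
connectivity stream's probe is far above chance, and it is the main reason
the contrastive stage needs substantial optimisation before cross-stream
retrieval emerges (see *Known limitations*).

**Connectivity encoder.** The length-`D` vector is cut into patches of
`patch_len` elements (the final patch zero-padded; padding never enters any
loss), each patch linearly embedded to `d2`, positionally encoded
(sinusoidal, matching the temporal stream), and passed through `L2` blocks;
`h2` is the layer-normalised mean over patch outputs. Full-scale defaults:
`d2 = 256`, `L2 = 2`, 8 heads, feed-forward 512, `patch_len = 100` (exactly
199 patches at `D = 19,900`, no padding). The pretext masks
`round(0.15·D)` elements, zeroing them before embedding — zero is the
natural null correlation — and decodes each patch token with a linear
`d2 → patch_len` head. The two pretexts run as independent loops by
default (equivalent to the joint weighted objective when no parameters are
shared); `joint_pretrain_loss(l_roi, l_pcc, λ)` implements the combined
form for a single optimiser, λ defaulting to 1 (no reported value exists to
calibrate it against).

## Contrastive alignment

Each stream gets its own projection head — two linear layers with one ReLU,
hidden 256 and output 128 at full scale — because the streams' feature
dimensions differ and the two heads are reported separately in the
fine-tuning diagnostics; the output is L2-normalised with an epsilon guard.
InfoNCE with temperature 0.07 treats the same subject's two projections as
the positive pair and all in-batch connectivity projections (positive
included) as the candidate set; the symmetrised average of both retrieval
directions is the default (`direction="t2p"` recovers the one-directional
form). Closed forms used as test oracles: identical embeddings give exactly
`log N`; a single pair gives 0; two orthogonal pairs give
`log(1 + e^{−1/τ})` per anchor. Encoder freezing during this stage is a
four-way policy (freeze both / temporal only / connectivity only / none);
frozen modules are bit-identical after the stage, which tests verify by
content hash. An optional window-augmentation mode computes each view from
an independent random temporal window of the subject (the connectivity view
recomputed on its window — the standard dynamic-FC construction); it is off
by default, matching plain same-subject pairing.

## Fusion and classification

All five operators consume the stream features and their linear alignments
`h̃s = W_s h_s + b_s` to a common `d_f` (default 128, matching the
projection output so that fine-tuning can route features through the
contrastively trained heads). Following the operator definitions literally,
the gate network and the bilinear form take the *raw* features while the
combination paths take the aligned ones. Cross-attention on single vectors
is degenerate (softmax over one key is identically 1); the default
single-token mode is kept faithful to the definition, and
`cross_attention_tokens = k` reshapes each aligned vector into `k`
sub-tokens when non-trivial attention is wanted. The bilinear operator uses
the full `d_f × d1 × d2` form at desk scale with an optional factored rank
cap for larger dimensions. Gate and attention networks use one hidden layer
of width `d_f` (width is otherwise unconstrained). The classifier is the
three-layer `[256, 64, 2]` softmax MLP with dropout 0.3; fine-tuning
minimises cross-entropy with Adam, checkpoints on validation AUC (the
primary model-selection metric), and early-stops at patience 20 full scale.
Checkpoint ties resolve to the *later* epoch: with small validation sets the
AUC saturates quickly, and continued optimisation at equal validation
evidence beats an early frozen snapshot. Fine-tuning defaults leave
encoders and projection heads unfrozen — the configuration reported as
strongest — with both freeze switches exposed.

## Synthetic cohorts

The generator emulates the statistical skeleton of a two-group, multi-site
resting-state cohort. Per subject, ROI signals follow the stationary AR(1)
recursion `x_t = a·x_{t−1} + √(1−a²)·e_t`, `e_t ~ N(0, C)`, which leaves
the instantaneous covariance *exactly* `C`: the implanted correlation
structure survives temporal smoothing. `C` is the identity except on a
designated edge set, where controls receive `base_r` (default 0.1) and
cases `base_r + delta_r` (default 0.5 — a strong, clearly learnable
effect). Infeasible targets are projected to the nearest positive-definite
correlation matrix, with an error if any target edge moves by more than
0.05. Defaults: 200 subjects, `R = 20`, `T = 100`, 3 pseudo-sites dealt
round-robin within class (labels exactly balanced), `a = 0.85` — the lag-1
autocorrelation of 0.01–0.1 Hz band-passed BOLD sampled at ~2 s, chosen so
masked time points are genuinely predictable from context. Optional
per-site mean offsets and variance scales (both off by default) create
distribution shift for cross-site evaluation; note correlation is invariant
to them, so they stress only the temporal stream.

What the generator does *not* emulate: haemodynamic response shape,
scanner-specific noise spectra, motion artefacts, group differences in
temporal dynamics (all group signal lives in the covariance), and
inter-subject variability beyond sampling noise. Consequently a passing
synthetic benchmark shows the machinery learns and attributes the structure
it was given, not that real-cohort accuracy is reproduced — and because the
temporal stream is by construction a noisier view of the same covariance
signal, dual-stream vs connectivity-only comparisons sit at a statistical
tie at these effect sizes rather than showing the complementary-information
gain expected on real data.

## Evaluation protocol

Splits are stratified by label with exact largest-remainder per-class
counts (70/10/20 canonical). Metrics: rank-based AUC, plus accuracy,
sensitivity, specificity and F1 at the 0.5 threshold; multi-seed runs
report mean ± sd and are compared by paired two-tailed t-tests with
Bonferroni correction (identical vectors report p = 1; a constant nonzero
difference has zero variance and is flagged rather than given a fake
t-value). Leave-one-site-out holds each site out in turn; subject-level
predictions aggregate sliding-window class votes by majority — ties broken
toward the positive class, a sensitivity-preserving convention — while the
AUC score is the mean window probability (vote counts are too coarse for
ranking). The default window is the full sequence, making windowed and
plain evaluation bit-identical. The "relative parameter change" diagnostic
is the per-tensor Frobenius ratio `‖Δθ‖/‖θ‖` averaged over tensors,
excluding zero-norm reference tensors (zero-initialised biases carry no
scale): an untouched module scores exactly 0 and a uniformly doubled one
exactly 1.

## Interpretability

Connection importance is the sample-averaged absolute gradient of the
case-class logit with respect to each flattened Pearson value, scattered
back to a symmetric matrix via the fixed edge ordering; the connectivity
vector is treated as the independent variable (its dependence on the series
is deliberately not chained). ROI importance averages gradients over time
*before* the absolute value — signed cancellation is meaningful — with
`abs_first=True` for the alternative order. Analytic surrogates (linear and
quadratic forms) pin both computations exactly in tests, and
finite-difference checks bound the autodiff path. Default analysis samples
are the held-out test split.

## Numerical and scaling choices

All network code is pure numpy differentiated by reverse-mode `autograd`;
Adam with decoupled-style L2 weight decay operates on named parameter
subtrees, and freezing is implemented by skipping a subtree's update
entirely (hence bit-exact). Dropout masks are drawn outside the autodiff
trace and applied multiplicatively. Desk-scale benchmark sizes — encoder
dims 32–64, 1–2 layers, cohorts of 120–200 subjects with 20 ROIs, 10–40
epochs per stage, batch 8–32 with learning rates 1e-3–5e-3 (larger than the
full-scale 1e-4/5e-5, as appropriate for the smaller models) — were chosen
so the complete pipeline runs in minutes on one CPU while every stage still
has measurable learning signal.

## Known limitations

* Subject-level cross-modal retrieval on held-out data does not reach high
  accuracy at desk scale: the pretext leaves `[CLS]` untrained, ~90
  training subjects invite InfoNCE memorisation, and 20 epochs are not
  enough for the temporal encoder to learn a generalisable
  correlation-signature estimator. Group-level alignment (positive pairs
  closer than negatives by ~0.2–0.3 cosine) emerges at roughly double that
  schedule.
* The three-stage pipeline occasionally (roughly one in five
  dataset/seed combinations at desk scale) enters a no-learning basin at
  fine-tuning: the contrastive stage leaves the projection heads in a
  collapsed configuration, fused features are near-constant, and the
  cross-entropy sits at log 2 with dead gradients. Re-running with a
  different seed recovers; lowering the contrastive learning rate or
  freezing encoders does *not* (weakly trained heads collapse more often,
  not less). Treat per-seed results below AUC ≈ 0.6 on clearly separable
  synthetic data as failed fits.
* At strong effect sizes both the dual model and the connectivity-only
  ablation saturate near AUC 1.0 and their ordering is noise; the synthetic
  benchmark cannot demonstrate the dual-stream advantage.
* The bilinear fusion's full tensor is quadratic in the feature dimensions;
  use the rank cap beyond `d_f ≈ 128`.
* Training is single-device, full-precision, and deterministic given one
  seed; no hyperparameter search is included.
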