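# Methods

This note documents the model, the choices made where the design was
genuinely open, the synthetic data the package is validated on, and the
numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Features

Recordings are zero-phase band-pass filtered (order-4 Butterworth,
forward–backward `sosfiltfilt`) into delta (1–3 Hz), theta (4–7 Hz), alpha
(8–13 Hz), beta (14–30 Hz) and gamma bands. Gamma is specified open-ended
(">31 Hz") and is capped at 0.45 × sampling rate so the filter stays inside
the Nyquist range. Signals are cut into 1-s non-overlapping windows by
default (configurable); trailing partial windows are dropped.

**Differential entropy (DE)** uses the Gaussian closed form
½ ln(2πe σ²) of each band-filtered window — the standard construction in
the DE literature, deterministic and cheap. The window variance is floored
at 1e-12 before the logarithm so constant windows stay finite (and log a
degenerate-input warning). **PSD** is the natural log of the mean
periodogram power over the frequency bins inside [low, high). **DASM** and
**RASM** are DE differences and ratios over symmetric left/right electrode
pairs; **ASM**, which the literature lists but does not define precisely,
is implemented as the concatenation [DASM ‖ RASM] along the pair axis.
No temporal smoothing (e.g. LDS) is applied by default; a moving-average
option exists.

Symmetric pairs are derived by odd/even label mirroring (F3–F4, CB1–CB2,
…); the packaged 62-channel extended 10-20 montage has 27 such pairs, and
synthetic montages are labelled so the same rule applies. Montage 2-D
coordinates come from an approximate row/arc layout on the unit disc —
adequate for kNN graph construction and topographic plotting, not for
source analysis.

## Network

Defaults (all exposed in `ModelConfig`): conv width C = 32, transformer
depth 2 with 4 heads and feed-forward width 2C, GAT with K = 4 heads and
F′ = 32 output features, dropout 0.3, Top-K k = 10, kNN k = 10, samples of
T = 10 consecutive windows (so T_r = 6). Width/depth values are not fixed
by the protocol we follow and were chosen small enough for desk-scale CPU
training.

Decisions where the construction was open:

- **Per-electrode convolutions.** The learning block is electrode-level:
  electrodes are batch entries, convolution weights are shared across them,
  and kernels run over the (band, time) plane. Kernel order is 3×3, 3×3,
  then 1×1, unpadded, collapsing five bands to one and shrinking time by 4.
- **Temporal attention shapes.** The printed parameter shapes for the
  temporal map (a length-T_r vector and a C×N matrix) cannot produce a
  T_r×T_r map; the implementation mirrors the spatial construction on the
  transposed tensor (contract electrodes with U₃, map channels to T_r with
  U₄), which does. The spatial and temporal mixing matrices V are
  independent parameters.
- **Mini-batch standardization.** The score standardization uses mean and
  *population* variance over every entry of the batch (batch-normalization
  convention), eps = 1e-5, scalar learnable affine, running statistics at
  evaluation time.
- **Top-K.** Applied row-wise, keeping each row's k largest entries at
  their original values; ties break toward the lower column index (stable).
  The sparsified adjacency may be asymmetric; the GAT neighborhood of node
  i is the nonzero set of row i plus a mandatory self-loop. Because
  standardized weights can be negative, repeated application is only
  guaranteed idempotent on nonnegative rows.
- **Adjacency → GAT coupling.** Retained adjacency weights are *added to
  the GAT attention logits* (e_ij + A_ij) before the softmax. A purely
  structural (mask-only) use of A would leave the spatial-attention
  parameters without any gradient path; the additive bias keeps the
  attention-coefficient formula intact on the neighborhood while making
  the dynamic adjacency trainable end to end. Head outputs are averaged
  (per the closed-form head-fusion equation rather than the prose's linear
  layer), passed through an ELU; LeakyReLU slope is 0.2 (GAT convention).
- **Static graph.** Variants without spatial attention (`tgat`,
  `tgat_tlb`) take a kNN graph (k = 10 by default — the Top-K value reused,
  since no separate kNN k is specified) built from 2-D electrode
  coordinates and symmetrized by edge union. An optional warm-start flag
  adds the kNN adjacency to the spatial-attention bias at initialization;
  off by default.
- **Readout and loss.** Mean over nodes → dropout → linear → cross-entropy.

## Training and evaluation

Adam with the published settings (lr 1e-5, batch 16, dropout 0.3, stop when
epoch-mean training loss < 0.15) is the `published` profile. Because the loss
threshold may never trigger, a `max_epochs` guard (200) is added. The
`test` profile (lr 1e-3, max 50 epochs) reaches the same stopping loss in
minutes on CPU and is used for the synthetic experiments. All randomness —
initialization, batch order, dropout — derives from one integer seed, and
reruns are bit-identical.

LOSO cross-validation trains one fold per subject on all other subjects;
test-subject disjointness is asserted on every fold, and per-feature
z-scoring is fit on the training fold only. Mean and (population) standard
deviation across subjects summarize a run. The protocol's repeated rounds
are implemented as reruns with different seeds; comparisons between
variants average those rounds, which is how the performance criterion is
defined in the protocol we follow. The ablation suite runs the eight
variants under identical seeds and fold assignments.

## Synthetic cohorts

The generator emulates the structure of multi-subject emotion-EEG corpora.
Defaults: 8 subjects, 24 channels, 3 classes, 6 trials per class, 20-s
trials at 200 Hz, coupling strength 0.8, 10 coupling edges per class. Each
class has a hidden graph of channel pairs sampled uniformly without
replacement; every edge carries a band-limited latent oscillator (cycling
through alpha, beta, gamma — the bands most associated with affective
state) added to both endpoint channels on top of unit-variance 1/f
background noise. Subjects differ by a log-normal multiplicative gain
(σ = 0.15) and an additive noise level (mean 0.2) — enough individual
variability to make LOSO nontrivial but solvable, which is the regime the
evaluation harness is meant to exercise.

What this emulates: cross-subject amplitude variability, class-dependent
band-limited connectivity, class-balanced trial structure. What it does
not: artifacts (EMG/EOG), non-stationarity within trials, volume
conduction, realistic spatial covariance of background EEG, or label noise.
Passing the end-to-end tests therefore shows that the pipeline recovers
class structure carried by band-limited coupling under subject
variability — not that any particular accuracy transfers to real EEG.

## Connectivity-recovery experiment

After training, per-sample dynamic adjacencies are extracted in evaluation
mode, averaged over all samples, symmetrized as (A + Aᵀ)/2, and the ten
globally largest upper-triangle entries are compared against the union of
the ground-truth class graphs (precision@10, chance level =
|union| / C(N,2)). The pre-Top-K standardized matrix is averaged by
default — averaging post-Top-K matrices biases toward frequently selected
but weak edges — with a flag to average the sparsified form instead. The
global ten-edge selection used for visualization is deliberately distinct
from the per-row Top-K inside the network.

The experiment trains three models on the full cohort (seeds 0–2) and
averages their adjacencies before scoring: connectivity analysis, unlike
accuracy estimation, has no held-out-subject requirement, and averaging
across independently initialized models suppresses the run-specific hub
structure a single model's learned adjacency carries. The recovery signal
is weak by construction — per-channel band features carry coupling only
through class-conditional co-elevation — so precision is expected modestly
above chance, not near 1.

## Problem sizes and determinism

The shipped experiments use the default cohort (288 samples of shape
24 × 5 × 10) with the `test` training profile; a full three-round
LOSO comparison of `stgate` and `baseline` plus the recovery experiment
runs in roughly ten minutes on one CPU. All computation is float64 NumPy;
results are deterministic given the same BLAS build. Degenerate inputs are
handled explicitly: constant windows hit the DE variance floor,
constant score batches standardize to zero via the eps guard, and empty
window lists (window longer than signal) warn rather than raise.
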