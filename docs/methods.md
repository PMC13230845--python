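# Methods

## Problem and approach

`duplexmap` scores candidate piRNA–mRNA interactions. Rather than feeding two
raw sequences to a network and hoping it discovers pairing rules, the package
renders each pair as an explicit interaction map on the L_p × L_m grid of all
(piRNA position i, site position j) combinations, with channels that encode
what is known about RNA duplex formation, and lets a small CNN learn which
spatial patterns on that map distinguish binding from non-binding pairs.

## Featurization

**Cleaning and geometry.** Sequences are uppercased, `T` is mapped to `U`,
and any other character outside {A,C,G,U} is rejected with its position —
ambiguity codes are not coerced because no principled encoding exists for
them in a pairing grid. Inputs are right-padded (sentinel `-`) or truncated
(keeping the 5′ prefix) to a fixed length policy; by default the policy is
the maximum cleaned lengths observed in the dataset (21/31 for the
benchmark-shaped generator). The sentinel one-hot encodes to the all-zero
row, so padded positions contribute zeros to the pair-identity and
compatibility channels. All coordinates are 0-based.

**Pair identities (16 channels).** `B_{a,b}[i,j] = P[i,a]·M[j,b]`; channel
`4a+b` with the piRNA base as major index. At every non-padded cell exactly
one channel is 1; at padded cells all are 0.

**Compatibility (1 channel).** `C = clip_[0,1](P·S·Mᵀ)` with

```
        A    C    G    U
  A  [  0    0    0    1  ]
  C  [  0    0    1    0  ]
  G  [  0    1    0   0.6 ]
  U  [  1    0   0.6    0 ]
```

Watson–Crick pairs weigh 1, the G·U wobble 0.6, everything else 0. The clip
is a no-op for one-hot inputs but kept so that soft encodings, if ever
supplied, stay bounded. `C` is exactly the linear functional
`Σ_{a,b} S[a,b]·B_{a,b}` of the identity channels — a property the test
suite asserts cell-by-cell.

**Helix runs (2 channels).** Duplex helices appear on the interaction map as
contiguous diagonal or anti-diagonal stretches of compatible cells.
`H_diag = (1/k)·Conv2D(C, I_k)` and `H_anti` uses the horizontally flipped
identity kernel; k = 7 (odd, roughly a seed length), stride 1, zero "same"
padding ⌊k/2⌋. Convolution is implemented as cross-correlation; since the
kernels are symmetric under 180° rotation, this choice only fixes the
anti-diagonal channel's orientation. Values are window means in [0,1];
border cells average over fewer in-bounds cells (e.g. corner value 4/7 on an
all-ones map at k = 7).

**Relative position (1 channel).** `Δ[i,j] = |i/(L_p−1) − j/(L_m−1)|`,
computed over the full fixed grid including padded positions. Masking Δ on
padding would be preferable in genuinely variable-length settings; at the
fixed 21/31 geometry this does not arise, and the fixed-grid behaviour is
the implemented default.

**Structural accessibility (1 channel).** A nucleotide already paired inside
its own molecule is unlikely to be free for intermolecular pairing. For each
cleaned, unpadded sequence a Nussinov dynamic program maximizes the number
of non-crossing pairs from {A·U, G·C, G·U}, subject to the minimum loop
constraint `j − i > l_min` (default 3, i.e. at least 3 unpaired bases
between partners). The traceback is made deterministic by a fixed preference
order: leave j unpaired, pair (i,j), bifurcate at the smallest split point.
Positions paired in this structure get unpairedness 0, all others 1; padded
positions get 0 (inaccessible). The channel is the outer product
`A[i,j] = u_p[i]·u_m[j]`. This is an accessibility *prior*, not a
thermodynamic structure prediction: it is O(L³), deterministic, and
cacheable (a JSON key-value store keyed by a hash of sequence, l_min and the
wobble flag), which matters when folding tens of thousands of short
sequences across folds. Whether wobble pairs should score in the fold is
genuinely ambiguous in the literature; `allow_gu` is a flag, on by default
for consistency with the wobble-aware compatibility channel.

**Ablation.** Channel groups (`Base16`, `C`, `Hdiag`, `Hanti`, `Delta`, `A`)
are removed, not zero-filled: the tensor narrows and the model's input-
channel count follows. This makes single-channel and leave-one-out models
structurally honest rather than masked variants of the full model.

## Classifier and training

Three conv blocks — 64@5×5 (pad 2), 128@3×3 (pad 1), 256@3×3 (pad 1), each
followed by batch normalization, ReLU, squeeze-and-excitation attention
(reduction 8), and 2×2 max pooling after the first two blocks — then global
max pooling, dense 256→128, ReLU, dropout 0.5, dense 128→1. Global max
pooling makes the parameter count independent of grid size and matches the
detection task: a binding signature is a localized pattern whose *presence*
matters more than its extent.

There is no deep-learning framework underneath: every layer implements
`forward` and `backward` on NumPy arrays. Convolution uses im2col plus one
BLAS matmul; max-pool gradients route to the argmax (first index on exact
ties); batch norm uses batch statistics in training and running statistics
(momentum 0.1) in evaluation, with correct gradients in both modes. All
gradients — including those with respect to the input tensor and the last
conv block's feature maps, which the interpretability code consumes — are
validated against central finite differences in float64 in the test suite.

Training: Adam (β = 0.9/0.999, ε = 1e-8) with L2 weight decay 1e-4 added to
the gradient, lr 1e-3, batch size 64, binary cross-entropy on the logit in
the numerically stable form. A stratified 10% inner validation split is
carved from each training set (the protocol names an inner split without a
size; 10% is the package's choice). After each epoch the inner ROC-AUC is
evaluated; the best-AUC weights are restored at the end; training stops
after 4 non-improving epochs or 30 epochs (learning plateaus within a
handful of epochs on both real-scale and synthetic data, so the cap is a
safety net, not a tuning knob). The learning rate halves after 3
non-improving epochs. Weight initialization is the framework-default
fan-based scheme, uniform(±1/√fan_in), so reproducibility rests on the seed
rather than a bespoke init. A single integer seed (default 42) drives the
fold splitter, the inner split, weight init, batch shuffling, and dropout;
identical seeds give bit-identical fold assignments, epoch-1 losses, and
selected thresholds.

**Thresholds.** Within cross-validation the decision threshold is selected
on the inner validation split by sweeping 0, 1 and all midpoints of sorted
distinct scores and maximizing Youden's J = TPR − FPR, ties broken toward
the smaller threshold; hard calls are `p ≥ t` (the boundary rule is a
convention, recorded here). External/prediction-mode evaluation uses a fixed
0.5 to avoid post hoc tuning. ROC-AUC and PR-AUC are trapezoidal areas over
the full curves (scikit-learn); the suite cross-checks ROC-AUC against an
independent rank-sum (Mann–Whitney) implementation with tie correction.

## SeedMatch baseline

A deterministic heuristic: slide every 7-nt piRNA window against every 7-nt
site window in antiparallel alignment (p[i+t] faces m[j+w−1−t]) and count
canonical complements (A·U, G·C; wobble excluded by default, flag
available); the score is the best count over w. It captures seed-like
pairing and nothing else, which is exactly why it is a useful control.

## Synthetic data

The generator emulates the benchmark's signal geometry at desk scale:
21-nt piRNAs and 31-nt sites drawn i.i.d. with a GC knob (default 0.42,
matching the benchmark's ~0.40–0.47 compositions). A positive embeds the
reversed complement of a random 12-nt piRNA window at a random site
position — antiparallel, consistent with duplex geometry and the
anti-diagonal helix kernel — with each planted position independently
switched to a wobble partner with probability 0.1 (where one exists) or
corrupted to a non-complementary base with probability 0.05. Negatives are
pure background. Labels are balanced.

What this does *not* emulate: CLASH negatives are energy-filtered near-miss
candidates rather than random background; real positives tolerate bulges
and fragmented pairing; real piRNA populations share sequence families.
Passing the end-to-end tests therefore demonstrates that the pipeline
learns planted complementarity signals end-to-end — not benchmark-level
accuracy on experimental data. One useful structural consequence of the
fixed 21/31 geometry: the positional channel Δ is *identical for every
record*, so a Δ-only model provably carries no label information and must
score at chance — the suite uses it as a negative control.

## Interpretability

Grad-CAM differentiates the logit against the last conv block's (post-SE)
feature maps, weights each map by the spatial mean of its gradient, sums,
applies ReLU, bilinearly resizes to the input grid, and min-max normalizes;
an identically-zero raw map is returned as zeros with a degenerate flag
rather than divided by zero. Channel saliency differentiates the logit
against the input tensor and aggregates the mean absolute gradient per
channel (absolute values prevent sign cancellation; the choice is recorded
in the report metadata), then sums into five groups — pair IDs,
compatibility, runs (diagonal + anti-diagonal), position, structure — and
normalizes to shares. Shares are invariant to positive rescaling of the
gradient, and ablated checkpoints report shares only over present groups.

## Problem sizes and numerical choices

The end-to-end suite runs 2-fold cross-validation on 2,000 synthetic pairs
(seed 42, generator defaults) — large enough for the full model to clearly
separate planted signal from the chance-level Δ-only control, small enough
for a single-CPU run in minutes. Unit-level training smokes use 200–600
pairs. Structure oracles enumerate all non-crossing matchings for sequences
up to 12 nt; helix-run oracles are explicit windowed means on random grids.
Model weights are float32 (gradient checks run the stack in float64);
metric computations are float64. Degenerate cases are defined rather than
left to chance: precision with zero positive calls reports 0 with a flag,
single-class inputs are rejected where a metric would be undefined, and
length-1 axes are rejected by the positional channel (division by L−1).

## Limitations

- The Nussinov mask is a coarse accessibility proxy; partition-function
  unpairedness probabilities would be a drop-in upgrade for the same
  channel definition.
- The fixed local site window cannot represent distal pairing context.
- The NumPy network is single-threaded BLAS-bound; it trains desk-scale
  datasets in minutes but is not built for hundred-thousand-pair corpora.
- Synthetic results bound what the pipeline can learn, not what it achieves
  on CLASH-derived benchmarks (see the generator section above).
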