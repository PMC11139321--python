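# Methods

`contactdiff` translates balanced Hi-C contact matrices toward Micro-C-like
matrices with a Hi-C-conditioned denoising diffusion model (DDPM), alongside
an identically-structured regression baseline, and evaluates the result at
the level of chromatin loops.  This note records the model, the numerical
choices, what the synthetic data emulate, and the limits of what the bundled
tests demonstrate.

## Problem setting

Micro-C (MNase-digested chromosome conformation capture) resolves chromatin
loops that restriction-enzyme Hi-C misses, because its signal-to-noise ratio
at loop-scale features is higher.  Far more Hi-C than Micro-C datasets
exist.  The package learns the conditional mapping from a Hi-C contact
matrix to the corresponding Micro-C matrix so that loop-level structure can
be read out of existing Hi-C.

Matrices are handled per chromosome as sparse upper-triangle triplets of
balanced values (`count * w_i * w_j` in the cool convention), with 0-based
bin indices over half-open intervals `[start, start + resolution)`.  Bins
with undefined balancing weight are *missing* and are distinguished from
true-zero pixels between valid bins.

## Value normalization

Balanced values are mapped to the network range [-1, 1] in four steps:
clip at `maxV`; linear map [0, maxV] -> [1, 10]; log10 -> [0, 1]; linear map
-> [-1, 1].  `maxV` (0.05 at 5 kb, 0.08 at 1 kb) sits near the smallest
non-zero value on the first two diagonals, so the extreme near-diagonal
pixels cannot dominate the scale.  Missing and zero pixels both map to -1:
the networks need dense grids, and zero contact is the natural floor level.
Network outputs are clipped to [-1, 1] before inversion, since the log-scale
inverse would otherwise explode.  The inverse transform is exact on
[0, maxV] (round-trip error < 1e-12 over the full range).

## Tiling and stitching

A chromosome matrix is covered by `window x window` tiles (256 at full
scale) whose top-left corner slides along the diagonal in fixed steps (50
bins at 5 kb, 100 at 1 kb) and rightwards in the same steps up to a cap,
keeping only pixels within 2 Mb genomic distance, the maximum loop length
considered.  Two end-handling rules guarantee complete coverage of in-scope
pixels at chromosome ends: a final diagonal anchor at `n_bins - window`, and
a final per-row column anchor at the same offset when the stepped columns
stop short.  Both are verified by an exhaustive enumeration test.
Predictions are inverse-normalized first and then averaged per pixel over
all covering tiles (averaging on the balanced scale); output is stored upper
triangle, and values always land in [0, maxV].

## Diffusion model

The forward process corrupts a normalized Micro-C tile x0 as
`x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps` with a linear variance
schedule.  Training uses T = 1000, beta from 1e-4 to 0.02.  The denoiser is
conditioned on a *continuous* noise level rather than the step index: with
`l_t = prod_{i<=t}(1 - beta_i)`, `l_0 = 1`, the level is drawn uniformly
from [l_t, l_{t-1}] at a uniformly chosen step t, and its sinusoidal
embedding (of a large-constant-scaled sqrt of the level by default; the raw
level is a config switch) enters every residual block as a per-channel
`(1 + scale, shift)` pair after the first normalization layer.  The loss is
the L1 norm of the noise-prediction error.

Because the denoiser understands noise levels rather than step indices,
inference can run a much shorter schedule: T = 50, beta_1 = 1e-4,
beta_T = 0.95 by default.  Ancestral sampling follows
`x_{t-1} = (x_t - (1-alpha_t)/sqrt(1-abar_t) eps_hat) / sqrt(alpha_t)
+ sigma_t z` with z = 0 at t = 1.  `sigma_t` is not pinned down by the
update rule itself.  The default is the forward-posterior standard
deviation, `sigma_t^2 = (1 - abar_{t-1}) / (1 - abar_t) * beta_t`, with
`sigma_1 = 0`: on a T = 1000-style schedule this is indistinguishable from
the simpler `sqrt(beta_t)`, but on the fast schedule (beta_T = 0.95) the
simpler choice injects late-step noise of scale ~0.97 that no subsequent
step can remove, and sampled matrices never leave the noise floor; both
choices (and "zero") are exposed in configuration.  During sampling the
implied clean tile can additionally be clamped to the data range [-1, 1]
at every step (`clip_denoised`, the usual stabilizer in this model
family's implementation lineage); chromosome prediction enables it, while
the raw update — whose zero-denoiser closed form the tests pin down —
remains the default of the sampler itself.  The inference schedule's own
cumulative level is what the denoiser sees during sampling, which is
exactly what makes the beta_T sweep meaningful: at beta_T = 0.01 the level
barely moves from 1 and the model is effectively denied its noise-level
signal.  Each tile draws its own x_T from the seeded stream; sampling is
fully deterministic given the seed.

## Networks

The denoiser is a U-Net: an initial convolution; per level two residual
blocks, a linear-attention block, and a stride-2 convolution downsample; a
middle block with vanilla (full softmax) attention; a symmetric up path
(nearest-neighbour upsample + convolution, skip concatenation).  Residual
blocks are conv -> group norm (4 groups) -> scale-shift -> SiLU, twice, with
an identity (or 1x1) shortcut.  Attention blocks are pre-normalized (1
group) with a residual connection; 4 heads x 32 dims by default (both
configurable; the attention geometry is not fixed by the architecture's
description, only its placement).  Depth multipliers default to (1, 2, 4, 8)
on a base width of 64 channels.  The Hi-C condition enters by channel
concatenation with x_t, and by default is additionally re-injected at
every resolution (average-pooled per scale and concatenated to each down
level's and the middle block's input).  Input-only concatenation — the
standard conditional image-to-image arrangement — is available as a config
switch, but on smooth training data the conditioning pathway is learned
very slowly through the input alone (see the desk-scale findings below),
so the multiscale route is the default.  The regression variant uses the
same backbone with the condition as its only input, no noise-level
pathway, and directly outputs the predicted tile.
The final convolution is zero-initialized in diffusion mode so training
starts from the unbiased eps = 0 prediction.

The networks, layers, and Adam optimizer are implemented on a small
reverse-mode autodiff engine over NumPy arrays (`contactdiff._nn`), written
for this package; convolutions are evaluated as nine shift-and-matmul
kernel taps, which keeps the arithmetic in BLAS.  Parameters are float32.
An inference mode (`no_grad`) skips graph construction during validation
and prediction.

## Training protocol

Adam at 1e-4 with batch 16 and L1 loss is the full-scale recipe; at 5-kb
scale the learning rate is cut 10x when validation L1 fails to improve for
10 epochs (the plateau rule is unit-tested as a contract), while the 1-kb
recipe runs a fixed 30,000 steps.  Validation tiles come only from held-out
chromosomes, and the split is asserted disjoint by construction.  The
checkpoint keeps the best-validation parameters (model selection is not
otherwise pinned down; best-validation is the conservative choice), together
with every config needed to reproduce predictions (architecture,
normalization, tiling, schedules).

## Synthetic study conditions

The generator emulates one chromosome arm per call: a shared power-law
distance-decay background `P(d) ~ (1 + d)^-1` scaled to peak at `maxV`;
planted Gaussian loop dots (sigma 2 bins) at 100 kb–2 Mb separations, at
least `2 * dot_width` apart so matching is unambiguous; fold enrichment 3
in the Micro-C member versus 1 in Hi-C; mean-one log-normal multiplicative
noise with dispersion 0.5 (Hi-C) versus 0.15 (Micro-C); 2% missing bins;
and Poisson count realization at depth 2e4 counts per unit balanced value,
with uniform balancing weights `1/sqrt(depth)` so raw counts, weights and
balanced values behave like a real cool matrix (and binomial read thinning
is meaningful).  In the noise-free limit counts are realized
deterministically, so a zero-amplitude, zero-dispersion pair collapses to
the shared background exactly (up to count quantization).  Defaults are
fixed once: a 512-bin chromosome at 5 kb with 40 loops.

The bundled dot detector (smoothed observed/expected local maxima against a
ring mean) is a deliberately simple stand-in for external loop callers; its
defaults were calibrated once against the generator defaults so the clean
Micro-C member recovers >= 90% of truth loops at extending size 1 while the
noisy Hi-C member trails by a wide margin — the premise the translation
exploits — and then frozen.  Its `2^-enrichment` pseudo-FDR exists only so
top-loop ranking has something to rank.

What the synthetic data do **not** emulate: TADs, compartments, stripes and
flames; distance-dependent noise structure; assay-specific systematic
biases; inter-chromosomal contacts.  Passing desk-scale tests therefore
shows the machinery is correct and that the models can learn a conditional
dot-enhancement mapping — not that the defaults reach publication-grade
performance on real 4DN/GEO data, which requires billions of read pairs and
external loop callers.

## Loop-level evaluation

Loop matching uses the `(2s+1) x (2s+1)` pixel square (s = 0..3); recovery
is the matched fraction of reference loops, monotone in s.  Top-loop
selection takes the n smallest FDRs with a deterministic lexicographic
tie-break.  APA averages `window x window` blocks centered on loop pixels
(11/3 corner at 5 kb, 51/15 at 1 kb); each corner score is the center pixel
of the averaged block divided by that corner block's mean (the center is the
single central pixel; a central block is a plausible alternative the
formula's description leaves open).  In observed/expected mode all loops are
usable; in raw mode loops are pre-filtered to 100 kb–2 Mb (both ends
inclusive).  Loops whose window leaves the matrix are skipped and counted,
not padded.  Anchors derive from bins as resolution-sized half-open
intervals, optionally extended ±5 kb to the 15-kb loci used for ChIP-seq
peak overlap; anchor deduplication is exact-interval.  CTCF orientation
classes (convergent = forward–reverse on the upstream/downstream anchors,
divergent, forward, reverse) resolve an anchor's strand only when all
overlapping motifs agree; anchors with both strands present stay
unclassified.  Enhancer–promoter loops require one extended anchor in an
enhancer and the other in a promoter, in either orientation.  All interval
machinery is tested against quadratic brute-force oracles.

## Desk-scale study (acceptance protocol)

Eight 512-bin chromosomes are generated (one blind test, six training, one
validation — training on a single chromosome memorizes its loop positions
instead of learning the amplification mapping); tiles are 64 bins with a
48-bin diagonal step and 8 rightward steps (the same geometry logic as
full scale, scaled so the 2-Mb cap stays reachable); the networks run base
16 channels with multipliers (1, 2, 4) and 2-head, 16-dim attention.
Optimization budgets are bounded (300 regression steps at batch 8, 400
diffusion steps at batch 4, Adam 2e-3; see `_study.py`) so the full
protocol — train both models, predict the blind-test chromosome with the
diffusion sampler at T = 50 / beta_T = 0.95, and score normalized L1 plus
truth-loop recovery — completes on a single CPU.  The ablation protocol
re-samples from the same diffusion checkpoint with beta_T = 0.01; the
down-sampling protocol thins raw Hi-C counts binomially at 1/4, 1/8 and
1/16 (weights rescaled by `1/sqrt(fraction)` to emulate re-balancing, so
degradation reflects shot noise rather than a global scale shift) and
re-predicts with the regression checkpoint across seeds.

## Desk-scale findings

Two properties of this protocol are worth understanding before reading
test output, because both are consequences of the study conditions rather
than defects in any verified component (every numerical operation in the
package is pinned to an independent oracle).

First, the regression baseline converges to a *smooth* prediction that
improves the Hi-C matrix substantially on the L1 scale but draws no loop
dots.  This is the conditional-median property of L1 regression: a dot
whose posterior probability given the noisy Hi-C evidence falls below 1/2
is excluded from the optimal prediction entirely, and in training
trajectories dot amplitude is carved only transiently before the optimizer
settles on the lower-loss smooth solution.  Loop recovery from the
regression prediction therefore falls *below* the Hi-C input's own
recovery under these conditions, even while its L1 is nearly twice as
good.

Second, the synthetic tiles are smooth and low-entropy enough that the
eps-predictor can infer the clean tile from the faint true-signal
component inside x_t at essentially every training noise level, so the
loss provides almost no incentive to exploit the Hi-C condition; the
learned denoiser behaves near-unconditionally no matter how the condition
is wired in.  Ancestral samples then converge to condition-inconsistent
draws from the marginal, and the sampled chromosome does not approach the
true Micro-C on the L1 scale at any desk budget.  The beta_T sweep
direction is nevertheless reproduced (near-constant noise levels are
clearly worse), and all sampler mechanics are verified exactly against
closed forms.  Real contact maps are far richer than the generator's
decay-plus-dots model, which is precisely why the published full-scale
method does not face this degeneracy; reproducing its headline loop
recovery requires either richer synthetic structure or full-scale data and
compute, both outside this package's desk envelope.

## Known limitations

- No GPU path; the NumPy engine is single-threaded BLAS and desk-scale by
  design.  Full-scale training (256-bin tiles, base 64, multipliers to 8)
  is implemented but impractical without substantial compute.
- `mcool`/multi-resolution selection, hic-format parsing, and matrix
  balancing itself are out of scope (weights are read, not computed).
- The dot detector is not Mustache/SIP and its pseudo-FDR is not a
  statistical FDR.
- Whether predicted matrices should carry a balancing-weight column is not
  standardized; predicted cools store balanced-scale values with unit
  weights.
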