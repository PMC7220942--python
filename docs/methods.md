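# Methods

## Model

`cnnpeaks` treats peak calling as learning a *local decision threshold* for
read-depth enrichment rather than classifying every base directly. A genomic
window is reduced to `L` bins; a convolutional network reads the smoothed
binned depth `x` together with a binary annotation track `λ` and outputs one
threshold `t_j` per segment of `L/S` consecutive bins. The per-bin peak
probability is `h_i = sigmoid(x_i − t_seg(i))`: the network does not score
bins, it decides *how high the signal must be, here,* to count as a peak.
This keeps the output layer at `S` values instead of `L` (the broadcast back
to `L` bins costs nothing) and bakes in the monotonicity a depth-based
caller should have — with thresholds fixed, more coverage never lowers the
peak probability.

Assumptions inherited by everything downstream:

- per-base counts are approximately Poisson, so the peak score uses an upper
  Poisson tail; overdispersed real data will yield optimistic p-values
  (ranking within one dataset is unaffected, since activation and rate enter
  every call identically);
- enrichment is local and visible at bin scale: peaks narrower than about
  two bins are not representable;
- expert labels are trustworthy but *sparse*: most of each training window
  is unlabeled and is masked out of the objective;
- no control/input sample exists anywhere in the pipeline; the learned
  thresholds absorb the role a control plays in classical callers.

## Preprocessing

Depth is per-base pileup (reads overlapping a base, via their aligned
blocks; no fragment extension, no duplicate filtering — upstream tools own
those decisions). A window of span `B` bases becomes `L` near-equal bins
(`bin i` covers `[round(iB/L), round((i+1)B/L))`); depth is binned by mean,
annotation by max. Binning is followed by a stride-1 max-pool (width `w`
bins, window `[n − w/2, n + w/2]` clipped at the edges) and convolution with
a normalized Gaussian (`M` taps, scale `σ` bins, zero-padded edges). The
max-pool mimics how a browser-scale view emphasizes local maxima; the
Gaussian suppresses bin-level jitter. Windows smaller than `L` bases are
rejected with instructions to extend or drop them.

Defaults (all in the config surface): `L = 12,000` bins, `w = 5`, `M = 11`,
`σ = 2`. The reduced profile used by the synthetic study sets `L = 2,000`
and 10 bp bins (20 kb windows).

## Network

Stem: one convolution per input (depth, annotation; kernel 7, 8 channels
each), ReLU, channel concatenation, stride-1 max-pool (width 3). Seven
concatenation modules follow, in the order A, A, B, B, B, C, C:

- **A**: convolution (kernel 3) + max-pool + average-pool branches,
  concatenated. The pooling branches pass all input channels through, so
  channel count grows with depth;
- **B**: three convolution branches (kernels 1, 3, 5) only — this is what
  stops the channel growth;
- **C**: four wider convolution branches (kernels 7, 11, 15, 21) with
  stride 2, nearest-neighbor-upsampled back to full length so the per-bin
  correspondence survives.

Additive residual connections join successive modules (1×1 projection when
channel counts differ); batch normalization sits between each convolution
and its ReLU. The head average-pools the feature map from `L` positions to
`S` segments and applies two position-wise fully connected layers (1×1
convolutions, 64 hidden channels) shared across segments.

The shared head is a deliberate design choice: supervision is sparse, and a
head with separate parameters per segment leaves every never-labeled segment
with an arbitrary threshold. In the synthetic study the per-segment variant
produced thresholds ranging from −27 to +38 on a signal in [0, 25] and
called 1,341 peaks where 20 exist; the shared head, trained identically,
calls 21. Weight sharing converts a handful of labeled segments into a
threshold *rule* that applies everywhere, which is the point of the method.

All tensors are float64 numpy arrays; the network, its reverse-mode
gradients, and Adam are implemented in-repo (`cnnpeaks.nn`) and verified
against central differences (see below).

## Objective

Per-bin loss is class-weighted cross-entropy,
`ℓ_i = −[y_i w log h_i + (1 − y_i) log(1 − h_i)]`, with
`w = (# negative labeled bins) / (# positive labeled bins)` computed over
the training set (a per-batch mode exists). Peaks are rare, so without `w`
the trivial all-negative caller wins. On top of that, only the `κ` largest
per-bin losses of each window are averaged (Top-K): large `κ` emphasizes
sensitivity, small `κ` specificity; the default `κ = L/2` balances them.
Unlabeled bins are masked out of both the loss and the ranking, and `κ` is
capped per window at the number of labeled bins. A bin counts as labeled
(and as positive) when more than half of its bases lie inside labeled
(respectively PEAK) intervals; AMBIGUOUS labels are collapsed to NOPEAK
first. The probability-space formula above is what the public
`weighted_ce` computes (inputs at exactly 0/1 are clamped to ±1e-7); the
training path evaluates the identical quantity in logit space for
stability. Optimization is minibatch Adam (default lr 1e-3, batch 8); all
shuffling and initialization derive from one seed, and identical seeds give
bit-identical loss histories.

## Calling and scoring

Chromosomes are tiled into non-overlapping windows of `L × bin_width`
bases. Bins with `h_i ≥ 0.5` (the sigmoid's natural boundary) form runs;
runs separated by ≤ 1 bin merge, runs shorter than 2 bins drop, and runs
touching a window joint merge across it (the merged call keeps the
length-weighted mean activation and the smaller p-value — both parts saw
the same background rate). Each peak's observed statistic is its mean
*unsmoothed* binned depth, scored against `λ` = contig-wide mean depth
(default) or a local flanking mean floored by the global value (`local`
mode, 50-bin flanks), as `score = activation × (−log10 P(N ≥ round(d)))`,
`N ~ Poisson(λ)`. The peak-level statistic is the mean rather than the
maximum so that score does not grow with peak width for flat enrichment.

## Synthetic data

`simulate_track` generates the conditions the model assumes: independent
per-base Poisson depth at rate `λ_bg` outside and `λ_peak` inside disjoint
uniformly-placed peaks; ~2 kb annotation records centered on a 66% share of
peaks (the fraction of expert-labeled peaks near transcription start sites
in real ChIP-seq label sets varies around two thirds) plus an equal number
of records placed at random; PEAK labels on every peak and NOPEAK labels on
an equal number of random peak-free intervals; and short (≤ 50 bp) unlabeled
depth artifacts at 5× background rate, one per Mb in expectation, mimicking
mapping noise. `simulate_bam` converts a track into single-end perfectly
mapped reads (starts drawn Poisson(depth/read_length)), which restores
read-length autocorrelation and produces a real indexed BAM.

What the generator does **not** emulate: fragment-length structure, GC and
mappability bias, copy-number variation, overdispersion, broad diffuse
domains, and label noise. Passing the recovery study therefore shows the
pipeline is implemented correctly and can learn local thresholds from
sparse labels under its own statistical assumptions — it does not certify
performance on real cancer-line data, where those violations are the
hard part.

## The recovery study

The reference study (`cnnpeaks.experiments.run_recovery_study`) simulates a
2 Mb contig with 20 peaks of 0.5–2 kb, `λ_bg = 2`, `λ_peak = 20`; windows
are 2,000 bins × 10 bp with `S = 100` segments, 8 channels per branch, 30
epochs. Every 4th window is held out of training; bin-level F1 on the
held-out quarter is measured against the simulation ground truth, and
genome-wide calls are matched to planted peaks at ≥ 50% reciprocal overlap.
These problem sizes run the whole chain in roughly two minutes on one CPU
core. At the canonical seed (1337) the study reaches held-out bin-level
F1 ≈ 0.95 with 20/20 peaks recovered; across other seeds F1 typically lands
in 0.88–0.95 with 18–20/20.

## Numerical choices

- Tolerances: signal/loss primitives match brute-force reimplementations to
  1e-10; analytic gradients match central differences to 1e-4 on a small
  network.
- Convolution edge handling is zero-padding; max-pool windows clip. Both
  preserve length (stride 1).
- Conv/Dense biases are initialized uniform(±1/√fan_in), not zero: with a
  binary annotation input, zero biases put every all-zero window *exactly*
  on the ReLU kink, a non-generic point where no numeric gradient check can
  pass and subgradient choices dominate early training.
- Max-pool backward splits the gradient equally among tied maxima. Binary
  inputs make ties systematic (constant runs), and tied entries move
  together under upstream perturbations, so the split is the directionally
  correct subgradient; routing to the first index is not.
- Sigmoid activations of strong peaks saturate to 1.0 in float64; peak
  activations are clamped into (0, 1) at 1e-12 from the boundary.
- Poisson tails come from `scipy.stats.poisson.sf`; the observed depth is
  rounded to the nearest integer.
- Degenerate inputs fail loudly: all-zero background (no rate estimate),
  label sets without positives (undefined class weight), windows smaller
  than `L`, non-finite network inputs, even-length filters.

## Known limitations

- Per-window thresholds are constant over `L/S` consecutive bins; peak
  boundaries inherit bin resolution.
- Window tiling is non-overlapping; a peak straddling a joint relies on
  joint-merging rather than being seen whole by the network.
- The Poisson background model ignores overdispersion; scores are
  comparable within a dataset, not across datasets.
- Training at the default `L = 12,000` / 16 channels is CPU-feasible but
  slow; the reduced profile is the practical desk-scale configuration.
- No peak-width refinement for narrow transcription-factor binding sites
  and no broad-domain calling mode.
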