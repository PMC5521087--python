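# Methods

## The model

`empick` classifies square boxes cut from cryo-EM micrographs as particle
(target 1) or non-particle (target 0) with an eight-layer convolutional
network: input plane, three convolutional layers (C1, C3, C5) alternating
with three average-subsampling layers (S2, S4, S6), and a fully connected
scalar output unit.

- **Convolutional layer.** Output map j is
  `X_j = f( sum_{i in M_j} X_i * W_ij + B_j )`, a *valid* cross-correlation
  with unit stride and shared kernels, followed by the activation f.  The
  connection table `M_j` defaults to full connectivity (every output map sees
  every input map); sparse tables are supported but nothing here uses them.
  `f` is the logistic sigmoid `1/(1+exp(-x))` by default; ReLU is available
  for the hidden layers, with the output unit always sigmoid so scores stay
  in (0, 1).
- **Subsampling layer.** A pure non-overlapping block average over M x N
  tiles (`1/(MN) * sum`), one output map per input map, no learnable
  parameters and no activation.  Input sides must divide evenly; the config
  validator rejects schedules where they do not.
- **Output layer.** `y = sigmoid(w . flat(X) + b)` over the flattened S6
  feature stack.

Layer geometry is specified the way such networks are tabulated: a list of
`(n_maps, map_side)` pairs for C1..S6.  Kernel sides are forced by the map
sides (`kernel = in - out + 1`) and pool sizes by their ratio
(`pool = in / out`), so a schedule is consistent by construction.  Bundled
schedules (`empick.network.SCHEDULES`) cover four published particle sizes
(272, 160, 150, 112 px) plus two reduced ones used throughout the tests:
`desk64` (64-px boxes: C1 6@56, S2 6@28, C3 12@24, S4 12@12, C5 12@8,
S6 12@4 — the same 6/12-map grammar at desk scale) and `tiny16`/`tiny8` for
fast property tests.

## Training

The objective is the squared error `E_N = 1/(2N) sum ||t_n - y_n||^2`,
minimized by explicit error back-propagation and the update
`w(t+1) = w(t) - eta * dE_N/dw` with `eta = 1` by default.  Gradients are
exact: the sigmoid derivative is taken as `y(1-y)` at each unit, a shared
kernel accumulates gradient over all of its spatial applications, and
average pooling distributes gradient uniformly with weight `1/(MN)`.  There
is no autodiff anywhere on this path; the test suite audits every gradient
component against central finite differences (step 1e-5, relative error
<= 1e-5) on a tiny eight-layer network.

Full-batch gradient descent is the default (the objective sums over the
whole set, so sample order is irrelevant); mini-batch SGD with a seeded
shuffle is available via `batch_size` and is what the synthetic end-to-end
experiments use (`batch_size=32`, `eta=3`), because it reaches the stopping
accuracy several times faster at identical data conditions.

**Initialization.** `init_network` defaults to drawing every weight and bias
uniformly from [0, 1).  That convention cannot train this architecture: with
all-positive weights, the C3 pre-activation is a sum of ~150 positive terms
with mean ~0.25 each, so the sigmoid saturates at 1.0 and the hidden
gradients vanish.  The training entry points therefore default to the
symmetric scheme, U[-a, a] with `a = 1/sqrt(fan-in)` and zero biases, which
keeps early pre-activations in the responsive range.  Both schemes are
selectable (`init="uniform01" | "symmetric"`).

**Data handling.** Each input box is standardized to zero mean and unit
variance before entering the network (raw-intensity mode via
`normalize_input=False`); without this the raw intensity scale of a
micrograph saturates the first layer.  The training set is augmented by the
three 90-degree rotations of every box (exactly a factor of four; targets
and provenance carried through).  Train and held-out sets must be disjoint
by originating boxed region, enforced by origin bookkeeping.  After each
epoch, held-out accuracy is measured with rotation-averaged scores at
threshold 0.5 (a score equal to the threshold counts as a positive — the
tie rule is tested); training stops at `target_accuracy` (default 0.95) or
`max_epochs`.  The per-epoch objective is taken from the backprop forward
passes: exact pre-update `E_N` in full-batch mode, the mean of per-batch
values in mini-batch mode.

**Recursive training-set optimization.** A first-round network separates
labeled boxes almost perfectly yet still fires on thousands of raster
windows it never saw the likes of, so picking precision starts low.  The
remedy is the feedback loop: pick a fresh micrograph, verify the picks
(against the exact synthetic ground truth here — the role a human plays
with real data; `evaluation.refresh_additions`), feed false positives back
with target 0 and missed particles with target 1
(`training.refresh_training_set`, which re-augments only the new originals
and drops duplicate origins), and retrain.  Two such rounds raise picking
precision from ~0.2 to >= 0.8 in the end-to-end test while recall stays
high.

## Recognition

A trained network raster-scans the micrograph with a configurable stride
(default 4 px; the end-to-end tests use larger strides — see problem sizes
below).  Every window is scored as the average output over its four
90-degree rotations; the four orbit scores are sorted before averaging so
the result is bit-identical for any rotated representative of the same box.
Candidates are score-grid positions that (a) clear the threshold and (b) are
the strict maximum within an `nms_radius` Chebyshev neighborhood (default
half the box side, so two accepted particles overlap by at most half a box);
exact score ties go to the earlier position in raster order.  A final filter
removes candidates whose box pixel standard deviation falls outside
`mean +/- k*sigma` (k = 2) of the pixel-std population of the micrograph's
own candidates — carbon edges and contaminants sit far above or below clean
ice — with an absolute `[lo, hi]` override; with fewer than two candidates
the relative band is undefined and the filter is a no-op.  Boxes are placed
only fully inside the micrograph; coordinates are reported on the stride
grid without sub-stride refinement.  Micrographs can be block-average binned
by an integer factor first (trailing rows/columns that do not fill a tile
are cropped).

Convolutions run as circular FFT products whose valid region is wrap-free,
so they equal the direct nested-loop computation to ~1e-13 relative error
(asserted against brute-force oracles); this is purely an implementation
choice for speed and memory, not an approximation in any practical sense.
Convolution orientation is cross-correlation (no kernel flip) — with learned
kernels the two conventions differ only by a reindexing of the parameters.

## Evaluation and threshold selection

Picks are matched one-to-one to ground-truth coordinates greedily in
descending score order; each pick claims the nearest unclaimed truth within
a tolerance (default a quarter of the box side, Euclidean distance; exact
distance ties go to the lower-index truth).  Unmatched picks are false
positives, unmatched truths false negatives.  Precision = TP/(TP+FP) and
recall = TP/(TP+FN); empty denominators (nothing picked / nothing to find)
are defined as 1.  The picking cutoff is the threshold maximizing
`F_beta = (1+beta^2) * P*R / (beta^2*P + R)` with beta = 2, which weights
recall above precision; ties go to the higher threshold (more precision at
equal F2).  `pr_curve` scans each micrograph once (the score map does not
depend on the threshold) and freezes each micrograph's pixel-std band at the
lowest threshold evaluated, which keeps the candidate sets nested as the
threshold rises — recall is then monotone non-increasing by construction.
The default threshold grid is 50 evenly spaced values in (0, 1).

## Synthetic micrographs

The generator emulates the controlled-SNR simulation regime: three smooth,
mutually distinct noise-free templates (an annular top view, a striped
barrel side view, an asymmetric multi-lobe blob — stand-ins for distinct
projection views), zero outside a circular support and unit RMS over it,
are placed at random positions and continuous rotations (bilinear
resampling) with a minimum pairwise center separation, then pixel-wise
independent zero-mean Gaussian noise is added everywhere.

**SNR definition.** SNR = (variance of the noise-free signal over particle
support pixels) / (variance of the added noise).  This is stated prominently
because alternatives (whole-image signal variance) change the scale
substantially; with this convention the generator hits the requested ratio
to well under 1% on a 1024-squared field at every level from 0.01 down to
0.001.  At SNR 0.01 the noise standard deviation is ten times the signal
RMS — individual particles are invisible by eye.

Optional contaminant patches (Poisson count with mean `contaminant_rate`,
square, 1-3 box sides wide) add a strong offset plus 3x noise, giving the
pixel-std filter realistic targets; the rate defaults to 0.  What the
generator does **not** model: CTF oscillations, ice-thickness gradients,
structured (colored) noise, particle overlap, or radiation damage — passing
the synthetic end-to-end test therefore demonstrates that the learning,
scanning and selection machinery works at realistic contrast, not that the
picker is production-ready for any real dataset.

`harvest_training_boxes` cuts all ground-truth boxes as positives and
`n_negatives` random boxes whose centers are farther than half a box side
from every particle center as negatives (seeded; an error if the exclusion
cannot be satisfied).

## Problem sizes and numerical choices

Everything runs in double precision; the gradient-check tolerance assumes
it.  The end-to-end experiments use 1024-squared micrographs, 64-px boxes,
the `desk64` schedule, 200+200 original training boxes harvested from four
micrographs at SNR 0.01 (and, as a degradation control, 0.001), two
refresh rounds of one fresh micrograph each, and two held-out micrographs
per SNR, scanned at stride 16 with match tolerance 16 px.  These sizes were
chosen so the complete pipeline runs on a single CPU core in minutes while
preserving every stage of the method; stride 16 on 64-px boxes keeps the
worst-case localization error (8 px Chebyshev) inside the matching
tolerance.  Determinism: every stochastic step (initialization, batch
shuffles, placement, noise, harvesting) flows from explicit integer seeds;
identical seeds give bit-identical micrographs, training runs and picks.

## Known limitations

- Scores concentrate near 0.5 early in training; threshold selection is
  only meaningful once training has spread them, which the refresh rounds
  accomplish.
- The pixel-std band recomputed per candidate population is sensitive to
  candidate count when a micrograph yields very few candidates; the
  absolute-range override exists for that case.
- Per-box normalization prevents running the convolutional stack once over
  the whole micrograph; scanning cost therefore grows with the number of
  stride positions, mitigated by batched FFT evaluation.
- The uniform[0,1) initialization option is retained for fidelity but is
  untrainable on deep sigmoid stacks, as explained above.
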