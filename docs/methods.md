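# Methods

## The sampling model

The package estimates a per-pixel invasive-probability field over a large
RGB image from point evaluations of a tile classifier. The estimate is a
scattered-data interpolant: tile probabilities are attributed to the tile's
centre pixel, and a piecewise-cubic Clough–Tocher interpolant over the
Delaunay triangulation of the centres extends them to every pixel. Outside
the convex hull of the samples the map takes the nearest sample's value
(constant extrapolation); cubic extrapolation is never used because it is
unbounded. The map is clipped to [0, 1] after interpolation, and the
gradient is computed on the clipped map — the clipped map is what every
consumer sees.

Acquisition treats the gradient magnitude |∇P| as an uncertainty proxy:
probability transitions concentrate at class boundaries, which is where
additional tile evaluations change the map the most. Each acquisition round
draws 2N candidates from the configured base sampler, looks |∇P| up at the
nearest stored pixel for each candidate (nearest-node lookup is
rank-equivalent to bilinear at pixel resolution and cheaper), stable-sorts
descending and keeps the first N. Ties are broken by candidate emission
order. The interpolant is cumulative: every iteration uses all samples
classified so far. With noiseless probabilities the map can only gain
information; this is also the only accounting under which a T-iteration run
classifies exactly T·N tiles.

Assumptions worth stating: the underlying field is piecewise-smooth with a
small number of connected positive regions; the classifier's tile
probability is attributable to the centre pixel (true when tile size is
small relative to region size); and classification cost dominates
interpolation cost, so the budget is counted in classifier calls.

## Samplers

* `regular` — inclusive-endpoint grid with step s; count
  (⌊span_r/s⌋+1)·(⌊span_c/s⌋+1). `dense` is step 1. (The closed form
  (K−k)² sometimes quoted for the dense count is the same quantity up to
  the ±1 boundary convention; this package enumerates inclusively.)
* `uniform` — i.i.d. integer coordinates from a seeded generator.
* `qmc_sobol` / `qmc_halton` — unscrambled sequences, no leap, index 0 (the
  origin) skipped as degenerate; unit-square points are mapped onto the
  valid-centre rectangle by flooring u·span. Unscrambled sequences are
  deterministic: runs built on them do not vary with the seed, which is a
  deliberate reproducibility choice. Both support exact continuation (the
  n-then-m draw equals the (n+m) draw), which the iterative loop relies on.
* `grad_*` — the 2N-candidate/top-N selector layered over any base above.

Duplicate centres are resolved within an iteration by continuing the
sequence until N fresh centres are found; across iterations the prediction
cache plays that role. Budget exactness (|samples| = T·N) is asserted, not
assumed.

`run_adaptive` accepts only iterative kinds; `regular`/`dense` runs go
through `run_regular`/`run_dense`, since a grid's size is fixed by its step
and the T·N accounting does not apply.

## Tile operations

Tiles are k×k (k odd, default 101) addressed by centre in 0-based
(row, col); a tile must lie fully inside the image (no padding). The
tissue filter declares a tile non-tissue iff grayscale (channel-mean)
standard deviation < 10 **and** mean > 240 — both comparisons strict, both
thresholds configurable; the intent is "homogeneous and near-white", i.e.
blank glass. Labels are positive when the masked fraction of the tile area
is ≥ 0.5 (configurable). Preprocessing converts RGB to YUV with the BT.601
full-range matrix (no named variant is canonical here; BT.601 is fixed and
documented) and standardises each channel to mean 0, variance 1 per tile,
with constant channels mapping to zero.

At prediction time tiles are classified whether or not they pass the
tissue filter (`classify_non_tissue=True` by default): the sampling budget
is the method's resource, and a tissue gate would silently change it. The
optional gate (`classify_non_tissue=False`) assigns probability 0 to
non-tissue tiles without a classifier call; the call count is reported
separately so the ledger stays exact.

## Classifiers

The softmax model minimises
L(W) = −(1/m) Σᵢ Σ_c 1{yᵢ=c} log softmax_c(W sᵢ) + (λ/2)‖W‖²_F
with the max-subtraction guard, trained by minibatch SGD (defaults:
minibatch 32, rate 0.01, 50 epochs, λ 1e-4, zero initialisation, seeded
shuffling; none of these has a canonical published value, all are exposed).
Features are standardised inside `train_sgd` (mean/scale stored with the
model): the CF statistics span several orders of magnitude and plain SGD on
the raw design diverges at any useful rate.

The 14 CF channels are R, G, B; H, S, V; L\*, a\*, b\*; Y, Cb, Cr;
channel-mean grayscale; and an optical-density-like channel
−log((gray+1)/256). The statistics are mean, standard deviation, skewness
and excess kurtosis (channel-major order), with skewness/kurtosis defined
as 0 for zero-variance channels. Only the counts (14 × 4 = 56) are
load-bearing; the membership is a documented, configurable choice.
Convolutional backends are intentionally out of scope — anything exposing
`predict_proba` over tiles plugs into the loop.

## The synthetic generator

A generated slide has three pixel populations: glass (252 ± 1.5 intensity
jitter — rejected by the default tissue filter), benign tissue (eosin-pink
mean (226, 176, 204) with σ = 12 Gaussian texture) and invasive blobs
(hematoxylin-purple mean (148, 112, 170), same texture). The tissue region
is a mildly perturbed central ellipse occupying 60 % of the frame; blobs
are ellipses with low-frequency Fourier radial perturbation (relative
amplitude `blob_irregularity`), placed fully inside the tissue without
mutual overlap, with one corrective radius rescale to land the invasive
area within ~±20 % of the target fraction.

Default geometry: 1024², 2 blobs, invasive fraction 0.25 of tissue,
irregularity 0.2. The scale is chosen so invasive regions span many tile
widths, matching the regime the method addresses (annotated invasive
regions on 32:1-downsampled slides are large relative to a 101-px tile);
under these defaults dense noiseless classification recovers the mask with
Dice > 0.95, so residual error is attributable to tile-average blur at
boundaries rather than generator artefacts.

What the generator does **not** emulate: stain physics (no optical-density
mixing), scanner artefacts, fat/stroma substructure, DCIS-like confounders,
multi-resolution pyramids. Consequently, passing tests demonstrate the
sampling machinery — budget accounting, acquisition targeting, strategy
ordering, metric correctness — not clinical detection performance on real
slides.

The ground-truth oracle classifier returns the masked fraction of the tile
footprint (integral-image box sum), optionally flipped to 1−fraction with
probability `label_noise`; flips are a counter-hash (splitmix64) of
(flip_seed, row, col), so they are deterministic per coordinate and
independent of query order and batch size.

## Evaluation harness

Confusion metrics follow the standard pixelwise definitions; ratios with a
zero denominator are reported as NaN with an `undefined` flag, never as 0.
AUC is the tie-aware Mann–Whitney formulation. The method-ranking procedure
fixes the repeated-subsample protocol at 100 groups of 60 % of instances
drawn without replacement within a group (the natural reading of "bootstrap
groups of 60 %": with replacement would duplicate instances inside a
group); methods are ranked per group, a Kruskal–Wallis H is computed on the
per-method rank samples, and Tukey's HSD criterion on the rank data gives
the pairwise significance matrix.

Strategy comparison pairs runs by (slide, seed) at matched budgets;
iterative strategies read intermediate budgets from the cumulative
per-iteration log of a single run, `regular` is swept by the step whose
grid count is closest to each budget, and `dense` is evaluated once per
slide. Gradient-QMC vs baseline ordering is tested with a one-sided paired
sign test.

## Numerical and cost choices

* Intermediate maps during a large comparison are evaluated on a coarse
  lattice (`map_grid_step`, default 1 = off; the comparison harness and the
  heavyweight tests pass 4) and bilinearly upsampled for any full-map use;
  the acquisition gradient is then computed on the lattice with the lattice
  spacing. At a 4-px step on 1024² slides this changes final Dice by < 0.01
  while cutting per-run cost ~8×. Dice is always computed at full
  resolution.
* Problem sizes used by the shipped test-and-reproduction harness: five
  1024² slides × 20 seeds for the strategy ordering, single 1024² runs for
  budget accounting and dense recovery, 512² slides for classifier
  training checks — sizes at which every stage's behaviour is already
  asymptotic while a full run of the suite stays in the minutes range.
* Degenerate interpolation inputs (< 4 centres or collinear centres) fall
  back to nearest-neighbour fill with a logged warning rather than failing.
* A probability map is exact at sample centres to 1e-6; cubic overshoot
  between nodes is expected and handled by the clip, which is part of the
  contract.
* Sign tests drop tied pairs; rank ties use average ranks.

## Known limitations

* Unscrambled QMC means no replicate variability for pure-QMC strategies;
  variance estimates for those strategies reflect slide variation only.
* The invasive-fraction target is met only to ±20 %; exact area control
  would require iterative rasterisation and no consumer needs it.
* `run_dense` with a feature classifier extracts every tile individually
  and is only practical for classifiers with a vectorised coordinate path
  (like the oracle) or small images.
* The gradient proxy targets boundaries of the *current* map; a region
  entirely missed by early exploration stays invisible until the base
  sampler's space-filling property finds it — one reason low-discrepancy
  bases dominate uniform ones in the comparisons.
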