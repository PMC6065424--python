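# Methods

This note records the model underlying the package, the parameter choices
that matter, what the synthetic phantom does and does not emulate, and the
numerical conventions, in enough detail to reproduce or challenge any design
decision.

## The spectral contrast transform

A grayscale frame, normalized to [0, 1] by acquisition bit depth, is scanned
with an odd `window x window` neighborhood centered at every pixel
(reflect-padded at borders).  Each neighborhood `X = [x_1 ... x_w]` is turned
into an unweighted, undirected graph with one node per *column*:

- kernel similarity `omega_ij = exp(-||x_i - x_j||^2 / (2 sigma^2))`;
- edge between `i != j` iff `omega_ij <= r` — edges join *dissimilar*
  columns, so a flat neighborhood is edgeless and a high-contrast one is
  densely connected.

The per-pixel contrast score `c_ij` is the Fiedler value of that graph: the
smallest eigenvalue above a zero tolerance (default `1e-8`) of the normalized
Laplacian `L = D^(-1/2)(D - S)D^(-1/2)` built on the non-isolated subgraph.
Conventions for degenerate graphs:

- isolated nodes are excluded from `L` (no `1/sqrt(0)`); an edgeless graph
  scores 0;
- for a disconnected graph the smallest *above-tolerance* eigenvalue is
  reported, not the textbook second-smallest (which would be 0).  This keeps
  the score monotone in texture at the cost of the standard algebraic-
  connectivity reading; the textbook variant is deliberately not offered.
- `lambda_2 <= 1` holds for every graph except those whose non-isolated
  subgraph is a disjoint union of cliques (a clique `K_m` contributes
  `m/(m-1)`; an isolated dissimilar pair scores 2).  These are the
  "pathological" cases of the 0-1 bound; `spectral.has_only_clique_components`
  identifies them.  Note the `n/(n-1)` upper bound applies per connected
  component, not to the node count of the whole patch.

The contrast matrix `C` is low-pass filtered with a Gaussian (default
`filter_sigma = 2` px, kernel truncated at 4 sigma) into the SFF map `F`.
Contrast change at time t is `V_t = F_t - F_0` with `F_0` the pre-injection
baseline; filtering is applied *before* subtraction, since the change map is
defined on `F`.  An ROI is quantified as the mean map value over its pixels
(the ROI sum divided by the ROI area); for an `SFFMap` the filtered `F` is
quantified.  Percent increments are taken against the frame-0 value of the
same quantifier with an `eps = 1e-9` guard; a (near-)zero reference yields a
signed-infinity sentinel plus a warning rather than a spurious number.

The whole-frame transform computes all pairwise column distances via shifted
difference images and running vertical sums, then solves all `w x w`
eigenproblems in one batched call; at 128x128 with `window = 9` one frame
takes about half a second on one CPU core.  The batched path is checked
against the literal per-pixel graph construction in the tests.

### Kernel parameters

`window = 9`, `r = 0.3`, `sigma = 0.25` by default.  `sigma` and `r` are
redundant through the edge-threshold distance `d* = sigma * sqrt(2 ln(1/r))`,
so only `sigma` was calibrated: it is set so that the *median background
patch of the pinned phantom baseline has edge density 0.5* (measured: exactly
0.50 at `sigma = 0.25`, versus 0.00 at `sigma = 0.5`).  Mid-range density
matters because a nearly edgeless background is dominated by isolated-pair
graphs that score the out-of-band value 2, turning map noise pathological;
a saturated background leaves no headroom for contrast growth.

## Motion compensation

Frame-to-frame tissue motion is modelled as rigid: rotation `theta` about
the ROI centroid followed by a translation `(dy, dx)`.  For each successive
frame pair the tracker scores every candidate on an exhaustive grid
(default: translations +-8 px in 1 px steps, rotations +-5 degrees in
0.5 degree steps) by the normalized cross-correlation between the previous
frame's tracked ROI pixels and the candidate-transformed pixels of the next
frame (bilinear sampling), and composes the winners cumulatively relative to
frame 0.  Exhaustive search was chosen over gradient refinement for
determinism.  For integer-pixel grids all shifts are scored from a single
gathered pixel neighborhood (the four bilinear corner terms are shifted
views), which makes the search fast without changing its result.

A pair whose best NCC falls below 0.2 is flagged as a tracking failure.  If
the tumor ROI's frame-0 intensity variance is below `1e-4` (on the [0, 1]
scale) it is considered featureless and the richest alternative ROI is
tracked instead, its transforms being applied to the tumor ROI — mirroring
how an operator falls back to a feature-rich region.  Tracked ROI intensity
is summarized per frame by the median (robust to a minority of outlier
pixels), min-max normalized to [0, 1]; "rise time" is defined as the first
frame reaching 90% of the peak, a definition this package fixes because the
term is otherwise ambiguous.

Rotation resolution scales with the ROI's lever arm: a half-degree step
moves the corner of a 28x28 window by ~0.17 px, below speckle-decorrelation
noise, so the recovery experiment tracks a 56x56 window.  Pairwise
composition accumulates an unbiased random walk of grid-rounding errors;
drift can be monitored via NCC against frame 0.

## Downstream analyses

*Vessel centers*: `V_t` is thresholded inside the tumor mask (default: 95th
percentile of in-mask values), cleaned by 3x3 binary opening then closing,
components smaller than 5 px discarded, and the geometric centroid of each
surviving component reported (intensity-weighted centroids by flag).

*Relative drug penetration*: each center is treated as an instantaneous
point source; the superposed 2-D Green's function
`sum_k w_k exp(-||x - x_k||^2 / (4 D_t))` is masked by the tumor boundary
and min-max normalized to [0, 1].  Only the product `D_t = D * t` (pixels^2,
default 25) enters the solution, so it is the single spread parameter.

*Group comparison*: two-sample t-tests on endpoint percent increments,
pooled-variance by default (Welch by flag), alpha = 0.05; the three-group
design runs all pairwise tests for both the spectral and the conventional
quantifier.  The conventional per-frame quantifier is the mean ROI intensity
of the motion-compensated frame (the mean of the subtraction image is
identically zero at baseline, so a relative increment on it is undefined).

## The synthetic phantom

Each frame is `clip(gain_t * warp(scene_t, T_t) + electronic_noise, 0, 1)`
with `scene_t = (tissue + sum_b amp_b(t) * profile_b + artifacts) * speckle_t`:

- **speckle**: envelope of a PSF-smoothed (sigma 1 px) complex circular
  Gaussian field — exactly Rayleigh-distributed per pixel (fully developed
  speckle, point contrast 0.52) with grain-scale spatial correlation, unit
  mean per realization.  A fraction (default 0.15) of the field is redrawn
  every frame; the rest is a static scatterer realization that moves with
  the tissue, consistent with the high frame-to-frame speckle correlation
  (~0.95) of stationary-probe cine imaging that makes speckle tracking
  possible at all;
- **accumulation**: each blob is a tapered disc whose added amplitude grows
  as `peak * (1 - exp(-rate * t))` (t in frames); frame 0 is always the
  pre-injection baseline.  Cohort analogs of the three temperature groups
  default to rates 0.01 / 0.03 / 0.06 per frame with 5 / 5 / 6 animals and a
  10% log-normal within-group rate jitter;
- **nuisances**: a static bright artifact band (skin line analog), per-frame
  multiplicative gain jitter (std 0.03) and small additive electronic noise
  (std 0.005) — the acquisition artifacts that corrupt direct pixel
  subtraction;
- **motion**: none, a fixed transform list, or a bounded integer random walk
  (default +-1 px/frame, cumulative bound 6 px; rotation optional, about the
  image center).

The pinned default acquisition (`sff/data/default_phantom.yaml`, seed 1234)
is 128x128, 40 frames at 20 f/s, one blob (radius 10 px, peak 0.35, rate
0.08), one artifact band, translation-only random walk.  Full determinism by
seed at every operation.

What the phantom does *not* emulate: beamforming and depth-dependent point
spread, attenuation and shadowing, tissue deformation (motion is rigid),
contrast-agent kinetics beyond the saturating law, and anatomical
heterogeneity.  Passing tests therefore demonstrate the pipeline's
correctness and its relative noise robustness under controlled conditions,
not clinical performance.

## Measured behavior at the pinned conditions

The experiments in `sff.experiments` (shared verbatim by the test suite and
`scripts/acceptance.py`) measure, per seed: the blob signal-to-background of
`V_final` versus the raw compensated difference image (median fold
improvement ~3x over ten seeds — the spectral map suppresses the static
band almost completely while subtraction inherits its multiplicative
noise); exact integer-translation recovery and rotation recovery within one
grid step on average; blob localization by the in-ROI argmax of `V_final`
(the compensated border margin contains resampling ghosts and is excluded,
as it would be in any real analysis).  Two properties fall short of their
aspirational rates under these noise conditions and are reported as-is by
the suite: the single-pixel argmax localization succeeds in ~85% of seeded
runs (isolated speckle-decorrelation flickers of the thresholded graphs
occasionally out-peak the blob), and the spectral quantifier's pairwise
t-tests beat the conventional ones in only about half of the reduced-size
cohort replicates — the saturating Fiedler response compresses the spread
between the two faster accumulation rates, so the spectral method's noise
advantage is offset by a smaller effect size at this scale.

## Numerical conventions

Coordinates are 0-based `(row, col)`, origin top-left; rectangles are
half-open in width/height.  Polygon ROIs are rasterized at pixel centers by
the even-odd rule.  Stacks are read from multi-page TIFF or PNG directories
(8/16-bit normalized by bit depth; float inputs must already be in [0, 1]);
maps are written as float32 TIFF; CSV output uses '.' decimals and a header
row.  Eigen-decomposition is dense (`eigvalsh`) — patch graphs never exceed
the window size.  Ties in the NCC grid search resolve to the first candidate
in deterministic grid order (rotations ascending, then row shifts, then
column shifts).
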