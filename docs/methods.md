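# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic benchmark does and does not show.

## Image model and assumptions

The pipeline assumes 2-D monolayer growth of rod-shaped (spherocylindrical)
cells: dark interiors on a bright background for phase contrast and bright
field (inverted for fluorescence-like data), approximately constant cell
width within a species, division preceded by a visible septum constriction,
and colonies that stay in focus. Frames are normalized to [0, 1] at load
(uint8/uint16 by full-scale division). When colonies pile into a third
dimension these assumptions break and segmentation quality degrades; nothing
in the pipeline detects that regime.

## Pipeline parameters

All defaults derive from four user inputs: calibration `cal_factor`
(μm/pixel), modality, expected `cell_length` and `cell_width` (μm). The
Salmonella-style defaults are 3.5 μm × 1.1 μm at 0.125 μm/pixel.

| parameter | default | units | rationale |
|---|---|---|---|
| valley threshold `t_valley` | 0.70 | width ratio | septum-to-flank width ratio at the frame before division; the usual range is 0.65–0.75 |
| point variance `point_sigma2` | 0.3 | px² | below 0.5 (half the inter-pixel distance) so point abundance tracks the distance transform instead of pooling between pixels |
| adaptive window | 1.7 × cell width | px | the local mean must track the bright ridges *between* touching cells; a window at cell-length scale averages them away and merges neighbours |
| adaptive offset | 0.05 | fraction of dynamic range | at the residual-noise scale after denoising; smaller offsets admit noise speckle as foreground |
| rolling-ball radius | 5 × cell width | px | large enough to roll over cells, small enough to track illumination |
| CLAHE | clip 0.01, 8×8 tiles | — | mild equalization; enough to restore cell contrast inside luminous local background without amplifying noise |
| watershed h-maxima | 0.5 | px | with PSF blur the distance-transform necks between end-to-end cells are shallower than 1 px; a 1 px suppression under-segments, and the design intent is over-segmentation ahead of puzzle solving |
| min fragment area `A` | ¼π(w/cal)² | px | the two pole caps of a rod; anything smaller is a fragment, not a cell |
| point budget `N` | ⌈½C·l·w/cal²⌉ | points | C/2 expected single-cell footprints; ceiling rounding (with a 1e-9 epsilon guard against float residue) |

`t_valley` can also be estimated from data: the width min/max ratio of the
largest collinear object in a pre-first-division frame, clamped to
[0.65, 0.75].

## Puzzle solving and its guards

Two touching watershed fragments merge when the union shows no deep valley
near their shared boundary. Two additional rod-plausibility guards are
applied, because the bow-tie test alone is blind to one failure mode: when
two rods lie side by side, the union's centerline runs *along* the shared
boundary and never crosses it, so no valley can appear. The guards are
(a) the union's inscribed radius (distance-transform maximum) must not
exceed 0.8 × cell width, and (b) the union's extent must not exceed
2.2 × cell length — a cell twice the expected length would have divided.
Merge preference is maximal post-merge solidity; ties go to the
smaller-area neighbour, then the lower fragment id. Each merge strictly
reduces the fragment count, so the queue terminates.

## MML mixture fitting

EM is run component-wise (one component updated per step, with incremental
renormalization) using the message-length-penalized weight update
`w_m ∝ max(0, n_m − n_par/2)` with `n_par = 5` for a 2-D full-covariance
component. A component is also annihilated when its support `n_m` falls
below `2·n_par` points: the message-length penalty vanishes as `w_m → 0`
and does not by itself prevent a component from collapsing onto a handful
of outliers with near-singular covariance. After convergence the weakest
component is forcibly removed and EM resumed; exploration stops after the
message length has worsened four consecutive levels (the optimum is
unimodal in practice), and the minimum-message-length model is returned.
Numerics: responsibilities in scaled-density space with per-sweep offset
refresh, covariance ridge 1e-4·I, convergence at relative ΔL < 1e-5 or 500
sweeps. Degenerate data (all components annihilated) falls back to a single
component.

Pixel-level regions follow from the fitted mixture: points take their
arg-max-responsibility component, pixels follow the majority of the points
they emitted (pixels that emitted none follow the component density at
their own centre), disconnected parts are split and sub-`A` parts
reabsorbed.

## Boundary refinement

Adaptive thresholding deliberately erodes cells to their dark cores, and can
pinch one cell in two where neighbours press on it. After per-object
segmentation the cores are grown back by a seeded watershed on the intensity
image over a *cell-support* mask (colony pixels darker than
`lo + 0.6·(hi − lo)`, where `lo`/`hi` are the median core and ring-background
intensities of that colony). A final merge pass rejoins region pairs whose
union is still a plausible single rod *and* whose shared boundary carries no
bright intensity ridge — the darkest fifth of the boundary is compared
against the union's interior median at a threshold of 0.22 × the colony's
contrast. The physical rationale: a completed division leaves a bright
cleavage line across the full cell width, whereas a septum constriction
(still one cell) keeps a dark waist centre. The 0.6 support quantile trades
full-extent recovery of isolated cells against support bridging in dense
interiors; the 0.22 ridge threshold sits between the measured ridge
distributions of same-cell pinches and genuine divisions on synthetic
fixtures.

## Tracking stand-in

The frame-to-frame cell tracker is a deliberately simple overlap maximizer
behind a small interface (`lineage.Tracker`), so a more sophisticated tracker
can be swapped in. Cells are matched greedily by pixel overlap after
shifting the previous frame by the colony centroid displacement; a mother
divides into the two best-overlapping daughters when their combined overlap
is ≥60% of her area with each ≥20%. Disappearance (death or leaving the
field of view) maps to a single fate, `lost`. Divisions trees contract each
life span to one node (the root plus every division-born cell).

## Growth models

* Single cell: `l(t) = l₀·e^{kt}`, nonlinear least squares initialized from
  the log-linear regression; elongation `E = ln(l_f/l₀)` (natural log, so
  that `E = k·T` is an identity under exponential growth).
* Colony counts: Baranyi–Roberts on log counts,
  `y(t) = y₀ + μ_max·A(t)`,
  `A(t) = t + (1/(nμ)) ln(e^{−nμt} + e^{−nμλ} − e^{−nμ(t+λ)})`,
  with m = 0 (no stationary-phase damping — these movies never reach
  stationary phase) and n = 20, which makes the lag-to-exponential
  transition nearly a kink at λ. The log term is evaluated via
  `logaddexp`/`log1p` to stay finite at large `nμt`. The fit runs from
  three λ starts (0, an early-time elbow, a third of the span) and keeps
  the best; gross non-monotone count series are fitted anyway but flagged.
* Life-attribute variability: gamma maximum likelihood with location fixed
  at zero (via `scipy.stats.gamma.fit(floc=0)`, equivalent to solving the
  digamma likelihood equation). Constant or non-positive samples are
  rejected as data errors.

## Synthetic movies: what they emulate, what they do not

The generator reproduces the features the segmentation method keys on:
exponential single-cell elongation with gamma-distributed rates and division
lengths (means ln2/25 min⁻¹ and 7 μm, CVs 0.15 and 0.10 — a ~25-min doubling
regime), 50/50 ± 2% division splits, septum constriction to 0.65 of the
width over the middle ~15% of the cell rendered for the pre-division frame,
repulsion-based dense packing (overlap tolerance 5% of the width), a
depth-shaded intensity model (cells darkest along the medial axis, brighter
toward the surface, a bright phase-contrast halo ring), PSF blur (σ = 1 px),
a multiplicative illumination gradient (10%), and additive Gaussian noise
(σ = 0.05 of the dynamic range). All randomness flows through one generator
keyed by the seed; identical parameters give bit-identical movies. A movie
is truncated (and flagged) when the colony reaches the image border.

Not emulated: real phase-contrast optics (shade-off, anisotropic halos),
cell motility, cell death, filamentous morphologies, 3-D stacking, focus
drift, camera fixed-pattern noise. Passing the synthetic benchmark therefore
demonstrates the algorithmic pipeline end to end against exact truth, not
performance on any particular microscope's data.

## Problem sizes

The test suite grows small movies (~25–30 cells, ~26 frames) for pipeline
and tracking fixtures, a ~500-division movie at coarser calibration for the
division-length distribution check, and the benchmark movie to ≥200 cells
(43 frames at the defaults), scoring the last five frames (~800 cell
instants). Mixture-recovery checks run 50 seeds per component count K ≤ 6;
parameter-recovery checks use 500 replicates (exponential, Baranyi–Roberts)
and n = 10⁴ (gamma).

## Known limitations

* Cells far from the expected width/length (e.g. filaments) violate the
  puzzle-solving guards and will be over-split.
* The overlap tracker assumes sampling fast relative to motion; large
  inter-frame drift beyond the colony-centroid compensation breaks it.
* The deep-valley threshold is a single global ratio; modalities whose septa
  image shallowly may need `t_valley` raised toward 0.75.
* Colony masks err outward by design (2 px dilation); colony area slightly
  overestimates the tight hull of the cells.
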