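# Methods

This note documents the models, rules and numerical choices behind each
analysis track, what the synthetic generators emulate (and what they do
not), and the design decisions that were genuinely open.

## Segmentation and aspect ratio

Images are background-subtracted with a morphological white top-hat
(structuring disc radius `background_radius_px`, default 50 px for typical
full-resolution fields; the test fixtures use 15 px for their smaller,
flat-background images). The top-hat is a deterministic stand-in for
rolling-ball background subtraction: any structure wider than the disc is
treated as background, so the radius must comfortably exceed the widest
mitochondrion. Thresholding is Otsu by default — the usual choice when no
threshold is reported — with a fixed-threshold mode for reproducibility
studies. Connected components (8-connectivity default) below
`min_object_area_px = 4` are discarded as shot noise.

The aspect ratio is the axis ratio of the ellipse with the same second
central moments as the region. Pixels are treated as unit squares, which
adds 1/12 to both diagonal moments; with this convention an axis-aligned
L×w rectangle measures exactly L/w and one-pixel-wide regions stay
non-degenerate. AR is rotation-invariant to within discretization error
(≈2 % for objects of ≥ 200 px).

## Network-morphology classification

The classical four categories are qualitative; this package makes them
rule-explicit and therefore reproducible:

| parameter | default | meaning |
|---|---|---|
| `tubular_ar_min` | 2.0 | an object is tubular when AR ≥ this |
| `class_fraction` | 0.9 | strict majority for Elongated / Fragmented |
| `hyperfused_component_fraction` | 0.75 | area share of the dominant component |
| `hyperfused_max_solidity` | 0.5 | a reticular component is sparse in its convex hull |
| `collapsed_radius_fraction` | 0.15 | clump radius as a fraction of the image diagonal |
| `collapsed_area_fraction` | 0.75 | area share that must lie inside the clump radius |

Rules are evaluated Collapsed → Hyperfused → Elongated → Fragmented →
Intermediate. Collapsed is checked first because a clumped network can
masquerade as anything through per-object statistics; Hyperfused before the
majority rules because one dominant reticular component has near-unit AR as
a whole and would otherwise read as "round". The dominant component counts
as reticular when its own AR ≥ `tubular_ar_min` or its solidity ≤ 0.5 (a
branched net fills little of its convex hull). An Intermediate fallback
exists because four explicit rules cannot be exhaustive. The AR threshold
separating tubular from round (2.0) is a judgement call exposed in config;
the classical definition does not state whether "tubular" was length-,
AR- or curvature-based.

Per-cell mean AR is the unweighted mean over objects (area weighting is a
different, also defensible choice; unweighted matches per-particle
averaging). Condition summaries report the percentage of cells per class
per replicate, then mean and SEM (sd/√n) across replicates.

## Tethering events

Detection: local maxima of the Gaussian-smoothed foci channel above
`spot_threshold`, refined to sub-pixel by intensity-weighted centroiding.
Linking: greedy nearest-neighbour within `max_link_px = 5` per frame with
gap closing over `max_gap_frames = 1`; with well-separated foci (as in the
fixtures) greedy equals optimal assignment, which a brute-force oracle
confirms on small instances. A full cost-matrix tracker is out of scope.

Event state machine: an event opens when a track's spot has ≥ 2 distinct
mitochondrial labels within `adjacency_radius_px`; at opening, one probe
pixel inside each partner is remembered. Fusion is declared when both
probes fall in the same label and stay merged for
`fusion_confirm_frames = 2` frames (guarding against transient touching);
separation when two-label adjacency is lost for more than the gap
tolerance, dated to the last adjacent frame; events still open at the last
frame are emitted as censored and excluded from duration statistics
(whether such events were counted in by-eye analyses is typically
unstated; excluding them avoids an obvious downward truncation bias).
Durations are (end − start) × dt and only events strictly longer than
`min_event_s = 15` are reported — "more than 15 s" is read as a strict
inequality, so a 15.0 s episode is excluded.

`adjacency_radius_px` defaults to 4. The junction gap between tethered
partners in the fixtures is 3 px (each partner 1.5 px from the focus) and
the focus jitters with sd 0.5 px/frame, so a 3 px radius transiently drops
one partner at ≈3σ excursions and truncates events; 4 px covers half-gap
plus 3σ of jitter while the separated configuration stays ≥ 5 px away and
is never misread as tethered.

## ER–mitochondria contacts

All geometry is in physical nanometres; no pixel calibration enters this
module. ER polylines are resampled at uniform `step_nm = 5` arc-length
steps; each sample takes its Euclidean distance to the nearest polygon
boundary (0 inside a polygon). Maximal runs of samples with distance
≤ 60 nm and a constant nearest mitochondrion become one contact each; a
run is split when the nearest mitochondrion changes so each contact
belongs to exactly one mitochondrion, matching per-mitochondrion
reporting. The per-contact GAP is the mean sampled distance over the run
(the minimum is available via `gap_reduction="min"`; which reduction
by-eye analyses used is unstated). GAP bins are half-open on the left —
[0,15), [15,30), [30,60] — because the printed ranges share endpoints; a
15 nm gap falls in the middle bin.

Coverage projects every contact sample to its nearest point on the
mitochondrial outline and takes the union of the resulting perimeter
intervals (wrap-around split at the ring origin), so overlapping ER traces
cannot push coverage past 100 %. Halving `step_nm` moves lengths and
coverage by < 1 %.

## PA-GFP fusion assay

GFP-positive pixels are those inside the mitochondrial mask whose
intensity exceeds `threshold_fraction = 0.2` of the median activated
intensity within ROI ∩ mask at t = 0 (the operational definition of
"GFP-positive area" is rarely stated; a fraction of the activated median
is robust to absolute intensity). Areas at 0, 5 and 10 min are normalized
to t = 0, so the curve starts at exactly 1 and, absent bleaching, is
non-decreasing and bounded by component area / initial activated area.
No photobleaching correction is applied; the fixtures are bleach-free.

## Synthetic data: what it emulates, what it does not

The generators produce the study conditions the analyses are verified
under, with ground truth known by construction; identical spec + seed
gives bit-identical output (one `numpy` Generator per call).

* **Morphology cells**: mixtures of round blobs (radius 5 px) and
  constant-width tubules (width 4 px, length ~N(40, 8) px) on a 256² field,
  rendered at amplitude 200 over a dark background with Gaussian PSF
  (σ = 1 px), Poisson shot noise and Gaussian read noise (sd 2). Tubules
  follow quadratic Bézier paths with the control-point offset bounded at
  0.04 × length, which keeps each tubule's moment-ellipse AR within ~5 %
  of its straight-tube value (verified at 4× supersampling; at native
  resolution pixelation adds comparable jitter). Objects are placed with
  ≥ 4 px clearance so the PSF never merges them — fixtures must not fail
  for segmentation reasons. Hyperfused cells are star-shaped tubule nets
  (arm length 0.4 × image size) holding most of the area; collapsed cells
  confine objects to a disc of radius 0.15 × image width, an operational
  stand-in for perinuclear clumping.
* **Time-lapse**: one event per grid site — two capsule mitochondria
  facing across a 3 px gap with a Gaussian focus at the junction for the
  drawn dwell (rounded to the 3 s frame grid), jittering at 0.5 px/frame.
  Fusion draws a bridge from the merge frame onward; separation widens the
  gap. Dwells that cannot complete inside the movie are redrawn
  (right-truncation) — a finite acquisition window cannot contain them,
  and with the default window the truncated tail shifts the 40 + Exp(40) s
  mean by ≈ 1 %.
* **EM scenes**: mitochondria as 720-gon circles; targeted ER segments as
  concentric arcs at the programmed stand-off (so the true GAP is the
  stand-off itself), untargeted segments far from everything. Arcs on one
  mitochondrion get disjoint angular ranges so truth coverage is a plain
  sum of projected arcs.
* **PA-GFP**: components as rectangular bars; spread fills the activated
  bar column-by-column to the requested fractions, so true normalized
  areas are exact pixel-count ratios.

None of this emulates real microscopy textures: no structured background,
out-of-focus light, motion of mitochondria between frames (beyond
programmed transitions), uneven illumination, or annotation error in the
traced geometry. Passing the recovery tests therefore demonstrates that
the measurement rules are implemented correctly and are internally
consistent — not that they are robust to every artefact of real data.

## Problem sizes and determinism

The bundled verification workloads use 25 cells per phenotype, 50 random
traced scenes, and 50–100 replicates of the two-condition tethering
experiment (23 + 18 events per replicate, 100 frames at 3 s) — sizes at
which every statistic is stable to well under its tolerance. All
randomness flows from explicit integer seeds; the pipeline stamps each
output CSV with a hash of the full configuration and reruns reproduce
outputs byte-identically.
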