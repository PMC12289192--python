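# Methods

This note documents the models, numerical choices and limitations behind
`fintrack`, in the order the pipeline runs.

## Gap-filling template tracking

The tracker assumes (i) a single focal animal, (ii) inter-frame motion of a
few pixels, and (iii) short missing segments, so that a template frozen at
the flanking anchor detection remains representative across the segment.

- **Anchors.** Per frame, the detection with confidence strictly above the
  threshold (default 0.70) wins; ties go to higher confidence, then larger
  box area, then input order. Multiple detections per frame therefore
  collapse to one — the single-animal assumption made explicit.
- **Matching.** Zero-normalized cross-correlation
  (`skimage.feature.match_template`) of the fixed anchor template against a
  search window of ±`search_radius` px around the previous box (default:
  half the anchor's characteristic length `√area`, floored at 10 px).
  Score ties (within 1e-9) are broken by smallest Euclidean displacement,
  then row-major order, making the fill bit-reproducible. The box size is
  frozen at the anchor size; sub-pixel displacement is not estimated — at
  the assay's motion scale (~3–6 px/frame) integer localization is well
  inside the PCK tolerance, and the flow stage refines the centroid anyway.
- **Midpoint rule.** For a segment `[start, end]`,
  `mid = floor((start+end)/2)`: forward tracking (from the anchor at
  `start−1`) fills `start..mid`, backward tracking fills `end..mid+1`, so
  the forward pass takes the extra frame on odd-length segments. Boundary
  segments with a single anchor are filled entirely from that side.
- **Degenerate inputs.** A zero-variance (textureless) template falls back
  to zero displacement with a warning; a template fully outside the image
  is an error; output boxes are clipped to image bounds.

## Virtual-gate geometry

- **Homology.** The vanishing point is the intersection of lines P5P6 and
  P7P8; lines parallel within |normalized cross| ≤ 1e-9 are rejected
  ("vanishing point at infinity"). μ = |ground−vp| / |top−vp| − 1 from the
  P5/P6 pair (optionally averaged with P7/P8). Manual clicks are imperfect,
  so the three points need only be collinear within 2 px (error above,
  warning above 0.5 px). The one-parameter form `x' = vp + (x−vp)/(1+μ)` is
  exact when the image plane is parallel to the two scene planes (nadir
  view) and is an approximation under camera tilt; the overhead rigs this
  targets are within a fraction of a pixel of the nadir case. Note μ may be
  negative: for a downward-looking camera the vanishing point is the nadir
  and raised points appear *further* from it, giving |top−vp| > |ground−vp|.
- **Voronoi cells.** `scipy.spatial.Voronoi` seeded by obstacle-top centers
  (radius taken as (bbox width + height)/4). Unbounded regions are
  reconstructed by extending infinite ridges 50× the seed span and are
  flagged `bounded=False`; because cells are convex, the truncated polygons
  are subsets of the true cells, so polygon arithmetic never creates false
  overlap. Two seeds are special-cased as bisector half-planes. Adjacency
  requires a shared edge of positive length (> 1e-9); cells meeting at a
  single vertex (cocircular seeds, e.g. a square grid's diagonals) are not
  adjacent — a point contact is not a traversable gap.
- **Gate length.** Default is the edge-to-edge gap
  `max(0, ‖c_i−c_j‖ − r_i − r_j)` — the physical width the animal can pass
  through; overlapping obstacles clamp to 0 with a warning. A
  center-to-center mode is available where the raw spacing is wanted.
- **Boundary gates.** A cell is "near the wall" if unbounded or poking
  outside the image. For edge-intersection tests cells are clipped to the
  frame inflated by 20% — enough to retain which projected tank edges an
  unbounded cell touches while keeping polygons finite. The imaginary
  obstacle is the perpendicular foot of the obstacle center on each
  intersecting projected edge, clamped to the edge segment (a corner
  obstacle thus gets two). Its radius is taken as zero, so the boundary
  gate length is `max(0, distance − r_obstacle)`.

## Optical-flow motion analysis

Per consecutive pair (k−1, k), flow is estimated inside the union of the
two tracked boxes inflated by 10% (motion spans both boxes). The field is
evaluated on the pixel grid of frame k — the solver is run with frame k as
reference and frame k−1 as moving image, and the vectors negated — so the
thresholded body mask sits on the frame the state is assigned to rather
than lagging one step (this halved the median centroid error on synthetic
trials). Frame 0, and any frame whose mask is empty (A = 0), falls back to
the box center with `degenerate=True`, keeping the trajectory total.

The default magnitude threshold is t = 0.1 px/frame (mask keeps `s ≥ t`);
raising t can only shrink the mask. Speed is reported as
`‖mean masked flow‖ × fps` — direction and speed derive from the same
averaged vector; the mean of magnitudes is not used because it cannot
cancel antiparallel jitter.

Two backends satisfy the flow contract: iterative Lucas–Kanade
(`skimage.registration.optical_flow_ilk`, default — fast and accurate at
this motion scale), TV-L1 for harder footage, and a brute-force
block-matching reference (exhaustive integer search, SSD, ties to the
smallest displacement) that is exact on rigid integer motion and anchors
the tests. Block matching is only valid in the window interior (no
correspondences exist inside the border margin).

## Crossing events

"The trajectory passed through a gate" is operationalized as segment
intersection: the polyline segment between consecutive centroids crossing
the gate segment (a point-on-segment condition would be measure-zero). An
optional proximity mode additionally counts centroids within ε px of the
gate. When one step segment meets several gates, events are ordered by the
intersection's position along the step, preserving the true temporal order
of near-simultaneous crossings. Repeated hits on the same gate in
consecutive frames merge into the first (centroid jitter near a gate);
separate re-crossings remain distinct events. Events carry the later frame of the pair and `time_s = frame/fps`.
A centroid on a shared Voronoi edge is attributed to the lower obstacle id.

## Evaluation metrics

PCK normalizes the centroid error by the *ground-truth* box's
characteristic length `√area` (prediction-normalization available); the
default threshold grid is 0.00–1.00 in steps of 0.02. Failure rate is
missed frames as a percentage to one decimal. Trajectory overlap reports
per-frame IoU on half-open boxes and the fraction above 0.5; per-frame
aggregation is the default (a per-trajectory aggregate can be formed from
the returned series when trials are the unit of analysis).

## Synthetic trials: what they do and do not emulate

The generator renders what the geometry and photometric assumptions
describe: a 960×720 overhead view (configurable; kept below full HD so
suites run quickly), 12 or 20 bright cylindrical obstacles with
perspective-consistent tops (μ = −0.12, vp near the image center; both the
calibration points and the rendered layout derive from the same homology,
so the geometry is self-consistent by construction), a textured two-lobed
fish (half-length 24 px, half-width 9 px) whose midline C-bends
sinusoidally at 2 Hz with 6 px amplitude — plain silhouettes would give
template matching and optical flow nothing to grip — swimming at up to
5 px/frame along a spline path repelled from obstacle discs, at 60 fps over
200 frames. Surface ripple is a traveling low-frequency intensity sinusoid
(amplitude 0.015 of full scale, wavelength 150 px, phase speed
0.08 px/frame) on the background. The detector emulation keeps a frame
with probability 0.4 (dropout 0.6, matching the ~40% high-confidence
anchor sparsity of real footage), draws kept confidences from
U(0.75, 1), jitters box corners with sd 1 px, and gives dropped frames
either nothing or a low-confidence row.

Ground truth is exact by construction: tight boxes and pixel-mass centroids
from the rendered fish mask, gates from the same geometry code as the
pipeline, and event sequences from the continuous path resampled at 10× the
frame rate.

Not emulated: occlusion of the fish by obstacles, lighting changes,
refraction, shadows, multi-animal scenes, detector false positives on
background structure, and ripple-driven apparent motion faster than the
flow threshold. Passing synthetic recovery therefore demonstrates the
correctness of the pipeline's logic and numerics under the stated
conditions, not detector-level robustness on real video.

## Problem sizes

Default synthetic trials are 200 frames at 960×720; the repeated-trial
recovery check uses 20 trials at these defaults. Oracle checks use 100
random pinhole scenes, 20 Voronoi seeds with 10,000 sample points, and 100
random flow fields.

## Known limitations

- Collinear obstacle layouts (≥ 3 seeds on one line) are not supported by
  the Voronoi backend; pseudo-random layouts never produce them.
- The template tracker does not handle in-segment appearance changes
  (rotation beyond a few degrees per frame, scale change); segments longer
  than a few tens of frames will drift.
- Flow-based centroids inherit a small bias toward the trailing edge when
  the body accelerates; at assay speeds this stays within ~2–3 px.
- Metric (mm) calibration and lens-distortion correction are out of scope;
  all quantities are in pixels and pixels/second.
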