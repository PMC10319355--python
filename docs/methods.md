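# Methods

This note documents the models, estimators, defaults and numerical choices
behind each pipeline, what the synthetic generators do and do not emulate,
and the design decisions taken where several reasonable options existed.

## Body morphometry

### Segmentation

The worm is assumed to be a single bright object on a darker background
(brightfield-like contrast, inverted if necessary). `segment_worm` applies
a global threshold (Otsu by default; an absolute value can be configured),
fills holes, removes objects below `min_area_px` (default 64 px), and
keeps the largest connected component. Three failure modes are rejected
explicitly rather than silently mis-measured: an empty mask ("no worm
found"), foreground touching the image border ("worm clipped" — the
tip-to-tip length would be truncated), and a skeleton with more than
`max_branches` (default 10) side branches ("coiled or overlapping worm" —
specimens are expected to be anesthetized and extended; untangling coiled
postures is out of scope).

Otsu assumes the background is a well-represented intensity class; images
should therefore be framed with generous background around the animal, as
real micrographs at low magnification are. The synthetic generator pads
its auto-sized frames by at least 1.2 × the maximal body radius for the
same reason.

### Midline

The binary mask is skeletonized (medial-axis thinning) and converted to an
8-connected pixel graph with Euclidean edge weights. Three cleanup steps
turn the raw skeleton into a tip-to-tip midline:

1. **Spur pruning.** Terminal branches shorter than 1.6 × the maximal
   half-width (the maximum of the mask's Euclidean distance transform)
   are removed. Such branches are artifacts of the medial-axis transform —
   diagonal corner branches at blunt body ends and boundary-noise
   whiskers — not body axis. All spur branches of a round are identified
   against the same graph state and deleted together; sequential deletion
   would demote a junction to degree 2 and let a sibling branch's walk run
   down the main axis.
2. **Longest geodesic.** The main axis is the longest weighted geodesic,
   found with a deterministic double Dijkstra sweep (farthest node from
   the lexicographically smallest node, then the farthest node from that);
   on path-like graphs this is exact, and ties break lexicographically so
   repeated runs are bit-identical.
3. **Corner-detour trimming and tip extension.** At a blunt end the medial
   axis kinks ~45° and runs into a cap corner over the last ~half-width of
   arc. Within the terminal 2.2 half-widths of each end, the local tangent
   (central difference over ±2 points) is compared with the tangent half a
   half-width further in; an angle above 25° marks the kink and the path
   beyond the pre-kink point is dropped. A genuinely curved midline
   rotates far more slowly on this scale (≲ 15° for the curvatures the
   generator produces) and is untouched. The path is then smoothed with a
   7-point moving average and each end is extended along the tangent of
   the last 5 points to the sub-pixel mask boundary, so the midline spans
   tip to tip.

Midline points are sub-pixel `(row, col)` coordinates (0-based); point 0
is the endpoint with the lexicographically smaller coordinate. No
anatomical head/tail identity is assigned — none of the outputs needs it
(the lumen module orients itself; see below).

### Length, widths, volume

*Length* is the polyline arc length divided by the calibration factor
(pixels/µm). *Width at arc position s* casts a transect perpendicular to
the local tangent (central differences over a 5-point window) and finds
the two 0.5-level crossings of the bilinearly interpolated mask, each by
linear interpolation between the last inside and first outside sample
(0.25 px steps) — sub-pixel boundaries at roughly ±0.5 px accuracy.
*Middle width* is the width at s = 0.5 (arc midpoint, not bounding-box
middle).

The *width profile* holds 31 radii (half-widths) at s = k/30. The two
boundary transects k = 0, 30 would sit exactly on the mask boundary where
a transect is degenerate, so they are evaluated 1.5 px inside the tip — a
negligible arc offset that moves the sample off the boundary's
partial-volume ramp; if even that fails the tip radius falls back to 0.
For tapering bodies the tip radii are ≈ 0 either way; for blunt-ended
bodies (e.g. a constant-radius validation cylinder) the inward nudge is
what lets the frustum sum recover the true volume instead of losing the
two end segments.

*Volume* is the 30-frustum sum
V = Σ (πh/3)(r_{i-1}² + r_{i-1}r_i + r_i²) with h = length/30. The sum is
exact for radius profiles linear within each segment (both validation
identities — cylinder and cone — are corollaries) and agrees with dense
quadrature of πr(s)² ds to ≪ 0.5% for smooth profiles of bounded
curvature.

Measured accuracy on synthetic cohorts (calibration 5 px/µm, lengths
800–1200 µm, smooth tapers, gentle bends): length within ~0.3%, mid-width
within ~0.4%, volume within ~0.5% — an order of magnitude inside the
documented contract of 2% / 5% / 10%.

## Lumen width

The intestinal lumen appears as a darker band along the midline of the
posterior body. `measure_lumen` casts perpendicular transects at two
posterior arc positions (defaults s = 0.70 and 0.85; configurable but
restricted to (0.5, 1.0)). On each transect the body cross-section is the
contiguous above-threshold run around the midline (a dark gap bounded by
body on both sides is treated as lumen, not background); the dark-band
threshold is the midpoint between the local body maximum and the lumen
floor, and the luminal width is the extent of the sub-threshold run
crossing the midline, with linearly interpolated sub-pixel edges. A
transect whose intensity dip is smaller than 15% of the body-to-background
contrast raises "no dark band" rather than returning a noise-derived
width.

Because the midline's index order is lexicographic, not anatomical, the
module orients itself: the half of the midline with lower mean intensity
(the lumen-bearing posterior) is flipped to s → 1 (`orient =
"darker-posterior"`, default; `"as-is"` trusts the given orientation).

The reported statistic is the arithmetic mean of the point widths —
identical to averaging hand-measured widths, which the manual mode (CLI
`--manual-widths`) supports directly.

## Defecation rhythm

Event logs are parsed from the BORIS aggregated-events CSV dialect
(configurable observation/time/behavior columns; case-insensitive alias
map, e.g. "posterior body contraction" → pBoc). Unknown behavior labels
are skipped with a warning count; state-event rows are collapsed to their
start time (DMP steps are point events). At identical timestamps a pBoc
sorts before other events because it delimits the cycle.

Definitions: a cycle is the interval between successive pBocs; the
per-animal mean is over the **first** 10 cycles (the consecutive-cycles
rule — not a random or trailing subset) and requires at least 10;
aBoc and expulsion frequencies are count ratios over pBoc. Exact
invariants: the cycle lengths partition the span between the first and
last pBoc; frequencies are invariant under uniform time shifts.

## Reporter assay

The tidy plate schema is `assay, plate, well, condition, construct, dose,
read_0s, read_5s`. The two 5-s reads are combined by their arithmetic mean
(policies `first` and `max` are available; mean is symmetric and
variance-reducing). Normalization is **per assay**: each collapsed well is
divided by the mean of that assay's ligand-free control wells, so the
control mean is exactly 1 and any uniform per-session gain (luminometer
drift, substrate lot) cancels exactly. Summaries first average wells
within (condition, assay), then average per-assay means across assays —
assays, not wells, are the independent replicates; SD is across assays and
is reported missing for a condition seen in a single assay. Basal receptor
activity is the per-assay ratio of mean receptor-well to mean
empty-vector-well raw luminescence (ligand-free wells only), averaged
across assays. Hypothesis testing is deliberately excluded; the outputs
are tidy tables for any stats package.

## Synthetic data: what it emulates, and what it does not

**Worm images.** A planar midline curve — a sinusoid whose x-extent is
solved (Brent's method) so the *arc length* equals the requested length
exactly, or a cubic spline through control points — swept by a circular
cross-section of radius r(s). The rendered tube is the solid of revolution
of r(s): flat-ended at the curve endpoints, with radius clamped to ≥
0.5 px so the mask stays connected at tapering tips, drawn with a 1-px
partial-volume edge ramp, an optional darker lumen band (width = fraction
of local body width, over the posterior 40% of arc by default), and
additive Gaussian noise. Rendering uses a Euclidean distance transform of
the rasterized curve followed by exact projection onto the local curve
segments — O(pixels) and sub-pixel accurate. Self-intersecting tubes and
worms that do not fit the requested frame are rejected.

Ground truth is computed **only** from the specification, never from the
rendered image: length and volume by 10⁵-sample trapezoid quadrature of
the curve and of πr(s)² ds, mid-width as 2r(0.5), lumen width as
fraction × local body width averaged over the two default measurement
positions. `rendered_mask` re-renders the noise-free mask separately as a
segmentation-area oracle.

Not emulated: 3-D posture, coiled/self-overlapping animals (rejected by
design), internal anatomy other than the lumen band, illumination
gradients, and camera noise models beyond additive Gaussian. Passing
recovery tests therefore demonstrates the geometry pipeline is unbiased on
clean extended specimens; it does not certify segmentation robustness to
uneven illumination or debris-touching-worm cases, which the QC flags and
explicit rejection errors are there to surface on real data.

**Event logs.** Cycle intervals are drawn from a normal distribution
truncated at zero (mean 50 s, SD 5 s by default — wild-type-like); the
truncation is numerically irrelevant at these defaults (5 SD from zero)
but keeps pathological parameterizations valid. aBoc/expulsion events
occur at most once per cycle with probabilities 0.9/0.95 (high, as in
healthy animals), placed at uniform fractions (0.60–0.85 and 0.88–0.98) of
the cycle — late in the cycle, as the motor program executes, though the
downstream statistics only count them. Realized intervals are returned so
recovery tests are exact, not statistical.

**Plates.** Well luminescence = baseline × true fold-change ×
lognormal(CV) with unit mean; the two reads are emitted as ±2% of the
latent value (a deterministic symmetric decay) so mean-collapse recovers
it exactly. The design defaults mirror the assay convention: triplicate
wells, 4 independent assays, 10% CV. Optional empty-vector wells at
baseline/basal-fold support the basal-activity comparison.

## Problem sizes and determinism

All generators and pipelines are deterministic under fixed seeds; cohort
helpers derive per-animal sub-seeds from one master seed. The validation
suite uses: 50 random smooth profiles for the frustum-vs-quadrature check;
20 worms at 5 px/µm (lengths 800–1200 µm) for morphometry recovery; a
5-step lumen dilation series at 4 px/µm; 1000 animals for the DMP grand
mean; and, for the end-to-end group comparison, 20 repetitions of two
20-animal cohorts differing 15% in true length, rendered at 1.5 px/µm —
sizes chosen so the full validation runs in minutes on a single CPU while
keeping every statistical bound at 3 standard errors.

## Known limitations

* Widths are measured on the binary mask, so sub-pixel accuracy depends on
  the threshold sitting near the true edge midpoint; heavily asymmetric
  intensity profiles would bias widths by up to ~1 px.
* The corner-detour trim assumes body curvature radius ≳ 2 × body radius
  near the tips; extremely curled tips at very low calibration could be
  trimmed as if they were cap corners.
* The lumen module measures a single dark band; it will reject (not
  mis-measure) bands whose contrast falls below the 15% floor, and it is
  not designed for anterior lumen or multi-band pathology.
* `mean_cycle_length` deliberately refuses logs with fewer than the
  required cycles rather than averaging what is available.
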