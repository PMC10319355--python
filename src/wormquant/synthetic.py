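"""Synthetic fixtures with analytically known ground truth.

Three generators mirror the three kinds of raw data the pipelines consume:

* tube-shaped worm images — a smooth planar midline curve swept by a
  circular cross-section of arc-position-dependent radius, rendered onto a
  calibrated pixel grid with an optional darker intestinal-lumen band and
  additive Gaussian noise. Length, mid-width and volume ground truth come
  from high-resolution quadrature of the specification itself (never from
  the rendered image), with the solid-of-revolution volume
  V = ∫ π r(s)² ds along the curve's arc length.
* behavioral event logs — pBoc times as cumulative sums of cycle intervals
  drawn from a normal distribution truncated at zero, with aBoc/expulsion
  events inserted per cycle with stated probabilities; the realized
  intervals are returned so recovery tests are exact.
* luminescence plates — per-well counts = baseline × condition fold-change
  × multiplicative lognormal noise (unit mean), emitted as the two 5-s
  reads the assay pipeline collapses.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from scipy.stats import truncnorm

from .assay import WellRecord
from .defecation import ABOC, EXP, PBOC, Event, EventLog
from .errors import GeometryError
from .morphometry import CalibratedImage

__all__ = [
    "LumenBand",
    "WormSpec",
    "WormGroundTruth",
    "EventLogSpec",
    "PlateSpec",
    "constant_radius",
    "tapered_radius",
    "linear_taper_radius",
    "generate_worm_image",
    "rendered_mask",
    "sample_worm_cohort",
    "generate_event_log",
    "generate_plate",
]

QUADRATURE_SAMPLES = 100_001  # ground-truth integration resolution
TIP_RADIUS_FLOOR_PX = 0.5  # keeps the rendered mask connected at the tips
DEFAULT_LUMEN_POSITIONS = (0.70, 0.85)  # posterior measurement transects


# ---------------------------------------------------------------------------
# radius profiles


def constant_radius(radius_um: float) -> Callable[[np.ndarray], np.ndarray]:
    """Constant cross-section radius (a cylinder when the midline is straight)."""

    def r(s):
        return np.full_like(np.asarray(s, dtype=float), radius_um)

    return r


def tapered_radius(
    max_radius_um: float, exponent: float = 0.4
) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth worm-like taper: r(s) = r_max (4 s (1-s))^exponent.

    Zero at both tips, maximal at mid-body; smaller exponents give blunter
    bodies. exponent 0.4 approximates the gently tapering adult silhouette.
    """

    def r(s):
        s = np.asarray(s, dtype=float)
        return max_radius_um * np.clip(4.0 * s * (1.0 - s), 0.0, 1.0) ** exponent

    return r


def linear_taper_radius(
    r_start_um: float, r_end_um: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Radius linear in arc position (a cone when r_end = 0)."""

    def r(s):
        s = np.asarray(s, dtype=float)
        return r_start_um + (r_end_um - r_start_um) * s

    return r


def _as_radius_fn(radius) -> Callable[[np.ndarray], np.ndarray]:
    return constant_radius(float(radius)) if np.isscalar(radius) else radius


# ---------------------------------------------------------------------------
# worm specification


@dataclass(frozen=True)
class LumenBand:
    """Darker intestinal-lumen band rendered along the posterior midline.

    ``width_fraction`` is the luminal width as a fraction of the local body
    width; ``contrast`` the intensity decrement below the body foreground;
    ``extent`` the (start, end) normalized arc range covered (posterior 40%
    of the body by default).
    """

    width_fraction: float = 0.20
    contrast: float = 12000.0
    extent: tuple[float, float] = (0.60, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.width_fraction < 1:
            raise ValueError("lumen width fraction must be in (0, 1)")
        if self.contrast <= 0:
            raise ValueError("lumen contrast must be positive")
        lo, hi = self.extent
        if not 0 <= lo < hi <= 1:
            raise ValueError("lumen extent must be an increasing subrange of [0, 1]")


@dataclass(frozen=True)
class WormSpec:
    """Geometry, optics and noise of one synthetic worm image.

    The midline is either a sinusoidal bend of exact arc length
    ``length_um`` (amplitude/waves parameters) or an explicit smooth curve
    through ``control_points_um`` (K x 2 array of (x, y) µm; overrides the
    sinusoid, and the arc length is whatever the spline gives). The
    cross-section is circular with radius ``radius_um(s)`` µm at normalized
    arc position s — a constant when a scalar is given.
    """

    length_um: float = 1000.0
    radius_um: float | Callable[[np.ndarray], np.ndarray] = 25.0
    bend_amplitude_um: float = 0.0
    bend_waves: float = 1.0
    control_points_um: np.ndarray | None = None
    pixels_per_um: float = 5.0
    image_shape: tuple[int, int] | None = None
    foreground: float = 30000.0
    background: float = 5000.0
    noise_sd: float = 800.0
    lumen: LumenBand | None = None
    seed: int = 0
    margin_px: int = 10

    def __post_init__(self) -> None:
        if not self.pixels_per_um > 0:
            raise ValueError("calibration (pixels/µm) must be > 0")
        if self.control_points_um is None and not self.length_um > 0:
            raise ValueError("worm length must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.foreground <= self.background:
            raise ValueError("foreground must exceed background")
        r = _as_radius_fn(self.radius_um)
        r0, rmid, r1 = (float(r(np.array([x]))[0]) for x in (0.0, 0.5, 1.0))
        if r0 < 0 or r1 < 0 or r0 > rmid or r1 > rmid:
            raise ValueError("tip radii must be >= 0 and <= the mid-body radius")

    # -- geometry -----------------------------------------------------------

    def curve_points_um(self, n: int) -> np.ndarray:
        """(n, 2) array of (x, y) µm along the midline, uniform in parameter."""
        if self.control_points_um is not None:
            cp = np.asarray(self.control_points_um, dtype=float)
            if cp.ndim != 2 or cp.shape[1] != 2 or len(cp) < 2:
                raise ValueError("control points must be a (K>=2, 2) array")
            chord = np.concatenate(
                [[0.0], np.cumsum(np.linalg.norm(np.diff(cp, axis=0), axis=1))]
            )
            spline = CubicSpline(chord, cp, axis=0)
            t = np.linspace(0.0, chord[-1], n)
            return spline(t)
        x_extent = self._sine_x_extent()
        x = np.linspace(0.0, x_extent, n)
        if self.bend_amplitude_um == 0:
            y = np.zeros_like(x)
        else:
            y = self.bend_amplitude_um * np.sin(2.0 * np.pi * self.bend_waves * x / x_extent)
        return np.column_stack([x, y])

    def _sine_x_extent(self) -> float:
        """x-extent giving the sinusoid the requested arc length."""
        if self.bend_amplitude_um == 0:
            return self.length_um

        def arclen(x_extent: float) -> float:
            x = np.linspace(0.0, x_extent, 4001)
            y = self.bend_amplitude_um * np.sin(2.0 * np.pi * self.bend_waves * x / x_extent)
            return float(
                np.sum(np.hypot(np.diff(x), np.diff(y)))
            )

        lo = self.length_um * 0.2
        hi = self.length_um
        if arclen(hi) > self.length_um + 1e-9:  # bent curve of x-extent L is longer than L
            return float(brentq(lambda x: arclen(x) - self.length_um, lo, hi, xtol=1e-6))
        return hi


@dataclass(frozen=True)
class WormGroundTruth:
    """Quadrature-derived truth for one :class:`WormSpec`.

    ``lumen_width_um`` is the mean true luminal width at the two default
    posterior measurement positions (s = 0.70, 0.85); None without a lumen.
    """

    length_um: float
    mid_width_um: float
    volume_um3: float
    lumen_width_um: float | None = None


def _arc_parameterization(spec: WormSpec, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Points (µm), cumulative arc (µm), normalized arc positions."""
    pts = spec.curve_points_um(n)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if arc[-1] <= 0:
        raise GeometryError("degenerate midline curve (zero length)")
    return pts, arc, arc / arc[-1]


def ground_truth(spec: WormSpec) -> WormGroundTruth:
    """Analytic ground truth by quadrature of the specification.

    Length is the curve's arc length; volume the trapezoid-rule integral of
    π r(s)² over arc length at ~1e5 samples; mid-width 2 r(0.5). Computed
    from the spec alone, independent of any rendering or pipeline code.
    """
    _, arc, s = _arc_parameterization(spec, QUADRATURE_SAMPLES)
    rfn = _as_radius_fn(spec.radius_um)
    r = np.asarray(rfn(s), dtype=float)
    volume = float(np.trapezoid(np.pi * r * r, arc))
    mid_width = 2.0 * float(rfn(np.array([0.5]))[0])
    lumen_width = None
    if spec.lumen is not None:
        pos = np.array(DEFAULT_LUMEN_POSITIONS)
        lumen_width = float(np.mean(spec.lumen.width_fraction * 2.0 * rfn(pos)))
    return WormGroundTruth(
        length_um=float(arc[-1]),
        mid_width_um=mid_width,
        volume_um3=volume,
        lumen_width_um=lumen_width,
    )


# ---------------------------------------------------------------------------
# rendering


def _render_geometry(spec: WormSpec):
    """Dense midline in pixel coordinates, per-sample radii, image shape."""
    ppu = spec.pixels_per_um
    pts_um, arc_um, s = _arc_parameterization(
        spec, max(2001, int(2 * spec.length_um * ppu) if spec.control_points_um is None else 4001)
    )
    rfn = _as_radius_fn(spec.radius_um)
    r_px = np.maximum(np.asarray(rfn(s), dtype=float) * ppu, TIP_RADIUS_FLOOR_PX)
    # (row, col) = (y, x) in pixels, shifted so the tube clears the margin
    rc = np.column_stack([pts_um[:, 1], pts_um[:, 0]]) * ppu
    lo = (rc - r_px[:, None]).min(axis=0)
    hi = (rc + r_px[:, None]).max(axis=0)
    if spec.image_shape is None:
        # pad generously so the frame keeps a realistic background fraction
        # (global thresholding assumes background-dominated micrographs)
        margin = max(spec.margin_px, int(np.ceil(1.2 * r_px.max())))
        offset = margin - lo
        shape = tuple(int(np.ceil(h + o)) + margin for h, o in zip(hi, offset))
    else:
        shape = tuple(spec.image_shape)
        # center the tube in the requested frame
        offset = (np.array(shape) - (hi - lo)) / 2.0 - lo
        if (lo + offset < 1).any() or (hi + offset > np.array(shape) - 2).any():
            raise GeometryError(
                f"worm (extent {np.round(hi - lo, 1)} px) does not fit inside "
                f"image shape {shape} with a 1-px clearance"
            )
    rc = rc + offset
    _check_self_intersection(rc, arc_um * ppu, r_px)
    return rc, s, r_px, shape


def _check_self_intersection(rc_px: np.ndarray, arc_px: np.ndarray, r_px: np.ndarray) -> None:
    """Reject tubes whose far-apart segments come closer than their radii."""
    r_max = float(r_px.max())
    spacing = max(1.0, r_max / 4.0)
    step = max(1, int(spacing / max(np.diff(arc_px).mean(), 1e-9)))
    idx = np.arange(0, len(rc_px), step)
    tree = cKDTree(rc_px[idx])
    for i, j in tree.query_pairs(r=2.0 * r_max):
        a, b = idx[i], idx[j]
        arc_sep = abs(arc_px[a] - arc_px[b])
        touch = r_px[a] + r_px[b]
        if arc_sep > 2.5 * touch and np.linalg.norm(rc_px[a] - rc_px[b]) < touch:
            raise GeometryError(
                "self-intersecting worm geometry: tube touches itself at arc "
                f"separation {arc_sep:.0f} px"
            )


def _distance_fields(spec: WormSpec):
    """Per-pixel distance to the midline and local radius, on the tube bbox.

    The tube is the solid of revolution of r(s) about the curve: it ends
    flat at the curve endpoints, so pixels beyond the tip planes carry a
    positive axial overshoot that excludes them (no spherical end caps).
    """
    rc, s, r_px, shape = _render_geometry(spec)
    r_max = float(r_px.max())
    r0 = max(int(np.floor(rc[:, 0].min() - r_max - 2)), 0)
    r1 = min(int(np.ceil(rc[:, 0].max() + r_max + 2)), shape[0] - 1)
    c0 = max(int(np.floor(rc[:, 1].min() - r_max - 2)), 0)
    c1 = min(int(np.ceil(rc[:, 1].max() + r_max + 2)), shape[1] - 1)
    box = (slice(r0, r1 + 1), slice(c0, c1 + 1))
    gshape = (r1 - r0 + 1, c1 - c0 + 1)
    n = len(rc)
    # nearest curve sample per pixel via a Euclidean distance transform on
    # the rasterized curve, then exact distance by projecting onto the
    # curve segments around that sample (sub-pixel accurate, O(pixels))
    idx_grid = np.full(gshape, -1, dtype=np.int64)
    ri = np.clip(np.round(rc[:, 0]).astype(int) - r0, 0, gshape[0] - 1)
    ci = np.clip(np.round(rc[:, 1]).astype(int) - c0, 0, gshape[1] - 1)
    idx_grid[ri, ci] = np.arange(n)
    edt, (nr, nc) = distance_transform_edt(idx_grid < 0, return_indices=True)
    k = idx_grid[nr, nc]
    band = edt <= r_max + 3.0
    grid = np.stack(
        np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"), axis=-1
    )
    P = grid[band].astype(float)
    kb = k[band]
    dist_b = np.full(len(P), np.inf)
    s_b = np.zeros(len(P))
    for off in range(-3, 3):
        ka = np.clip(kb + off, 0, n - 1)
        k2 = np.clip(kb + off + 1, 0, n - 1)
        A, B = rc[ka], rc[k2]
        AB = B - A
        L2 = np.einsum("ij,ij->i", AB, AB)
        t = np.einsum("ij,ij->i", P - A, AB) / np.maximum(L2, 1e-12)
        t = np.clip(np.where(L2 > 0, t, 0.0), 0.0, 1.0)
        Q = A + t[:, None] * AB
        d = np.hypot(P[:, 0] - Q[:, 0], P[:, 1] - Q[:, 1])
        better = d < dist_b
        dist_b[better] = d[better]
        s_b[better] = (s[ka] + t * (s[k2] - s[ka]))[better]
    dist = np.full(gshape, r_max + 3.0)
    s_near = np.zeros(gshape)
    dist[band] = dist_b
    s_near[band] = s_b
    r_loc = np.maximum(
        np.asarray(_as_radius_fn(spec.radius_um)(s_near), dtype=float) * spec.pixels_per_um,
        TIP_RADIUS_FLOOR_PX,
    )
    overshoot = np.full(gshape, -1.0)  # <= -0.5 means fully inside axially
    over_b = np.full(len(P), -1.0)
    for end_sel, end_idx, into in ((kb <= 3, 0, rc[1] - rc[0]),
                                   (kb >= n - 4, n - 1, rc[-2] - rc[-1])):
        if end_sel.any():
            t_out = -into / np.linalg.norm(into)  # unit tangent pointing past the tip
            over_b[end_sel] = (P[end_sel] - rc[end_idx]) @ t_out
    overshoot[band] = over_b
    return shape, box, dist, s_near, r_loc, overshoot


def rendered_mask(spec: WormSpec) -> np.ndarray:
    """Noise-free boolean tube mask (the segmentation area oracle)."""
    shape, box, dist, _, r_loc, overshoot = _distance_fields(spec)
    mask = np.zeros(shape, dtype=bool)
    mask[box] = (dist <= r_loc) & (overshoot <= 0)
    return mask


def generate_worm_image(spec: WormSpec) -> tuple[CalibratedImage, WormGroundTruth]:
    """Render a worm micrograph and return it with its analytic ground truth.

    The tube body is drawn with a one-pixel linear edge ramp (partial-volume
    boundary); the optional lumen band is a darker stripe of width
    ``width_fraction`` × local body width over the posterior arc extent.
    Additive Gaussian noise (``noise_sd``) is drawn from the spec seed, so
    two seeds share identical ground truth but different noise.
    """
    truth = ground_truth(spec)
    shape, box, dist, s_near, r_loc, overshoot = _distance_fields(spec)
    img = np.full(shape, spec.background, dtype=float)
    # soft 1-px boundary: fraction of the pixel inside the tube
    coverage = np.clip(r_loc - dist + 0.5, 0.0, 1.0)
    coverage = np.minimum(coverage, np.clip(0.5 - overshoot, 0.0, 1.0))
    tile = spec.background + (spec.foreground - spec.background) * coverage
    if spec.lumen is not None:
        lum = spec.lumen
        half = lum.width_fraction * r_loc
        in_extent = (s_near >= lum.extent[0]) & (s_near <= lum.extent[1])
        lumen_cov = np.clip(half - dist + 0.5, 0.0, 1.0) * in_extent
        tile = tile - lum.contrast * lumen_cov
    img[box] = tile
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    image = CalibratedImage(
        pixels=img, pixels_per_um=spec.pixels_per_um, source=f"synthetic-seed{spec.seed}"
    )
    return image, truth


def sample_worm_cohort(
    n: int,
    seed: int,
    length_range_um: tuple[float, float] = (800.0, 1200.0),
    mid_radius_range_um: tuple[float, float] = (20.0, 30.0),
    bend_amplitude_range_um: tuple[float, float] = (20.0, 80.0),
    pixels_per_um: float = 5.0,
    taper_exponent: float = 0.4,
    lumen: LumenBand | None = None,
    noise_sd: float = 800.0,
) -> list[WormSpec]:
    """Draw a cohort of smoothly varying worm specs (one animal per spec).

    Lengths, mid-body radii and bend amplitudes are uniform over the given
    ranges; each spec gets its own sub-seed so noise realizations are
    independent but the whole cohort is reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        specs.append(
            WormSpec(
                length_um=float(rng.uniform(*length_range_um)),
                radius_um=tapered_radius(float(rng.uniform(*mid_radius_range_um)), taper_exponent),
                bend_amplitude_um=float(rng.uniform(*bend_amplitude_range_um)),
                bend_waves=1.0,
                pixels_per_um=pixels_per_um,
                noise_sd=noise_sd,
                lumen=lumen,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# behavioral event logs


@dataclass(frozen=True)
class EventLogSpec:
    """Ground-truth parameters of one simulated animal's DMP log.

    Cycle intervals are normal(mean, sd) truncated at zero; wild-type
    cycles are tightly clustered around ~50 s, which a mildly dispersed
    truncated normal emulates. aBoc/expulsion events occur at most once per
    cycle with the given probabilities, placed inside the cycle interval.
    """

    mean_period_s: float = 50.0
    period_sd_s: float = 5.0
    n_cycles: int = 10
    aboc_probability: float = 0.9
    expulsion_probability: float = 0.95
    seed: int = 0
    animal: str = "sim-0"

    def __post_init__(self) -> None:
        if not self.mean_period_s > 0:
            raise ValueError("mean period must be > 0")
        if self.period_sd_s < 0:
            raise ValueError("period sd must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("need at least 1 cycle")
        for p in (self.aboc_probability, self.expulsion_probability):
            if not 0 <= p <= 1:
                raise ValueError("event probabilities must be in [0, 1]")


def generate_event_log(spec: EventLogSpec) -> tuple[EventLog, np.ndarray]:
    """Simulate one animal's event log; returns (log, realized intervals)."""
    rng = np.random.default_rng(spec.seed)
    if spec.period_sd_s == 0:
        intervals = np.full(spec.n_cycles, spec.mean_period_s)
    else:
        a = (0.0 - spec.mean_period_s) / spec.period_sd_s
        intervals = truncnorm.rvs(
            a, np.inf, loc=spec.mean_period_s, scale=spec.period_sd_s,
            size=spec.n_cycles, random_state=rng,
        )
    pboc_times = np.concatenate([[0.0], np.cumsum(intervals)])
    events = [Event(time_s=float(t), label=PBOC, animal=spec.animal) for t in pboc_times]
    for i in range(spec.n_cycles):
        t0, dt = pboc_times[i], intervals[i]
        if rng.random() < spec.aboc_probability:
            events.append(
                Event(time_s=float(t0 + rng.uniform(0.60, 0.85) * dt), label=ABOC,
                      animal=spec.animal)
            )
        if rng.random() < spec.expulsion_probability:
            events.append(
                Event(time_s=float(t0 + rng.uniform(0.88, 0.98) * dt), label=EXP,
                      animal=spec.animal)
            )
    events.sort(key=lambda e: (e.time_s, {PBOC: 0, ABOC: 1, EXP: 2}[e.label]))
    return EventLog(animal=spec.animal, events=tuple(events)), intervals


# ---------------------------------------------------------------------------
# luminescence plates


@dataclass(frozen=True)
class PlateSpec:
    """Design of a simulated reporter-assay experiment.

    ``conditions`` lists (label, true fold-change over the ligand-free
    control); the control itself (fold 1) is added automatically under
    ``control_label`` if absent. Wells get multiplicative lognormal noise
    of the given coefficient of variation with unit mean.
    ``empty_vector_basal_fold`` optionally adds ligand-free empty-vector
    wells whose mean is control/fold — the basal-activity comparison group.
    """

    conditions: tuple = (("ligand", 3.0),)
    control_label: str = "control"
    wells_per_condition: int = 3
    n_assays: int = 4
    cv: float = 0.10
    baseline: float = 10000.0
    seed: int = 0
    empty_vector_basal_fold: float | None = None

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.baseline < 0:
            raise ValueError("baseline luminescence must be >= 0")
        if self.wells_per_condition < 1 or self.n_assays < 1:
            raise ValueError("need at least one well and one assay")
        folds = dict(self.conditions)
        if self.control_label in folds and folds[self.control_label] != 1.0:
            raise ValueError("the control condition must have fold-change 1")
        if any(f < 0 for f in folds.values()):
            raise ValueError("fold-changes must be >= 0")

    def true_folds(self) -> dict[str, float]:
        folds = {self.control_label: 1.0}
        folds.update(dict(self.conditions))
        return folds


def generate_plate(spec: PlateSpec) -> tuple[list[WellRecord], dict[str, float]]:
    """Simulate a multi-assay plate experiment; returns (wells, true folds).

    Each well's latent luminescence is baseline × fold × lognormal(CV)
    with unit-mean noise, split into two reads (0 s slightly above, 5 s
    slightly below — a 2% symmetric decay) whose mean is exactly the
    latent value.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = float(np.sqrt(np.log1p(spec.cv**2)))
    folds = spec.true_folds()

    def noise() -> float:
        if sigma == 0:
            return 1.0
        return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))

    wells: list[WellRecord] = []
    for a in range(1, spec.n_assays + 1):
        for label, fold in folds.items():
            for w in range(1, spec.wells_per_condition + 1):
                lum = spec.baseline * fold * noise()
                wells.append(
                    WellRecord(
                        assay=f"assay-{a}",
                        plate=f"plate-{a}",
                        well=f"{label}-{w}",
                        condition=label,
                        construct="receptor",
                        read_0s=1.02 * lum,
                        read_5s=0.98 * lum,
                    )
                )
        if spec.empty_vector_basal_fold is not None:
            for w in range(1, spec.wells_per_condition + 1):
                lum = spec.baseline / spec.empty_vector_basal_fold * noise()
                wells.append(
                    WellRecord(
                        assay=f"assay-{a}",
                        plate=f"plate-{a}",
                        well=f"empty-{w}",
                        condition=spec.control_label,
                        construct="empty",
                        read_0s=1.02 * lum,
                        read_5s=0.98 * lum,
                    )
                )
    return wells, folds
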