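"""Fiber-level collagen morphometry.

This module plays the role the CT-FIRE / CurveAlign tools play in a
microscopy workflow, with a transparent, testable tracer in place of their
curvelet machinery:

* gland/stroma segmentation of a two-channel image (glands are
  autofluorescent tissue that is locally SHG-sparse);
* individual fiber tracing on the SHG channel — ridge smoothing,
  thresholding, skeletonization, branch-point splitting and gap linking —
  with per-point widths from the Euclidean distance transform;
* per-fiber metrics (length, straightness, width, orientation), bulk
  orientation coherence from the structure tensor, and the acute angle of
  each fiber to the nearest tumor-gland boundary;
* across-fiber means filling the morphology fields of a FeatureVector.

Orientations are axial ([0, 180) degrees, measured from the +col axis);
fiber-to-boundary angles are folded to [0, 90].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor
from skimage.measure import find_contours, label
from skimage.morphology import disk, skeletonize

from ._angles import axial_difference, principal_axis_deg, wrap_axial
from .content import FeatureVector
from .prep import MPMImage, _remove_small, threshold_channel, tissue_mask


@dataclass(frozen=True)
class Fiber:
    """One traced collagen fiber."""

    points: np.ndarray        # (n, 2) ordered (row, col) pixel coordinates
    widths_px: np.ndarray     # per-point full-width estimates (pixels)
    pixel_size_um: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(pts) < 2:
            raise ValueError("a fiber needs >= 2 points")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "widths_px",
                           np.asarray(self.widths_px, dtype=float))

    @property
    def length_px(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))

    @property
    def length_um(self) -> float:
        return self.length_px * self.pixel_size_um

    @property
    def mean_width_px(self) -> float:
        """Mean width over interior points (endpoints bias widths low)."""
        w = self.widths_px[1:-1] if len(self.widths_px) > 4 else self.widths_px
        return float(np.mean(w))

    @property
    def mean_width_um(self) -> float:
        return self.mean_width_px * self.pixel_size_um

    @property
    def orientation_deg(self) -> float:
        return principal_axis_deg(self.points)

    @property
    def straightness(self) -> float:
        return fiber_straightness(self)


def fiber_straightness(fiber: Fiber) -> float:
    """Endpoint (chord) distance over arc length, clipped to (0, 1]."""
    arc = fiber.length_px
    if arc == 0:
        raise ValueError("zero arc length")
    chord = float(np.linalg.norm(fiber.points[-1] - fiber.points[0]))
    return float(np.clip(chord / arc, np.finfo(float).tiny, 1.0))


@dataclass(frozen=True)
class TracerParams:
    """Knobs of the fiber tracer; defaults were set on phantom recoveries.

    ``halfmax_width`` rescales the raw distance-transform radius to a
    full-width-at-half-maximum under a Gaussian cross-section model, so
    reported widths estimate the fiber's physical width rather than the
    width of its thresholded footprint (which depends on the threshold).
    """

    ridge_sigma_px: float = 2.0
    min_fiber_length_px: float = 15.0
    link_max_gap_px: float = 8.0
    link_max_angle_deg: float = 20.0
    halfmax_width: bool = True

    def __post_init__(self) -> None:
        for name in ("ridge_sigma_px", "min_fiber_length_px",
                     "link_max_gap_px", "link_max_angle_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BoundarySet:
    """Gland/stroma interfaces: the gland mask and its boundary contours."""

    contours: list[np.ndarray]    # closed (n, 2) polylines in (row, col)
    gland_mask: np.ndarray
    stroma_mask: np.ndarray | None = None


@dataclass(frozen=True)
class GlandSegmentationConfig:
    """Gland detection: tissue regions locally free of SHG signal.

    A pixel belongs to a gland when a disk of radius ``open_radius_px``
    fits around it inside the SHG-void (tissue minus SHG foreground) —
    a morphological opening. The radius must exceed the typical fiber-free
    gap of the stroma but stay below the gland caliber.
    """

    open_radius_px: int = 12
    min_gland_area_px: int = 2000
    min_shg_object_px: int = 5
    tissue_method: str = "otsu"
    tissue_value: float | None = None
    shg_method: str = "otsu"
    shg_value: float | None = None


def segment_glands(image: MPMImage,
                   config: GlandSegmentationConfig = GlandSegmentationConfig()
                   ) -> BoundarySet:
    """Segment gland vs. stroma from the two channels.

    Glands are SHG-free voids in otherwise fibrous tissue: the SHG
    foreground (isolated noise specks removed) is subtracted from the
    tissue mask and the remaining void is morphologically opened with a
    disk of ``open_radius_px``, which erases inter-fiber stromal gaps but
    preserves gland-sized voids with crisp borders, then hole-filled and
    area-filtered. Contours follow the gland-mask border; stroma is
    tissue minus glands. An image with no SHG signal anywhere classifies
    essentially all tissue as gland and raises a warning.
    """
    tissue = tissue_mask(image.channel_g, method=config.tissue_method,
                         value=config.tissue_value)
    if not tissue.any():
        raise ValueError("no tissue")

    try:
        shg_fg = threshold_channel(image.channel_r, method=config.shg_method,
                                   value=config.shg_value, mask=tissue)
    except ValueError:
        shg_fg = np.zeros_like(tissue)
    if not shg_fg.any():
        warnings.warn("no stromal SHG: the entire tissue may classify as gland",
                      RuntimeWarning, stacklevel=2)
    shg_fg = _remove_small(shg_fg, config.min_shg_object_px)

    void = tissue & ~shg_fg
    gland = ndimage.binary_opening(void, structure=disk(config.open_radius_px))
    gland = ndimage.binary_fill_holes(gland)
    gland = _remove_small(gland, config.min_gland_area_px)
    # trim the sliver where the opening disk leaks over the tissue border
    gland &= ndimage.binary_erosion(tissue, structure=disk(2))

    contours = find_contours(gland.astype(float), 0.5)
    return BoundarySet(contours=contours, gland_mask=gland,
                       stroma_mask=tissue & ~gland)


# ---------------------------------------------------------------------------
# Skeleton tracing
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                     (0, 1), (1, -1), (1, 0), (1, 1)]


def _order_path(coords: np.ndarray) -> np.ndarray | None:
    """Order the pixels of a simple skeleton path from one end to the other."""
    coord_set = {tuple(p) for p in coords}
    neighbors = {p: [q for q in ((p[0] + dr, p[1] + dc)
                                 for dr, dc in _NEIGHBOR_OFFSETS)
                     if q in coord_set] for p in coord_set}
    endpoints = [p for p, nb in neighbors.items() if len(nb) <= 1]
    start = min(endpoints) if endpoints else min(coord_set)  # cycles: arbitrary cut
    path, prev, cur = [start], None, start
    while True:
        nxt = [q for q in neighbors[cur] if q != prev and q not in path[-3:-1]]
        nxt = [q for q in nxt if q not in path]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        path.append(cur)
    if len(path) < 2:
        return None
    return np.array(path, dtype=float)


def _end_direction(points: np.ndarray, at_start: bool, window: int = 5) -> float:
    """Local orientation (axial, degrees) of a polyline end."""
    seg = points[:window + 1] if at_start else points[-(window + 1):]
    if len(seg) < 2:
        return 0.0
    d = seg[-1] - seg[0] if not at_start else seg[0] - seg[-1]
    return float(wrap_axial(np.rad2deg(np.arctan2(d[0], d[1]))))


def _skeleton_segments(skeleton: np.ndarray) -> list[np.ndarray]:
    """Split a skeleton at branch points and return ordered pixel paths."""
    neighbor_count = ndimage.convolve(skeleton.astype(np.uint8),
                                      np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]),
                                      mode="constant")
    simple = skeleton & (neighbor_count <= 2)
    labeled, n = label(simple, connectivity=2, return_num=True)
    segments = []
    for idx in range(1, n + 1):
        path = _order_path(np.argwhere(labeled == idx))
        if path is not None:
            segments.append(path)
    return segments


def _link_segments(segments: list[np.ndarray], max_gap: float,
                   max_angle: float) -> list[np.ndarray]:
    """Greedily join segment ends that are close and near-collinear.

    Candidate end pairs are sorted by angular difference then gap
    distance (the tie-break); each endpoint is used at most once. Joined
    segments become a single polyline spanning the gap.
    """
    ends = []  # (segment index, end flag: 0 = start, 1 = end, point, direction)
    for i, seg in enumerate(segments):
        ends.append((i, 0, seg[0], _end_direction(seg, True)))
        ends.append((i, 1, seg[-1], _end_direction(seg, False)))

    candidates = []
    for a in range(len(ends)):
        for b in range(a + 1, len(ends)):
            ia, _, pa, da = ends[a]
            ib, _, pb, db = ends[b]
            if ia == ib:
                continue
            gap = float(np.linalg.norm(pa - pb))
            if gap > max_gap:
                continue
            dang = float(axial_difference(da, db))
            if dang >= max_angle:
                continue
            candidates.append((dang, gap, a, b))
    candidates.sort(key=lambda t: (t[0], t[1]))

    # chains of points; each original end descriptor maps to the chain it
    # currently terminates (or None once consumed or interior)
    chains: dict[int, np.ndarray] = {i: seg for i, seg in enumerate(segments)}
    chain_ends: dict[int, tuple[int, int]] = {i: (2 * i, 2 * i + 1)
                                              for i in chains}   # (head, tail)
    end_location: dict[int, tuple[int, str]] = {}
    for i in chains:
        end_location[2 * i] = (i, "head")
        end_location[2 * i + 1] = (i, "tail")

    for _, _, a, b in candidates:
        if a not in end_location or b not in end_location:
            continue
        ca, side_a = end_location[a]
        cb, side_b = end_location[b]
        if ca == cb:
            continue
        pts_a, pts_b = chains[ca], chains[cb]
        head_a, tail_a = chain_ends[ca]
        head_b, tail_b = chain_ends[cb]
        if side_a == "head":                    # joined end must be A's tail
            pts_a = pts_a[::-1]
            head_a, tail_a = tail_a, head_a
        if side_b == "tail":                    # joined end must be B's head
            pts_b = pts_b[::-1]
            head_b, tail_b = tail_b, head_b
        merged = np.vstack([pts_a, pts_b])
        chains[ca] = merged
        chain_ends[ca] = (head_a, tail_b)
        del chains[cb], chain_ends[cb]
        # the two joined ends disappear; the two surviving ends now belong
        # to the merged chain
        end_location.pop(a)
        end_location.pop(b)
        end_location[head_a] = (ca, "head")
        end_location[tail_b] = (ca, "tail")
    return list(chains.values())


def trace_fibers(shg: np.ndarray, mask: np.ndarray,
                 params: TracerParams = TracerParams(),
                 pixel_size_um: float = 1.0) -> list[Fiber]:
    """Trace individual fibers on the SHG channel within ``mask``.

    Pipeline: Gaussian ridge smoothing -> Otsu threshold within the mask ->
    skeletonization -> branch-point splitting -> pruning of short segments
    -> greedy gap linking -> per-point widths as twice the Euclidean
    distance transform of the foreground at the skeleton. An empty result
    is a valid outcome (e.g. collagen-free stroma).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    raw = np.asarray(shg, dtype=float)
    smoothed = ndimage.gaussian_filter(raw, params.ridge_sigma_px)
    try:
        from skimage.filters import threshold_otsu
        thr = float(threshold_otsu(smoothed[mask]))
    except ValueError:
        return []
    fg = (smoothed > thr) & mask
    if not fg.any():
        return []

    skeleton = skeletonize(fg)
    segments = [s for s in _skeleton_segments(skeleton)
                if _arc_length(s) >= params.min_fiber_length_px]
    linked = _link_segments(segments, params.link_max_gap_px,
                            params.link_max_angle_deg)

    # widths from the raw image at the same threshold: the EDT radius is the
    # half-width of the ridge at intensity thr; under a Gaussian cross-section
    # with peak p this rescales to FWHM by sqrt(ln 2 / ln(p / thr))
    fg_raw = (raw > thr) & mask
    edt_raw = ndimage.distance_transform_edt(fg_raw)
    edt_smooth = ndimage.distance_transform_edt(fg)
    peaks = ndimage.maximum_filter(raw, size=3)
    fibers = []
    for path in linked:
        if _arc_length(path) < params.min_fiber_length_px or len(path) < 2:
            continue
        rr = path[:, 0].astype(int)
        cc = path[:, 1].astype(int)
        base = edt_raw[rr, cc]
        # skeleton points outside the raw footprint (noise dips) fall back to
        # the smoothed footprint's radius
        widths = 2.0 * np.where(base > 0, base, edt_smooth[rr, cc])
        if params.halfmax_width and thr > 0:
            p = peaks[rr, cc]
            log_ratio = np.log(np.maximum(p / thr, 1.0 + 1e-6))
            # cap the upscaling at 2x for points barely above threshold
            factor = np.sqrt(np.log(2.0) / np.maximum(log_ratio, np.log(2.0) / 4.0))
            widths = widths * factor
        fibers.append(Fiber(points=path, widths_px=np.maximum(widths, 1.0),
                            pixel_size_um=pixel_size_um))
    return fibers


def _arc_length(path: np.ndarray) -> float:
    if len(path) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# Coherence and boundary angles
# ---------------------------------------------------------------------------

def compute_coherence(shg: np.ndarray, mask: np.ndarray,
                      sigma_px: float = 2.0) -> float:
    """Structure-tensor orientation coherence over the mask, in [0, 1].

    The local structure tensor (gradient outer product, Gaussian-averaged
    at ``sigma_px``) is summed over the mask — an average weighted by
    gradient energy — and the coherence of the summed tensor,
    (l1 - l2) / (l1 + l2), is returned. 1 means a single dominant
    orientation; 0 an isotropic gradient field.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    img = np.asarray(shg, dtype=float)
    if np.ptp(img[mask]) == 0:
        raise ValueError("no gradient energy: image is constant in mask")
    axx, axy, ayy = structure_tensor(img, sigma=sigma_px, order="rc")
    sxx, sxy, syy = axx[mask].sum(), axy[mask].sum(), ayy[mask].sum()
    trace = sxx + syy
    if trace <= 0:
        raise ValueError("no gradient energy: image is constant in mask")
    return float(np.sqrt((sxx - syy) ** 2 + 4.0 * sxy ** 2) / trace)


def fiber_boundary_angle(fiber: Fiber, boundaries: BoundarySet,
                         tangent_window: int = 5) -> float:
    """Acute angle between a fiber and the nearest tumor-gland boundary.

    The boundary point closest to the fiber midpoint is found across all
    contours; the boundary tangent is estimated over a +/- ``tangent_window``
    point window (wrapping around closed contours); the result is the
    axial difference between the fiber orientation and that tangent,
    folded to [0, 90] degrees. With no boundary present the feature is
    missing (NaN).
    """
    if not boundaries.contours:
        return float("nan")
    midpoint = fiber.points[len(fiber.points) // 2]

    best = (np.inf, None, None)
    for contour in boundaries.contours:
        d = np.linalg.norm(contour - midpoint, axis=1)
        j = int(np.argmin(d))
        if d[j] < best[0]:
            best = (d[j], contour, j)
    _, contour, j = best
    n = len(contour)
    closed = bool(np.allclose(contour[0], contour[-1])) and n > 2
    if closed:
        lo = contour[(j - tangent_window) % (n - 1)]
        hi = contour[(j + tangent_window) % (n - 1)]
    else:
        lo = contour[max(j - tangent_window, 0)]
        hi = contour[min(j + tangent_window, n - 1)]
    t = hi - lo
    if np.allclose(t, 0):
        return float("nan")
    tangent_deg = wrap_axial(np.rad2deg(np.arctan2(t[0], t[1])))
    return float(axial_difference(fiber.orientation_deg, tangent_deg))


def summarize_fibers(fibers: list[Fiber],
                     angles: list[float] | None = None) -> FeatureVector:
    """Across-fiber means of width, length, straightness and boundary angle.

    An empty fiber list leaves every morphology field missing; boundary
    angles that are missing (no boundary) are excluded from the mean.
    """
    if not fibers:
        return FeatureVector()
    width = float(np.mean([f.mean_width_um for f in fibers]))
    length = float(np.mean([f.length_um for f in fibers]))
    straight = float(np.mean([fiber_straightness(f) for f in fibers]))
    angle = float("nan")
    if angles:
        finite = [a for a in angles if np.isfinite(a)]
        if finite:
            angle = float(np.mean(finite))
    return FeatureVector(fiber_width_um=width, fiber_length_um=length,
                         fiber_straightness=straight, fiber_angle_deg=angle)
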