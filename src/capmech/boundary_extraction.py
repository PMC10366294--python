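"""Image-processing chain: camera frame -> 1D membrane-node feature vector.

The chain mirrors what a microfluidic characterisation rig does per frame:

1. ``preprocess`` — background subtraction, binarisation, largest connected
   component, centring into a square region of interest one tube diameter
   wide;
2. ``trace_boundary`` — ordered counter-clockwise border following on the
   binary component (Moore-neighbour tracing with Jacob's stopping
   criterion);
3. ``smooth_and_resample`` — piecewise local quadratic least-squares
   smoothing of the staircase pixel border, followed by equal arc-length
   resampling into a fixed number of membrane nodes in tube-radius units;
4. ``to_feature_vector`` — canonical start node and orientation, interleaved
   ``(x1, y1, x2, y2, ...)`` coordinates, centroid-centred.

All pixel work uses 0-based indices with a pixel-centre convention, and the
image row axis is flipped to the mathematical y axis before any orientation
logic, so "counter-clockwise" has its usual mathematical meaning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .profile_synthesis import CapsuleImage, CapsuleProfile

__all__ = [
    "FeatureVector",
    "BoundaryTrace",
    "preprocess",
    "trace_boundary",
    "smooth_and_resample",
    "to_feature_vector",
    "profile_from_vector",
    "extract_profile",
    "read_image",
]


@dataclass
class FeatureVector:
    """Flat interleaved node coordinates (x1, y1, x2, y2, ...), centred."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size % 2 != 0 or v.size < 6:
            raise ValueError("feature vector length must be even and >= 6")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.size // 2

    def profile(self) -> CapsuleProfile:
        return CapsuleProfile(self.values.reshape(-1, 2))


@dataclass
class BoundaryTrace:
    """Ordered counter-clockwise border pixels in mathematical (x, y) coords.

    ``roi_side`` (when the trace came from a RoI grid) records the grid side
    in pixels, which fixes the pixels-per-tube-radius scale (side / 2).
    """

    points: np.ndarray
    roi_side: Optional[int] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("trace must contain at least 3 points")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


def read_image(path: Union[str, Path]) -> np.ndarray:
    """Read a grayscale PNG/TIFF image as a float array."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # collapse RGB(A) to luminance
        arr = arr[..., :3].mean(axis=-1)
    return arr


def preprocess(
    image: Union[CapsuleImage, np.ndarray],
    background: Union[CapsuleImage, np.ndarray, None],
    tube_diameter_px: int,
    threshold_rule: Union[str, float] = "otsu",
) -> np.ndarray:
    """Binarise and centre the capsule into a square RoI.

    With a background frame, the absolute difference image is thresholded
    (Otsu by default, or a fixed numeric threshold), which makes the result
    invariant to a common illumination offset. Without one, the image itself
    is thresholded and the minority phase is taken as the capsule. The
    largest 8-connected foreground component is kept and shifted so that its
    centroid lands on the centre pixel of a ``tube_diameter_px`` square grid.
    """
    img = image.pixels if isinstance(image, CapsuleImage) else np.asarray(image, float)
    if background is not None:
        bg = (background.pixels if isinstance(background, CapsuleImage)
              else np.asarray(background, float))
        if bg.shape != img.shape:
            raise ValueError("image and background must have the same shape")
        work = np.abs(img - bg)
        if isinstance(threshold_rule, str):
            if threshold_rule != "otsu":
                raise ValueError(f"unknown threshold rule {threshold_rule!r}")
            if work.max() <= work.min():
                raise ValueError("no foreground component: image equals background")
            thr = threshold_otsu(work)
        else:
            thr = float(threshold_rule)
        binary = work > thr
    else:
        if isinstance(threshold_rule, str):
            if threshold_rule != "otsu":
                raise ValueError(f"unknown threshold rule {threshold_rule!r}")
            if img.max() <= img.min():
                raise ValueError("no foreground component: uniform image")
            thr = threshold_otsu(img)
        else:
            thr = float(threshold_rule)
        above = img > thr
        # the capsule occupies less area than the empty field
        binary = above if above.sum() <= above.size / 2 else ~above

    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        raise ValueError("no foreground component")
    sizes = np.bincount(labels.ravel())[1:]
    comp = labels == (1 + int(np.argmax(sizes)))

    rows, cols = np.nonzero(comp)
    cr, cc = int(round(rows.mean())), int(round(cols.mean()))
    side = int(tube_diameter_px)
    half = (side - 1) // 2
    roi = np.zeros((side, side), dtype=bool)
    centre = side // 2
    for r, c in zip(rows, cols):
        rr, cc2 = r - cr + centre, c - cc + centre
        if not (0 <= rr < side and 0 <= cc2 < side):
            raise ValueError("component does not fit in the RoI after centring")
        roi[rr, cc2] = True
    if roi[0, :].any() or roi[-1, :].any() or roi[:, 0].any() or roi[:, -1].any():
        raise ValueError("component touches the RoI border after centring")
    return roi


# Moore neighbourhood in clockwise order (row, col offsets), starting West.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(binary: np.ndarray) -> BoundaryTrace:
    """Ordered outer border of the single foreground component.

    Moore-neighbour border following with Jacob's stopping criterion. The
    returned points are de-duplicated in first-visit order, converted to
    mathematical (x, y) coordinates (y axis up) and oriented counter-
    clockwise. One-pixel-thin parts are traversed on both sides during the
    walk, so for such degenerate shapes first/last adjacency is not
    guaranteed after de-duplication; blobs with interior are unaffected.
    """
    grid = np.asarray(binary).astype(bool)
    n_labels = measure.label(grid, connectivity=2).max()
    if n_labels == 0:
        raise ValueError("no foreground component to trace")
    if n_labels > 1:
        raise ValueError("boundary tracing requires exactly one component")
    if grid.sum() < 4:
        raise ValueError("component must contain at least 4 pixels")

    h, w = grid.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and grid[r, c]

    rows, cols = np.nonzero(grid)
    start = (int(rows.min()), int(cols[rows == rows.min()].min()))

    back0 = (start[0], start[1] - 1)  # exterior by start construction
    cycle = []
    cur, back = start, back0
    start_visits = 0
    for _ in range(8 * int(grid.sum()) + 8):
        cycle.append(cur)
        k0 = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        nxt = None
        for step in range(1, 9):
            k = (k0 + step) % 8
            cand = (cur[0] + _MOORE[k][0], cur[1] + _MOORE[k][1])
            if fg(*cand):
                nxt = cand
                back = (cur[0] + _MOORE[(k - 1) % 8][0],
                        cur[1] + _MOORE[(k - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel; excluded by the >= 4 px guard
            break
        cur = nxt
        # Jacob's criterion: stop on re-entering the start pixel the same way
        # (with a second-visit fallback so the walk always terminates cleanly)
        if cur == start:
            start_visits += 1
            if back == back0 or start_visits >= 3:
                break

    # de-duplicate preserving first-visit order, drop closing repeat
    seen = set()
    pts = []
    for p in cycle:
        if p not in seen:
            seen.add(p)
            pts.append(p)
    arr = np.array(pts, dtype=float)
    xy = np.column_stack([arr[:, 1], (h - 1) - arr[:, 0]])  # (x, y), y up

    # enforce counter-clockwise orientation
    x, y = xy[:, 0], xy[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        xy = xy[::-1]
    return BoundaryTrace(points=xy, roi_side=h if h == w else None)


def _local_quadratic_smooth(pts: np.ndarray, window: int) -> np.ndarray:
    """Smooth a closed polyline by per-point rotated-frame quadratic fits.

    For each point, ``window`` consecutive neighbours are rotated into a
    frame aligned with the local chord, a least-squares quadratic is fitted
    to the transverse coordinate, and the central point is replaced by its
    fitted position. The overlapping windows blend into a piecewise
    second-order approximation of the border.
    """
    m = pts.shape[0]
    half = window // 2
    out = np.empty_like(pts)
    for i in range(m):
        idx = (np.arange(i - half, i + half + 1)) % m
        wpts = pts[idx]
        centre = wpts.mean(axis=0)
        q = wpts - centre
        chord = q[-1] - q[0]
        norm = np.hypot(*chord)
        if norm < 1e-12:
            out[i] = pts[i]
            continue
        cth, sth = chord[0] / norm, chord[1] / norm
        rot = np.array([[cth, sth], [-sth, cth]])
        local = q @ rot.T
        A = np.column_stack([np.ones(window), local[:, 0], local[:, 0] ** 2])
        coef, *_ = np.linalg.lstsq(A, local[:, 1], rcond=None)
        xc = local[half, 0]
        fitted = np.array([xc, coef[0] + coef[1] * xc + coef[2] * xc**2])
        out[i] = fitted @ rot + centre
    return out


def smooth_and_resample(
    trace: BoundaryTrace,
    n_nodes: int = 60,
    window_px: int = 9,
    scale: Optional[float] = None,
    boundary_offset_px: float = 0.5,
) -> CapsuleProfile:
    """Smooth a pixel border and sample equally arc-spaced membrane nodes.

    ``scale`` is the pixels-per-tube-radius factor; when omitted it is taken
    from the trace's RoI side (side / 2, the RoI spanning one tube diameter),
    falling back to 1 so that standalone geometric use keeps pixel units.

    ``boundary_offset_px`` compensates the half-pixel quantisation bias of
    border following: under the pixel-centre convention the outermost
    foreground pixel centres sit about half a pixel inside the true object
    outline, so the smoothed border is pushed outward along its local normal
    by that amount (set 0 to disable, e.g. for traces that are not pixel
    borders). The output profile is centred on its polygon centroid.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be at least 3")
    if window_px < 5:
        raise ValueError("window_px must be at least 5")
    pts = trace.points
    if window_px > len(pts):
        raise ValueError("smoothing window larger than the trace")
    if window_px % 2 == 0:
        window_px += 1

    smooth = _local_quadratic_smooth(pts, window_px)
    if boundary_offset_px != 0.0:
        tang = np.roll(smooth, -1, axis=0) - np.roll(smooth, 1, axis=0)
        norm = np.linalg.norm(tang, axis=1, keepdims=True)
        tang = tang / np.maximum(norm, 1e-12)
        x, y = smooth[:, 0], smooth[:, 1]
        ccw = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) > 0
        sign = 1.0 if ccw else -1.0
        outward = sign * np.column_stack([tang[:, 1], -tang[:, 0]])
        smooth = smooth + boundary_offset_px * outward

    closed = np.vstack([smooth, smooth[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_nodes) * (s[-1] / n_nodes)
    nodes = np.column_stack(
        [np.interp(targets, s, closed[:, 0]), np.interp(targets, s, closed[:, 1])]
    )

    if scale is None:
        if trace.roi_side is not None:
            centre = (trace.roi_side - 1) / 2.0
            nodes = (nodes - centre) / (trace.roi_side / 2.0)
        # else: keep pixel units
    else:
        nodes = nodes / scale

    prof = CapsuleProfile(nodes)
    if prof.signed_area < 0:
        prof = CapsuleProfile(prof.nodes[::-1])
    return prof.recentre()


def to_feature_vector(profile: CapsuleProfile) -> FeatureVector:
    """Canonicalised 1D coordinate vector of a profile.

    The start node is pinned to the leading tip — the maximum-x crossing of
    the symmetry axis (y = 0), located by linear interpolation along the
    polyline and, among equal-x crossings, the one with smaller y — and the
    node sequence is re-sampled at equal arc increments from that point,
    counter-clockwise. The same shape presented with any rotated node
    numbering (or a sub-node phase shift, as happens after re-extraction
    from pixels) therefore maps to the same vector. Centred on the polygon
    centroid.
    """
    nodes = profile.nodes - profile.centroid
    if CapsuleProfile(nodes).signed_area < 0:
        nodes = nodes[::-1]
    n = nodes.shape[0]

    closed = np.vstack([nodes, nodes[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]

    # axis crossings of each edge (sign change of y, endpoints included)
    y0, y1 = closed[:-1, 1], closed[1:, 1]
    x0, x1 = closed[:-1, 0], closed[1:, 0]
    cross = (y0 == 0.0) | (y0 * y1 < 0.0)
    if not np.any(cross):  # no axis crossing: fall back to the max-x node
        tip_arc = s[int(np.lexsort((nodes[:, 1], -nodes[:, 0]))[0])]
    else:
        idx = np.nonzero(cross)[0]
        t = np.where(y0[idx] == 0.0, 0.0, y0[idx] / (y0[idx] - y1[idx]))
        xc = x0[idx] + t * (x1[idx] - x0[idx])
        yc = y0[idx] * (1.0 - t)  # ~0; kept only for deterministic tie-breaks
        best = idx[np.lexsort((yc, -xc))[0]]
        tb = 0.0 if y0[best] == 0.0 else y0[best] / (y0[best] - y1[best])
        tip_arc = s[best] + tb * seg[best]

    targets = (tip_arc + np.arange(n) * (total / n)) % total
    resampled = np.column_stack(
        [np.interp(targets, s, closed[:, 0]), np.interp(targets, s, closed[:, 1])]
    )
    resampled = resampled - CapsuleProfile(resampled).centroid
    return FeatureVector(values=resampled.ravel())


def profile_from_vector(vector: Union[FeatureVector, np.ndarray]) -> CapsuleProfile:
    """Rebuild the node polyline behind a feature vector."""
    values = vector.values if isinstance(vector, FeatureVector) else np.asarray(vector)
    return CapsuleProfile(np.asarray(values, dtype=float).reshape(-1, 2))


def extract_profile(
    image: Union[CapsuleImage, np.ndarray],
    background: Union[CapsuleImage, np.ndarray, None],
    tube_diameter_px: int,
    n_nodes: int = 60,
    window_px: int = 9,
    threshold_rule: Union[str, float] = "otsu",
) -> CapsuleProfile:
    """Full chain: image (+ optional background) -> membrane-node profile."""
    roi = preprocess(image, background, tube_diameter_px, threshold_rule)
    trace = trace_boundary(roi)
    return smooth_and_resample(trace, n_nodes=n_nodes, window_px=window_px)
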