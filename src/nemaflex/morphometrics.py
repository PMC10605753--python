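"""Worm body measurements from arena images.

Length is measured along the centerline (topological skeleton pruned to
its longest path, extended to the body tips), diameter at the mid-section
(arc-length midpoint of the centerline).  Because force conversion is
adjusted by body diameter and the pillar compliance changes by several
percent per micrometre of contact height, the diameter estimate is
refined to subpixel precision from intensity profiles across the body
rather than read off the binarised mask alone.

Adults are classified by body size plus the presence of egg-like dark
inclusions within the body.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import dijkstra
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

from .geometry import DeviceGeometry
from .grid import PillarGrid

__all__ = ["WormMeasurement", "segment_worm", "measure_worm"]


@dataclass
class WormMeasurement:
    """Per-animal morphometrics, medians across usable frames."""

    diameter_um: float
    length_um: float
    is_adult: bool
    frames_used: int

    def __post_init__(self) -> None:
        if self.frames_used < 1:
            raise ValueError("frames_used must be >= 1")
        if not (self.diameter_um < self.length_um):
            raise ValueError("diameter must be below length")


def segment_worm(
    frame: np.ndarray,
    grid: PillarGrid,
    geometry: DeviceGeometry,
    deflections_px: np.ndarray | None = None,
    expected_length_um: float = 1050.0,
    expected_diameter_um: float = 46.0,
) -> np.ndarray | None:
    """Binary worm mask for one frame, or None if no worm-sized component.

    Pillar disks (at reference plus measured deflection, slightly dilated)
    are excised from the dark foreground; the largest remaining dark
    connected component with area within [0.3, 3] x the expected worm area
    is taken as the worm.  The returned mask never includes pillar
    interiors; downstream centerline extraction re-closes the bites.
    """
    img = frame if np.issubdtype(frame.dtype, np.floating) else frame.astype(np.float32)
    if float(img.max() - img.min()) < 30.0:
        return None
    thr = threshold_otsu(img)
    dark = img < thr

    px = geometry.pixel_size_um
    radius_px = geometry.pillar_diameter_um / 2.0 / px + 2.0
    centers_px = grid.centers_um / px
    if deflections_px is not None:
        centers_px = centers_px + deflections_px
    h, w = dark.shape
    for cx, cy in centers_px:
        x0, x1 = max(int(cx - radius_px) - 1, 0), min(int(cx + radius_px) + 2, w)
        y0, y1 = max(int(cy - radius_px) - 1, 0), min(int(cy + radius_px) + 2, h)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dark[y0:y1, x0:x1] &= (xx - cx) ** 2 + (yy - cy) ** 2 > radius_px**2

    excised = dark.copy()
    # a pillar bite can sever the body outline entirely; close with a
    # pillar-radius kernel so the worm stays one component for selection
    dark = _binary_close(dark, radius_px + 2.0)

    expected_area = expected_length_um * expected_diameter_um / px**2
    best = None
    best_area = 0
    for region in regionprops(label(dark)):
        if not (0.3 * expected_area <= region.area <= 3.0 * expected_area):
            continue
        if region.area > best_area:
            best, best_area = region, region.area
    if best is None:
        return None
    mask = np.zeros_like(dark)
    mask[best.slice][best.image] = True
    mask = ndimage.binary_fill_holes(mask)
    return mask & excised  # pillar interiors stay out of the worm mask


def _binary_close(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Morphological closing with a disk, via two distance transforms."""
    if not mask.any():
        return mask
    dilated = ndimage.distance_transform_edt(~mask) <= radius_px
    return ndimage.distance_transform_edt(dilated) > radius_px - 0.5


def _skeleton_longest_path(mask: np.ndarray) -> np.ndarray | None:
    """Ordered (row, col) pixels of the skeleton's longest geodesic path."""
    skel = skeletonize(mask)
    pts = np.argwhere(skel)
    if len(pts) < 3:
        return None
    index = {tuple(p): i for i, p in enumerate(pts)}
    from scipy.sparse import lil_matrix

    n = len(pts)
    adj = lil_matrix((n, n))
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None and j > i:
                    wgt = math.hypot(dr, dc)
                    adj[i, j] = wgt
                    adj[j, i] = wgt
    adj = adj.tocsr()
    # double sweep: farthest point from an arbitrary start, then farthest
    # from that — the classic diameter heuristic, exact on trees
    d0 = dijkstra(adj, indices=0)
    d0[~np.isfinite(d0)] = -1
    a = int(np.argmax(d0))
    da, pred = dijkstra(adj, indices=a, return_predecessors=True)
    da[~np.isfinite(da)] = -1
    b = int(np.argmax(da))
    path = [b]
    while path[-1] != a:
        nxt = pred[path[-1]]
        if nxt < 0:
            break
        path.append(int(nxt))
    return pts[path[::-1]]


def _tip_extension(
    img: np.ndarray, end_rc: np.ndarray, direction_rc: np.ndarray, max_px: float = 40.0
) -> float:
    """Signed distance from a centerline endpoint to the body tip.

    Samples the image along the outward end direction and finds the
    half-contrast crossing where the dark body gives way to background.
    Negative when the skeleton overran into a healed blob beyond the tip.
    """
    norm = math.hypot(direction_rc[0], direction_rc[1])
    if norm == 0:
        return 0.0
    d = np.asarray(direction_rc, dtype=float) / norm
    ts = np.arange(-6.0, max_px, 0.5)
    rr = end_rc[0] + ts * d[0]
    cc = end_rc[1] + ts * d[1]
    h, w = img.shape
    inside = (rr >= 0) & (cc >= 0) & (rr <= h - 1) & (cc <= w - 1)
    if inside.sum() < 8:
        return 0.0
    vals = ndimage.map_coordinates(img, [rr[inside], cc[inside]], order=1)
    ts = ts[inside]
    lo, hi = vals.min(), np.percentile(vals, 95.0)
    if hi - lo < 40.0:
        return 0.0
    half = (hi + lo) / 2.0
    dark = vals < half
    if not dark[0]:
        return 0.0
    k = int(np.argmin(dark))  # first bright sample
    if k == 0 or dark.all():
        return 0.0
    t_cross = ts[k - 1] + (ts[k] - ts[k - 1]) * (half - vals[k - 1]) / (
        vals[k] - vals[k - 1]
    )
    return float(t_cross)


def _profile_diameter_px(
    img: np.ndarray, point_rc: np.ndarray, normal_rc: np.ndarray, max_half_px: float
) -> float | None:
    """Full width of the dark body along a normal profile, at half contrast."""
    ts = np.linspace(-max_half_px, max_half_px, int(4 * max_half_px) + 1)
    rr = point_rc[0] + ts * normal_rc[0]
    cc = point_rc[1] + ts * normal_rc[1]
    h, w = img.shape
    if rr.min() < 0 or cc.min() < 0 or rr.max() > h - 1 or cc.max() > w - 1:
        return None
    vals = ndimage.map_coordinates(img, [rr, cc], order=1)
    lo = vals.min()
    hi = np.percentile(vals, 95.0)
    if hi - lo < 40.0:
        return None
    half = (hi + lo) / 2.0
    below = vals < half
    mid = len(ts) // 2
    if not below[mid]:
        return None
    i = mid
    while i > 0 and below[i - 1]:
        i -= 1
    j = mid
    while j < len(ts) - 1 and below[j + 1]:
        j += 1
    if i == 0 or j == len(ts) - 1:
        return None
    # linear interpolation of each half-contrast crossing
    t_left = ts[i - 1] + (ts[i] - ts[i - 1]) * (vals[i - 1] - half) / (vals[i - 1] - vals[i])
    t_right = ts[j] + (ts[j + 1] - ts[j]) * (half - vals[j]) / (vals[j + 1] - vals[j])
    return float(t_right - t_left)


def measure_worm(
    frames: list[np.ndarray] | np.ndarray,
    grid: PillarGrid,
    geometry: DeviceGeometry,
    expected_length_um: float = 1050.0,
    expected_diameter_um: float = 46.0,
    adult_length_threshold_um: float = 900.0,
) -> WormMeasurement:
    """Diameter, length and adult flag, medians across usable frames.

    Per frame: segment the worm, skeletonize, take the longest path as the
    centerline; length is the path arc length plus the distance-transform
    radius at each endpoint (the skeleton stops about one body radius short
    of each tip); diameter is measured at stations around the arc-length
    midpoint, first as twice the distance-transform value on the
    centerline, then refined from subpixel intensity profiles normal to
    the centerline (stations too close to a pillar are skipped).  Adults
    need both length above the threshold and egg-like inclusions.
    """
    px = geometry.pixel_size_um
    diameters, lengths, egg_flags = [], [], []
    for frame in frames:
        if not np.issubdtype(frame.dtype, np.floating):
            frame = frame.astype(np.float32)
        mask = segment_worm(
            frame, grid, geometry,
            expected_length_um=expected_length_um,
            expected_diameter_um=expected_diameter_um,
        )
        if mask is None:
            continue
        # re-close the pillar bites so the centerline runs through the body
        pillar_r_px = geometry.pillar_diameter_um / 2.0 / px + 2.0
        healed = ndimage.binary_fill_holes(_binary_close(mask, pillar_r_px + 2.0))
        path = _skeleton_longest_path(healed)
        if path is None or len(path) < 10:
            continue
        # smooth away the 8-connected staircase before measuring length
        # (raw pixel-chain arc length overestimates smooth curves by ~8%)
        smooth = ndimage.uniform_filter1d(
            path.astype(float), size=15, axis=0, mode="nearest"
        )
        steps = np.hypot(*np.diff(smooth, axis=0).T)
        edt = ndimage.distance_transform_edt(healed)
        # the skeleton stops short of (or, after bite-healing, can overrun)
        # the body tips; locate each tip from the intensity itself
        ext_head = _tip_extension(frame, smooth[0], smooth[0] - smooth[10])
        ext_tail = _tip_extension(frame, smooth[-1], smooth[-1] - smooth[-11])
        length_um = (steps.sum() + ext_head + ext_tail) * px
        arclen = np.concatenate([[0.0], np.cumsum(steps)])

        diam_px = _diameter_at_midsection(frame, mask, path, arclen, grid, geometry, edt)
        if diam_px is None:
            continue
        diameters.append(diam_px * px)
        lengths.append(length_um)
        egg_flags.append(_has_egg_inclusions(frame, mask, px))
    if not diameters:
        raise ValueError("no usable frames for morphometrics")
    diameter = float(np.median(diameters))
    length = float(np.median(lengths))
    has_eggs = bool(np.mean(egg_flags) >= 0.5)
    return WormMeasurement(
        diameter_um=diameter,
        length_um=length,
        is_adult=(length >= adult_length_threshold_um) and has_eggs,
        frames_used=len(diameters),
    )


def _diameter_at_midsection(frame, mask, path, arclen, grid, geometry, edt):
    """Median body width (px) at stations around the arc-length midpoint."""
    px = geometry.pixel_size_um
    centers_px = grid.centers_um / px
    pillar_r_px = geometry.pillar_diameter_um / 2.0 / px
    total = arclen[-1]
    stations = np.linspace(0.40, 0.60, 9) * total
    widths = []
    for s in stations:
        k = int(np.searchsorted(arclen, s))
        k = min(max(k, 2), len(path) - 3)
        point = path[k].astype(float)
        # clear of pillars: profiles crossing a pillar edge are unusable
        d_pillar = np.hypot(
            centers_px[:, 0] - point[1], centers_px[:, 1] - point[0]
        ).min()
        if d_pillar < pillar_r_px + edt[path[k][0], path[k][1]] + 3.0:
            continue
        tang = path[min(k + 2, len(path) - 1)] - path[max(k - 2, 0)]
        tn = math.hypot(tang[0], tang[1])
        if tn == 0:
            continue
        normal = np.array([-tang[1] / tn, tang[0] / tn])
        wpx = _profile_diameter_px(
            frame, point, normal, max_half_px=2.5 * edt[path[k][0], path[k][1]] + 4.0
        )
        if wpx is not None:
            widths.append(wpx)
    if not widths:
        # fall back to the mask distance transform at the midpoint
        k = int(np.searchsorted(arclen, 0.5 * total))
        k = min(max(k, 0), len(path) - 1)
        w = 2.0 * edt[path[k][0], path[k][1]]
        return float(w) if w > 0 else None
    return float(np.median(widths))


def _has_egg_inclusions(frame, mask, pixel_size_um) -> bool:
    """Detect egg-like darker inclusions inside the body mask."""
    img = frame
    body = img[mask]
    if body.size == 0:
        return False
    body_level = np.median(body)
    inclusions = mask & (img < body_level - 25.0)
    # an egg spans a few tens of square micrometres in the image
    min_area = 30.0 / pixel_size_um**2
    max_area = 1500.0 / pixel_size_um**2
    for region in regionprops(label(inclusions)):
        if min_area <= region.area <= max_area:
            return True
    return False
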