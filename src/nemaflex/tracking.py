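"""Pillar localization and deflection quantification.

Recovers the undeflected reference lattice from a recording and measures
per-frame, per-pillar displacement vectors.  Pillars are imaged as dark,
radially shaded disks; localization is an iterated intensity-weighted
centroid of the inverted image inside a circular window confined to the
pillar interior, which reaches well below 0.1 px on clean renders.
Reference centers are temporal medians across frames (no worm-free frame
is guaranteed), and a rigid square lattice is fit to them as a sanity
check on arena regularity.

Deflections below a data-driven noise floor — a multiple of the median
localization jitter of never-contacted pillars — are zeroed so that pure
camera noise cannot enter the maximal-force distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .geometry import DeviceGeometry
from .grid import PillarGrid

__all__ = [
    "DeflectionTrack",
    "detect_reference_grid",
    "localize_pillar",
    "measure_deflections",
    "max_deflection_per_frame",
]

# window radius for centroiding, as a fraction of the pillar radius; the
# full disk plus its edge ramp carries the most position information, and
# the body is excluded from a ~2 px collar around every pillar footprint,
# so a window at 1.0x the radius still cannot see worm darkness
WINDOW_RADIUS_FRACTION = 1.0
CONVERGENCE_PX = 0.01
MAX_ITERATIONS = 20
# occlusion guard: a window with less than this 10-90 percentile intensity
# range has no radial structure to localize (flat worm body or background)
MIN_WINDOW_CONTRAST = 25.0


@dataclass
class DeflectionTrack:
    """Dense frames x pillars displacement field, in micrometres.

    ``dx_um``/``dy_um`` are (n_frames, n_pillars) with NaN for missing
    localizations; magnitudes below ``noise_floor_um`` have been zeroed.
    """

    dx_um: np.ndarray
    dy_um: np.ndarray
    noise_floor_um: float
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.dx_um = np.asarray(self.dx_um, dtype=float)
        self.dy_um = np.asarray(self.dy_um, dtype=float)
        if self.dx_um.shape != self.dy_um.shape:
            raise ValueError("dx/dy shape mismatch")
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.dx_um.shape[0]

    @property
    def n_pillars(self) -> int:
        return self.dx_um.shape[1]

    @property
    def magnitude_um(self) -> np.ndarray:
        return np.hypot(self.dx_um, self.dy_um)

    def to_csv(self, path) -> None:
        frames, pillars = np.meshgrid(
            np.arange(self.n_frames), np.arange(self.n_pillars), indexing="ij"
        )
        df = pd.DataFrame(
            {
                "frame": frames.ravel(),
                "pillar": pillars.ravel(),
                "dx_um": self.dx_um.ravel(),
                "dy_um": self.dy_um.ravel(),
                "magnitude_um": self.magnitude_um.ravel(),
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, noise_floor_um: float = 0.0) -> "DeflectionTrack":
        df = pd.read_csv(path)
        n_f = int(df["frame"].max()) + 1
        n_p = int(df["pillar"].max()) + 1
        dx = np.full((n_f, n_p), np.nan)
        dy = np.full((n_f, n_p), np.nan)
        dx[df["frame"], df["pillar"]] = df["dx_um"]
        dy[df["frame"], df["pillar"]] = df["dy_um"]
        return cls(dx, dy, noise_floor_um, np.ones(n_p, dtype=bool))


def localize_pillar(
    frame: np.ndarray,
    approximate_center_px: tuple[float, float],
    geometry: DeviceGeometry,
) -> tuple[float, float] | None:
    """Subpixel pillar center (x, y) in pixels, or None if unlocatable.

    Iterated intensity-weighted centroid of the inverted image within a
    circular window of one pillar radius, baseline-subtracted at the
    window's 10th percentile.  Returns None when the window leaves the
    image or the window is featureless (pillar occluded).
    """
    win_r = WINDOW_RADIUS_FRACTION * geometry.pillar_diameter_um / 2.0 / geometry.pixel_size_um
    h, w = frame.shape
    cx, cy = float(approximate_center_px[0]), float(approximate_center_px[1])
    img = frame if np.issubdtype(frame.dtype, np.floating) else frame.astype(np.float32)

    def window(cx, cy):
        x0, x1 = int(math.floor(cx - win_r)), int(math.ceil(cx + win_r)) + 1
        y0, y1 = int(math.floor(cy - win_r)), int(math.ceil(cy + win_r)) + 1
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            return None
        patch = 255.0 - img[y0:y1, x0:x1]
        xs = np.arange(x0, x1, dtype=float)
        ys = np.arange(y0, y1, dtype=float)
        mask = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= win_r**2
        vals = np.sort(patch[mask])
        if vals.size < 8:
            return None
        p10 = vals[int(0.1 * vals.size)]
        p90 = vals[int(0.9 * vals.size)]
        return patch, xs, ys, mask, p10, p90

    contrast_ok = False
    converged = False
    for it in range(MAX_ITERATIONS):
        win = window(cx, cy)
        if win is None:
            return None
        patch, xs, ys, mask, p10, p90 = win
        contrast_ok = (p90 - p10) >= MIN_WINDOW_CONTRAST
        if it > 0 and not contrast_ok:
            return None
        weights = np.clip(patch - p10, 0.0, None) * mask
        total = weights.sum()
        if total <= 0:
            return None
        nx = float((weights.sum(axis=0) * xs).sum() / total)
        ny = float((weights.sum(axis=1) * ys).sum() / total)
        shift = math.hypot(nx - cx, ny - cy)
        cx, cy = nx, ny
        if shift < CONVERGENCE_PX:
            converged = True
            break
    if not converged or not contrast_ok:
        # final featurelessness check at the converged position
        win = window(cx, cy)
        if win is None:
            return None
        *_rest, p10, p90 = win
        if (p90 - p10) < MIN_WINDOW_CONTRAST:
            return None
    return (cx, cy)


def _candidate_centers(
    frame: np.ndarray, geometry: DeviceGeometry, thr: float | None = None
) -> np.ndarray:
    """Dark-disk candidate centers (px) in one frame via threshold + labels."""
    img = frame if np.issubdtype(frame.dtype, np.floating) else frame.astype(np.float32)
    spread = float(img.max() - img.min())
    if spread < 30.0:  # featureless frame (pure noise / blank)
        return np.empty((0, 2))
    if thr is None:
        thr = threshold_otsu(img)
    dark = img < thr
    radius_px = geometry.pillar_diameter_um / 2.0 / geometry.pixel_size_um
    area0 = math.pi * radius_px**2
    out = []
    for region in regionprops(label(dark)):
        if not (0.35 * area0 <= region.area <= 1.8 * area0):
            continue
        # cheap roundness screen: a disk fills ~pi/4 of its bounding box,
        # which is itself nearly square
        r0, c0, r1, c1 = region.bbox
        hgt, wid = r1 - r0, c1 - c0
        if max(hgt, wid) > 1.5 * min(hgt, wid):
            continue
        if not (0.55 <= region.area / (hgt * wid) <= 0.95):
            continue
        cy, cx = region.centroid
        out.append((cx, cy))
    return np.asarray(out, dtype=float).reshape(-1, 2)


def detect_reference_grid(
    stack: np.ndarray,
    geometry: DeviceGeometry,
    max_sample_frames: int = 24,
) -> PillarGrid:
    """Recover the undeflected reference lattice from an image stack.

    Candidate dark disks are detected per frame and clustered across
    frames; each cluster's reference center is the temporal median of its
    subpixel localizations (robust to transient worm contact).  Pillars
    seen in fewer than 20% of sampled frames (persistently overlapped by
    the worm) are flagged invalid.  A rigid square lattice (pitch,
    orientation, origin) is least-squares fit to the valid centers; a
    residual above a quarter pitch means this is not a regular arena.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, H, W)")
    if stack.shape[0] < 10:
        raise ValueError("need at least 10 frames to build a reference grid")
    n_sample = min(max_sample_frames, stack.shape[0])
    sample_idx = np.unique(np.linspace(0, stack.shape[0] - 1, n_sample).astype(int))

    radius_px = geometry.pillar_diameter_um / 2.0 / geometry.pixel_size_um
    if np.issubdtype(stack.dtype, np.floating):
        float_frames = {fi: stack[fi] for fi in sample_idx}
    else:
        float_frames = {fi: stack[fi].astype(np.float32) for fi in sample_idx}
    anchors: list[np.ndarray] = []
    counts: list[int] = []
    # lighting is static within a recording: one threshold serves all frames
    thr = None
    first = float_frames[sample_idx[0]]
    if float(first.max() - first.min()) >= 30.0:
        thr = float(threshold_otsu(first))
    for fi in sample_idx:
        cands = _candidate_centers(float_frames[fi], geometry, thr=thr)
        if cands.size == 0:
            continue
        if anchors:
            tree = cKDTree(np.asarray(anchors))
            dist, nearest = tree.query(cands)
            for c, d, j in zip(cands, dist, nearest):
                if d <= radius_px:
                    counts[j] += 1
                else:
                    anchors.append(c)
                    counts.append(1)
        else:
            anchors.extend(cands)
            counts.extend([1] * len(cands))
    # transient worm-shaped fragments can masquerade as single-frame
    # candidates; a real pillar is re-detected in many frames
    min_seen = max(2, int(0.08 * len(sample_idx)))
    keep = [i for i, c in enumerate(counts) if c >= min_seen]
    anchors = [anchors[i] for i in keep]
    counts = [counts[i] for i in keep]
    if len(anchors) < 4:
        raise ValueError("fewer than 4 detected pillars")

    # refine each anchor with subpixel localization, temporal median
    refined = []
    valid = []
    for anchor, seen in zip(anchors, counts):
        hits = []
        for fi in sample_idx:
            loc = localize_pillar(float_frames[fi], tuple(anchor), geometry)
            if loc is not None:
                # reject localizations that wandered to a neighbour
                if math.hypot(loc[0] - anchor[0], loc[1] - anchor[1]) <= radius_px:
                    hits.append(loc)
        if not hits:
            refined.append(anchor)
            valid.append(False)
            continue
        refined.append(_position_mode(np.asarray(hits), bandwidth=0.15))
        valid.append(len(hits) >= 0.2 * len(sample_idx))
    centers_px = np.asarray(refined)
    valid = np.asarray(valid, dtype=bool)
    if valid.sum() < 4:
        raise ValueError("fewer than 4 detected pillars")

    pitch_px, theta, origin_px, residual_px, point_residuals = _fit_square_lattice(
        centers_px[valid]
    )
    # off-lattice stragglers (e.g. a misdetected fragment) are dropped and
    # the lattice refit on the inliers
    outliers = point_residuals > 0.25 * pitch_px
    if np.any(outliers):
        valid_idx = np.flatnonzero(valid)
        valid[valid_idx[outliers]] = False
        if valid.sum() < 4:
            raise ValueError("fewer than 4 detected pillars")
        pitch_px, theta, origin_px, residual_px, _ = _fit_square_lattice(
            centers_px[valid]
        )
    if residual_px > 0.25 * pitch_px:
        raise ValueError(
            f"lattice residual {residual_px:.2f} px exceeds a quarter pitch; "
            "not a regular pillar arena"
        )
    px = geometry.pixel_size_um
    return PillarGrid(
        centers_um=centers_px * px,
        pitch_um=pitch_px * px,
        orientation_rad=theta,
        origin_um=(origin_px[0] * px, origin_px[1] * px),
        valid=valid,
        fit_residual_um=residual_px * px,
    )


class PillarTemplate:
    """Mean pillar appearance of one recording, with a Gauss-Newton aligner.

    The template is the average of pillar patches re-centred at their
    centroid localizations, so it is calibrated from the data itself and
    assumes nothing about the pillar's intensity profile.  ``refine``
    solves for the subpixel shift (plus per-patch gain and offset, so
    local illumination cannot bias the fit) that photometrically aligns
    the template with the image; gradient-based alignment avoids the
    pixel-locking of correlation-peak interpolation and roughly halves
    the centroid's localization noise.
    """

    def __init__(self, template: np.ndarray, radius_px: float):
        self.template = template
        half = (template.shape[0] - 1) // 2
        self.half = half
        self.ys, self.xs = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
        gy, gx = np.gradient(template)
        self.mask = (self.xs**2 + self.ys**2 <= radius_px**2).ravel()
        A = np.column_stack(
            [
                gx.ravel()[self.mask],
                gy.ravel()[self.mask],
                np.ones(int(self.mask.sum())),
                template.ravel()[self.mask],
            ]
        )
        self.solver = np.linalg.pinv(A)

    @classmethod
    def build(
        cls,
        frames: list[np.ndarray],
        positions: np.ndarray,
        radius_px: float,
        min_samples: int = 10,
    ) -> "PillarTemplate | None":
        """Average re-centred patches; (x, y) ``positions`` pair 1:1 with frames."""
        half = int(math.ceil(radius_px + 2.0))
        acc = np.zeros((2 * half + 1, 2 * half + 1))
        n = 0
        for frame, (cx, cy) in zip(frames, positions):
            if not (np.isfinite(cx) and np.isfinite(cy)):
                continue
            h, w = frame.shape
            if cx < half + 1 or cy < half + 1 or cx > w - half - 2 or cy > h - half - 2:
                continue
            acc += _bilinear_patch(frame, cx, cy, half)
            n += 1
        if n < min_samples:
            return None
        return cls(acc / n, radius_px)

    def refine(
        self,
        frame: np.ndarray,
        start_px: tuple[float, float],
        max_iter: int = 6,
    ) -> tuple[float, float] | None:
        half = self.half
        cx, cy = float(start_px[0]), float(start_px[1])
        h, w = frame.shape
        for _ in range(max_iter):
            if cx < half + 1 or cy < half + 1 or cx > w - half - 2 or cy > h - half - 2:
                return None
            patch = _bilinear_patch(frame, cx, cy, half)
            coef = self.solver @ patch.ravel()[self.mask]
            ddx, ddy = float(coef[0]), float(coef[1])
            cx -= ddx
            cy -= ddy
            if math.hypot(ddx, ddy) < 0.002:
                break
            if math.hypot(cx - start_px[0], cy - start_px[1]) > 3.0:
                return None  # diverged away from the centroid estimate
        return (cx, cy)


def _bilinear_patch(frame: np.ndarray, cx: float, cy: float, half: int) -> np.ndarray:
    """(2*half+1)^2 patch centred at subpixel (cx, cy), bilinear blend."""
    ix, iy = int(math.floor(cx)), int(math.floor(cy))
    fx, fy = cx - ix, cy - iy
    x0, y0 = ix - half, iy - half
    a = frame[y0 : y0 + 2 * half + 2, x0 : x0 + 2 * half + 2]
    top = a[:-1, :-1] * (1.0 - fx) + a[:-1, 1:] * fx
    bot = a[1:, :-1] * (1.0 - fx) + a[1:, 1:] * fx
    return top * (1.0 - fy) + bot * fy


def _position_mode(points: np.ndarray, bandwidth: float, n_iter: int = 12) -> np.ndarray:
    """Densest cluster of per-frame pillar positions (mean-shift mode).

    A plain temporal median drifts when the worm repeatedly pushes a
    pillar in a consistent direction; at-rest localizations, in contrast,
    form a tight cluster (spread = localization jitter) while deflected
    ones scatter with the force distribution.  Mean-shift with a bandwidth
    a few times the jitter converges onto the at-rest cluster.
    """
    if len(points) < 4:
        return np.median(points, axis=0)
    # seed at the densest observation, not the median: with many deflected
    # frames the median can sit in the gap between clusters
    tree = cKDTree(points)
    neighbor_counts = np.array([len(n) for n in tree.query_ball_point(points, bandwidth)])
    est = points[int(np.argmax(neighbor_counts))]
    for _ in range(n_iter):
        near = tree.query_ball_point(est, bandwidth)
        if len(near) < 3:
            break
        new = points[near].mean(axis=0)
        if math.hypot(new[0] - est[0], new[1] - est[1]) < 1e-3 * bandwidth:
            est = new
            break
        est = new
    return est


def _fit_square_lattice(centers_px: np.ndarray):
    """Fit pitch, orientation and origin of a square lattice to points."""
    tree = cKDTree(centers_px)
    dist, idx = tree.query(centers_px, k=2)
    nn_vec = centers_px[idx[:, 1]] - centers_px
    nn_dist = dist[:, 1]
    pitch = float(np.median(nn_dist))
    # orientation modulo 90 degrees via angle quadrupling
    ang = np.arctan2(nn_vec[:, 1], nn_vec[:, 0])
    theta = float(np.angle(np.mean(np.exp(4j * ang))) / 4.0)
    c, s = math.cos(-theta), math.sin(-theta)
    rot = centers_px @ np.array([[c, -s], [s, c]]).T
    base = rot.min(axis=0)
    indices = np.round((rot - base) / pitch)
    # least-squares origin given integer indices and pitch
    origin = (rot - indices * pitch).mean(axis=0)
    fitted = origin + indices * pitch
    point_residuals = np.sqrt(np.sum((rot - fitted) ** 2, axis=1))
    residual = float(np.sqrt(np.mean(point_residuals**2)))
    cb, sb = math.cos(theta), math.sin(theta)
    origin_img = origin @ np.array([[cb, -sb], [sb, cb]]).T
    return pitch, theta, (float(origin_img[0]), float(origin_img[1])), residual, point_residuals


def measure_deflections(
    stack: np.ndarray,
    grid: PillarGrid,
    geometry: DeviceGeometry,
    noise_floor_multiplier: float = 4.0,
) -> DeflectionTrack:
    """Per-frame, per-pillar displacement vectors relative to the reference.

    Each valid pillar is localized in each frame starting from its
    reference position; the displacement is the localized minus reference
    center, converted to micrometres.  The noise floor is
    ``noise_floor_multiplier`` times the median per-frame jitter magnitude
    of never-contacted pillars (identified by their own quiet statistics);
    displacement vectors with magnitude below it are set to exactly zero.
    Missing localizations propagate as NaN.
    """
    stack = np.asarray(stack)
    px = geometry.pixel_size_um
    refs_px = grid.centers_um / px
    n_frames = stack.shape[0]
    n_pillars = len(grid)
    radius_px = geometry.pillar_diameter_um / 2.0 / px
    dx = np.full((n_frames, n_pillars), np.nan)
    dy = np.full((n_frames, n_pillars), np.nan)
    if np.issubdtype(stack.dtype, np.floating):
        float_frames = [stack[f] for f in range(n_frames)]
    else:
        stack_f = stack.astype(np.float32)
        float_frames = [stack_f[f] for f in range(n_frames)]
    for f, frame in enumerate(float_frames):
        for p in range(n_pillars):
            if not grid.valid[p]:
                continue
            ref = refs_px[p]
            # warm start from the previous frame's center when available
            if f > 0 and np.isfinite(dx[f - 1, p]):
                guess = (ref[0] + dx[f - 1, p] / px, ref[1] + dy[f - 1, p] / px)
            else:
                guess = (ref[0], ref[1])
            loc = localize_pillar(frame, guess, geometry)
            if loc is None:
                continue
            # a localization that wandered toward a neighbour is no
            # measurement of *this* pillar
            if math.hypot(loc[0] - ref[0], loc[1] - ref[1]) * px > 0.45 * grid.pitch_um:
                continue
            dx[f, p] = (loc[0] - ref[0]) * px
            dy[f, p] = (loc[1] - ref[1]) * px

    # second pass: refine every localization against the recording's own
    # mean pillar appearance, then re-reference so the pillar-specific
    # template bias cancels out of the displacement
    template = _recording_template(float_frames, refs_px, dx, dy, radius_px, px)
    if template is not None:
        rdx = np.full_like(dx, np.nan)
        rdy = np.full_like(dy, np.nan)
        for f, frame in enumerate(float_frames):
            for p in range(n_pillars):
                if not np.isfinite(dx[f, p]):
                    continue
                start = (refs_px[p][0] + dx[f, p] / px, refs_px[p][1] + dy[f, p] / px)
                loc = template.refine(frame, start)
                if loc is None:
                    continue
                rdx[f, p] = (loc[0] - refs_px[p][0]) * px
                rdy[f, p] = (loc[1] - refs_px[p][1]) * px
        # per-pillar re-referencing: subtract each pillar's own at-rest
        # offset so any constant template misalignment drops out
        for p in range(n_pillars):
            good = np.isfinite(rdx[:, p])
            if good.sum() < 5:
                continue
            pts = np.column_stack([rdx[good, p], rdy[good, p]]) / px
            rest = _position_mode(pts, bandwidth=0.15) * px
            if math.hypot(rest[0], rest[1]) < 0.5 * px:
                rdx[good, p] -= rest[0]
                rdy[good, p] -= rest[1]
        refined_ok = np.isfinite(rdx)
        dx[refined_ok] = rdx[refined_ok]
        dy[refined_ok] = rdy[refined_ok]

    mag = np.hypot(dx, dy)
    floor = _noise_floor(mag, noise_floor_multiplier)
    small = mag < floor
    dx[small] = 0.0
    dy[small] = 0.0
    return DeflectionTrack(dx_um=dx, dy_um=dy, noise_floor_um=floor, valid=grid.valid.copy())


def _recording_template(
    float_frames: list[np.ndarray],
    refs_px: np.ndarray,
    dx_um: np.ndarray,
    dy_um: np.ndarray,
    radius_px: float,
    px: float,
    target_samples: int = 150,
) -> PillarTemplate | None:
    """Build the mean pillar appearance from a spread of localizations."""
    n_frames, n_pillars = dx_um.shape
    step = max(1, (n_frames * n_pillars) // target_samples)
    frames = []
    positions = []
    k = 0
    for f in range(n_frames):
        for p in range(n_pillars):
            if not np.isfinite(dx_um[f, p]):
                continue
            k += 1
            if k % step:
                continue
            frames.append(float_frames[f])
            positions.append(
                (refs_px[p][0] + dx_um[f, p] / px, refs_px[p][1] + dy_um[f, p] / px)
            )
    if not positions:
        return None
    return PillarTemplate.build(frames, np.asarray(positions), radius_px)


def _noise_floor(magnitudes: np.ndarray, multiplier: float) -> float:
    """Noise floor (um) from the jitter of never-contacted pillars.

    A pillar counts as never-contacted when its 95th-percentile
    displacement stays within 3x its median displacement — the signature
    of pure localization jitter (for noise, that ratio is ~2).  The floor
    is ``multiplier`` times the median of those pillars' median jitter.
    """
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(magnitudes, axis=0)
        p95 = np.nanpercentile(magnitudes, 95.0, axis=0)
    quiet = np.isfinite(med) & np.isfinite(p95) & (p95 < 3.0 * np.maximum(med, 1e-12))
    if not np.any(quiet):
        return 0.0
    jitter = float(np.median(med[quiet]))
    return multiplier * jitter


def max_deflection_per_frame(
    track: DeflectionTrack,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-frame maximal deflection over valid, non-missing pillars.

    Returns (frame_indices, argmax_pillar, delta_max_um, n_dropped) where
    dropped frames are those with every pillar missing.  Ties break to the
    lowest pillar index.
    """
    if track.valid.sum() < 1:
        raise ValueError("no valid pillars")
    mag = track.magnitude_um[:, track.valid]
    pillar_ids = np.flatnonzero(track.valid)
    usable = ~np.all(np.isnan(mag), axis=1)
    n_dropped = int((~usable).sum())
    if not np.any(usable):
        raise ValueError("no usable frames")
    mag_use = np.where(np.isnan(mag[usable]), -np.inf, mag[usable])
    arg = np.argmax(mag_use, axis=1)  # first occurrence wins ties
    frames = np.flatnonzero(usable)
    return (
        frames,
        pillar_ids[arg],
        mag_use[np.arange(len(arg)), arg],
        n_dropped,
    )
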