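"""Synthetic micropillar-arena recordings with exact ground-truth forces.

No raw videos from the flight experiment are publicly deposited, so every
downstream stage is validated against synthetic recordings in which the
contact forces are *prescribed*, not emulated mechanically: a smooth
undulating worm centerline moves through the pillar lattice, pillars near
the body receive stochastic contact forces, each force is turned into a
pillar-top displacement through the same cantilever mechanics the analysis
inverts, and frames are rasterised with subpixel placement plus camera
noise.  The generator therefore knows the true per-frame maximal force and
the true f95 of every recording, which is what the pipeline is judged
against.

Cohorts mirror the flight study's 2x2 design: strain (wt, dys-1) crossed
with environment (ground, flight), group sizes 30/30/25/29, body sizes
drawn from the published per-group means, and flight groups given reduced
force scales matching the published strength ratios.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile

from .geometry import DeviceGeometry, force_to_deflection
from .grid import PillarGrid, make_pillar_grid
from .published import REFERENCE_GROUPS

__all__ = [
    "WormModel",
    "GroundTruth",
    "GroupSpec",
    "CohortDesign",
    "AnimalRecording",
    "default_cohort_design",
    "generate_trajectory",
    "assign_contact_forces",
    "render_frames",
    "generate_recording",
    "generate_cohort",
]


@dataclass(frozen=True)
class WormModel:
    """Geometric and gait parameters of one simulated adult."""

    length_um: float = 1077.0
    diameter_um: float = 47.0
    gait_amplitude_um: float = 25.0
    gait_wavelength_um: float = 450.0
    gait_speed_um_s: float = 120.0
    has_eggs: bool = True

    def __post_init__(self) -> None:
        if not (self.length_um > self.diameter_um > 0):
            raise ValueError("need length_um > diameter_um > 0")
        if self.gait_wavelength_um <= 0:
            raise ValueError("gait_wavelength_um must be positive")


@dataclass
class GroundTruth:
    """Per-frame applied forces and the displacement each one produces.

    ``contacts[f]`` holds (pillar_indices, force_vectors_uN,
    displacement_vectors_um) for frame f; displacement magnitudes equal
    ``force_to_deflection`` of the force magnitudes exactly
    (pre-rasterisation).  ``true_f95_uN`` is the 95th percentile of the
    per-frame maximal applied force magnitudes (frames without contact
    contribute zero, exactly as the measurement pipeline sees them).
    """

    contacts: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    frame_max_force_uN: np.ndarray
    frame_max_pillar: np.ndarray
    true_f95_uN: float
    seed: int
    no_contact_warning: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.contacts)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": int(self.seed),
            "true_f95_uN": float(self.true_f95_uN),
            "no_contact_warning": bool(self.no_contact_warning),
            "frame_max_force_uN": self.frame_max_force_uN.tolist(),
            "frame_max_pillar": self.frame_max_pillar.tolist(),
            "contacts": [
                {
                    "pillars": idx.tolist(),
                    "forces_uN": fv.tolist(),
                    "displacements_um": dv.tolist(),
                }
                for idx, fv, dv in self.contacts
            ],
        }
        Path(path).write_text(json.dumps(payload))


@dataclass(frozen=True)
class GroupSpec:
    """One cell of the strain x environment design."""

    strain: str
    environment: str
    n: int
    force_multiplier: float
    diameter_mean_um: float
    diameter_sd_um: float
    length_mean_um: float
    length_sd_um: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2 (group statistics undefined)")
        if self.force_multiplier < 0:
            raise ValueError("force_multiplier must be >= 0")
        if self.diameter_sd_um < 0 or self.length_sd_um < 0:
            raise ValueError("SDs must be >= 0")


@dataclass(frozen=True)
class CohortDesign:
    """Study design plus the base force distribution.

    Per-pillar per-frame contact-force magnitudes are log-normal with the
    given median and log-scale shape, scaled by the group multiplier and by
    a mean-one per-animal log-normal factor whose coefficient of variation
    ``animal_cv`` sets the between-animal strength spread.
    """

    groups: tuple[GroupSpec, ...]
    force_median_uN: float = 10.0
    force_sigma_log: float = 0.3
    animal_cv: float = 0.25
    duration_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design has no groups")
        if self.force_median_uN <= 0 or self.force_sigma_log < 0:
            raise ValueError("invalid base force distribution")

    @property
    def n_animals(self) -> int:
        return sum(g.n for g in self.groups)


def default_cohort_design(seed: int = 0, duration_s: float = 60.0) -> CohortDesign:
    """The flight-study design: published group sizes and body sizes, with
    group force scales proportional to the published f95 group means."""
    base = REFERENCE_GROUPS[("wt", "ground")]["f95_mean"]
    groups = []
    for (strain, env), ref in REFERENCE_GROUPS.items():
        groups.append(
            GroupSpec(
                strain=strain,
                environment=env,
                n=int(ref["n"]),
                force_multiplier=ref["f95_mean"] / base,
                diameter_mean_um=ref["diameter_mean"],
                diameter_sd_um=ref["diameter_sd"],
                length_mean_um=ref["length_mean"],
                length_sd_um=ref["length_sd"],
            )
        )
    return CohortDesign(groups=tuple(groups), seed=seed, duration_s=duration_s)


@dataclass
class AnimalRecording:
    """One simulated animal: labels, true worm, ground truth and frames."""

    animal_id: str
    strain: str
    environment: str
    worm: WormModel
    grid: PillarGrid
    ground_truth: GroundTruth
    stack: np.ndarray | None = None  # (frames, H, W) uint8, None if not rendered


# ----------------------------------------------------------------------
# trajectory
# ----------------------------------------------------------------------

def generate_trajectory(
    worm: WormModel,
    duration_s: float,
    frame_rate_hz: float,
    arena_um: tuple[float, float],
    seed: int = 0,
    points_per_worm: int = 400,
) -> np.ndarray:
    """Per-frame centerline point sequences, shape (frames, points, 2) um.

    The body is laid along a closed elliptical patrol path inside the
    arena (so minute-long recordings stay in the field of view) with a
    sinusoidal undulation superimposed normal to the path; the head
    advances along the path at the gait speed while the undulation phase
    travels backwards along the body.  Every frame's centerline is
    re-sampled to the exact body arc length, uniformly spaced.
    Deterministic given the seed (which sets the starting station and
    undulation phase).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    width, height = arena_um
    margin = worm.gait_amplitude_um + worm.diameter_um + 10.0
    a = width / 2.0 - margin
    b = height / 2.0 - margin
    if a <= 0 or b <= 0:
        raise ValueError("arena too small for this worm's gait envelope")

    # dense arc-length parameterisation of the ellipse
    t = np.linspace(0.0, 2.0 * math.pi, 4096, endpoint=False)
    ex = width / 2.0 + a * np.cos(t)
    ey = height / 2.0 + b * np.sin(t)
    seg = np.hypot(np.diff(ex, append=ex[:1]), np.diff(ey, append=ey[:1]))
    s_knots = np.concatenate([[0.0], np.cumsum(seg)])
    circumference = s_knots[-1]
    if circumference < 1.3 * worm.length_um:
        raise ValueError("arena too small: patrol path shorter than the worm")
    ex_k = np.concatenate([ex, ex[:1]])
    ey_k = np.concatenate([ey, ey[:1]])

    def path_point(s):
        s = np.mod(s, circumference)
        x = np.interp(s, s_knots, ex_k)
        y = np.interp(s, s_knots, ey_k)
        return np.column_stack([x, y])

    rng = np.random.default_rng(seed)
    s0 = rng.uniform(0.0, circumference)
    phi0 = rng.uniform(0.0, 2.0 * math.pi)

    n_frames = int(round(duration_s * frame_rate_hz))
    times = np.arange(n_frames) / frame_rate_hz
    # undulation phase speed: wave travels one wavelength while the worm
    # advances one wavelength (retrograde wave, kinematically crawl-like)
    omega = 2.0 * math.pi * worm.gait_speed_um_s / worm.gait_wavelength_um

    du = 2.0
    u = np.arange(0.0, 1.25 * worm.length_um, du)  # head -> tail, overshoot
    frames = np.empty((n_frames, points_per_worm, 2), dtype=float)
    u_target = np.linspace(0.0, worm.length_um, points_per_worm)
    for f, tf in enumerate(times):
        s_head = s0 + worm.gait_speed_um_s * tf
        base = path_point(s_head - u)
        # tangent/normal along the path (central differences on the samples)
        d = np.gradient(base, axis=0)
        norm = np.hypot(d[:, 0], d[:, 1])
        norm[norm == 0] = 1.0
        nvec = np.column_stack([-d[:, 1] / norm, d[:, 0] / norm])
        lateral = worm.gait_amplitude_um * np.sin(
            2.0 * math.pi * u / worm.gait_wavelength_um - omega * tf + phi0
        )
        pts = base + nvec * lateral[:, None]
        # trim to the exact body arc length, then resample uniformly
        seglen = np.hypot(*np.diff(pts, axis=0).T)
        arclen = np.concatenate([[0.0], np.cumsum(seglen)])
        if arclen[-1] < worm.length_um:
            raise RuntimeError("overshoot too short for body length")
        frames[f, :, 0] = np.interp(u_target, arclen, pts[:, 0])
        frames[f, :, 1] = np.interp(u_target, arclen, pts[:, 1])
    return frames


# ----------------------------------------------------------------------
# ground-truth forces
# ----------------------------------------------------------------------

def assign_contact_forces(
    centerlines: np.ndarray,
    grid: PillarGrid,
    geometry: DeviceGeometry,
    worm_diameter_um: float,
    force_median_uN: float = 10.0,
    force_sigma_log: float = 0.3,
    multiplier: float = 1.0,
    seed: int = 0,
) -> GroundTruth:
    """Prescribe contact forces and the displacements they must produce.

    A pillar is contacted in a frame when its center lies within one worm
    radius of the centerline.  Contacted pillars draw independent
    log-normal force magnitudes (median ``force_median_uN`` x
    ``multiplier``, log-sd ``force_sigma_log``), directed along the local
    centerline normal, away from the body.  Displacements follow from the
    forward cantilever model at this worm's diameter.
    """
    if len(grid) == 0:
        raise ValueError("empty pillar grid")
    rng = np.random.default_rng(seed)
    radius = worm_diameter_um / 2.0
    centers = grid.centers_um
    n_frames = centerlines.shape[0]

    compliance_delta = force_to_deflection(1.0, geometry, worm_diameter_um)

    contacts = []
    frame_max_force = np.zeros(n_frames)
    frame_max_pillar = np.full(n_frames, -1, dtype=int)
    any_contact = False
    for f in range(n_frames):
        pts = centerlines[f]
        # distance from every pillar center to the sampled centerline
        d2 = (
            (centers[:, None, 0] - pts[None, :, 0]) ** 2
            + (centers[:, None, 1] - pts[None, :, 1]) ** 2
        )
        nearest = np.argmin(d2, axis=1)
        dist = np.sqrt(d2[np.arange(len(centers)), nearest])
        touched = np.flatnonzero(dist <= radius)
        if touched.size == 0:
            contacts.append(
                (np.empty(0, dtype=int), np.empty((0, 2)), np.empty((0, 2)))
            )
            continue
        any_contact = True
        if multiplier > 0:
            mags = np.exp(
                rng.normal(
                    math.log(force_median_uN * multiplier),
                    force_sigma_log,
                    touched.size,
                )
            )
        else:
            mags = np.zeros(touched.size)
        # push direction: from the nearest centerline point toward the pillar
        # (the outward normal of the body surface at the contact)
        vec = centers[touched] - pts[nearest[touched]]
        vnorm = np.hypot(vec[:, 0], vec[:, 1])
        vnorm[vnorm == 0] = 1.0
        unit = vec / vnorm[:, None]
        force_vec = unit * mags[:, None]
        disp_vec = unit * (mags * compliance_delta)[:, None]
        contacts.append((touched, force_vec, disp_vec))
        k = int(np.argmax(mags))
        frame_max_force[f] = mags[k]
        frame_max_pillar[f] = touched[k]

    true_f95 = float(np.percentile(frame_max_force, 95.0)) if n_frames else 0.0
    return GroundTruth(
        contacts=contacts,
        frame_max_force_uN=frame_max_force,
        frame_max_pillar=frame_max_pillar,
        true_f95_uN=true_f95,
        seed=seed,
        no_contact_warning=not any_contact,
    )


# ----------------------------------------------------------------------
# rendering
# ----------------------------------------------------------------------

# intensity model (8-bit): bright background, dark pillars and worm.
BACKGROUND_LEVEL = 200.0
PILLAR_DEPTH = 140.0      # darkness at the pillar center
PILLAR_CORE_SAG = 0.8     # radial intensity sag: profile = 1 - sag*(r/R)^2
WORM_DEPTH = 130.0
EGG_EXTRA_DEPTH = 55.0
EDGE_SOFT_PX = 0.75       # half-width of the linear anti-aliasing ramp
TAPER_UM = 60.0           # body taper length at head and tail


def _pillar_stamp(canvas: np.ndarray, cx_px: float, cy_px: float, radius_px: float) -> None:
    """Draw one pillar's darkness profile with subpixel placement (max-blend)."""
    h, w = canvas.shape
    r_ext = radius_px + EDGE_SOFT_PX + 1.0
    x0, x1 = int(math.floor(cx_px - r_ext)), int(math.ceil(cx_px + r_ext)) + 1
    y0, y1 = int(math.floor(cy_px - r_ext)), int(math.ceil(cy_px + r_ext)) + 1
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(xx - cx_px, yy - cy_px)
    core = 1.0 - PILLAR_CORE_SAG * (r / radius_px) ** 2
    edge = np.clip((radius_px + EDGE_SOFT_PX - r) / (2.0 * EDGE_SOFT_PX), 0.0, 1.0)
    prof = PILLAR_DEPTH * np.clip(core, 0.0, None) * edge
    np.maximum(canvas[y0:y1, x0:x1], prof, out=canvas[y0:y1, x0:x1])


def _tube_darkness(
    shape: tuple[int, int],
    points_px: np.ndarray,
    radius_px: float | np.ndarray,
    depth: float,
) -> np.ndarray:
    """Darkness map of a soft-edged tube along a dense point sequence.

    ``radius_px`` may vary per point (tapered body ends).
    """
    h, w = shape
    canvas = np.zeros(shape, dtype=float)
    radii = np.broadcast_to(np.asarray(radius_px, dtype=float), (len(points_px),))
    r_ext = float(radii.max()) + EDGE_SOFT_PX + 1.0
    ir = int(math.ceil(r_ext))
    # stamp grid shared by all samples
    yy, xx = np.mgrid[-ir : ir + 1, -ir : ir + 1]
    for (px, py), rad in zip(points_px, radii):
        if rad <= 0:
            continue
        cx, cy = int(round(px)), int(round(py))
        fx, fy = px - cx, py - cy
        r = np.hypot(xx - fx, yy - fy)
        prof = depth * np.clip(
            (rad + EDGE_SOFT_PX - r) / (2.0 * EDGE_SOFT_PX), 0.0, 1.0
        )
        x0, x1 = cx - ir, cx + ir + 1
        y0, y1 = cy - ir, cy + ir + 1
        sx0, sy0 = max(0, -x0), max(0, -y0)
        sx1 = prof.shape[1] - max(0, x1 - w)
        sy1 = prof.shape[0] - max(0, y1 - h)
        if sx0 >= sx1 or sy0 >= sy1:
            continue
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        np.maximum(
            canvas[y0:y1, x0:x1], prof[sy0:sy1, sx0:sx1], out=canvas[y0:y1, x0:x1]
        )
    return canvas


def render_frames(
    centerlines: np.ndarray,
    grid: PillarGrid,
    ground_truth: GroundTruth,
    geometry: DeviceGeometry,
    worm: WormModel | None,
    noise_sd: float = 5.0,
    illumination_gradient: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Rasterise a recording: (frames, H, W) uint8.

    Pillars are radially shaded dark disks (darkest at the center, as a
    slightly defocused pillar top appears) drawn at reference-plus-
    displacement positions with subpixel anti-aliasing; the worm is a dark
    soft-edged tube along the centerline, excluded from pillar footprints
    (the body bends around pillars, it cannot overlap them), with small
    darker inclusions mid-body for gravid adults.  Gaussian camera noise
    and an optional linear illumination gradient complete the frame.
    Pass ``worm=None`` (with empty centerlines) for worm-free recordings.
    """
    px = geometry.pixel_size_um
    if px <= 0:
        raise ValueError("pixel_size_um must be positive")
    h, w = geometry.image_height_px, geometry.image_width_px
    n_frames = ground_truth.n_frames if worm is None else centerlines.shape[0]
    radius_px = geometry.pillar_diameter_um / 2.0 / px
    centers_px = grid.centers_um / px
    if np.any(centers_px < -0.5) or np.any(centers_px[:, 0] > w - 0.5) or np.any(
        centers_px[:, 1] > h - 0.5
    ):
        raise ValueError("pillar grid outside the field of view")
    if worm is not None:
        lo = centerlines.min(axis=(0, 1)) / px
        hi = centerlines.max(axis=(0, 1)) / px
        half_w = worm.diameter_um / 2.0 / px
        if (
            lo[0] - half_w < -0.5
            or lo[1] - half_w < -0.5
            or hi[0] + half_w > w - 0.5
            or hi[1] + half_w > h - 0.5
        ):
            raise ValueError("worm outside the field of view")

    rng = np.random.default_rng(seed)
    bg = np.full((h, w), BACKGROUND_LEVEL, dtype=float)
    if illumination_gradient:
        ramp = illumination_gradient * (np.arange(w) / max(w - 1, 1) - 0.5)
        bg = bg * (1.0 + ramp)[None, :]

    stack = np.empty((n_frames, h, w), dtype=np.uint8)
    egg_offsets = None
    if worm is not None and worm.has_eggs:
        # fixed arc-length stations around mid-body, alternating small
        # lateral offsets; they ride along with the worm
        n_eggs = 6
        stations = np.linspace(0.35, 0.65, n_eggs) * worm.length_um
        egg_offsets = (stations, np.where(np.arange(n_eggs) % 2 == 0, 1.0, -1.0)
                       * 0.18 * worm.diameter_um)

    for f in range(n_frames):
        pillar_dark = np.zeros((h, w), dtype=float)
        disp_px = np.zeros_like(centers_px)
        idx, _fv, dv = ground_truth.contacts[f]
        if idx.size:
            disp_px[idx] = dv / px
        pos = centers_px + disp_px
        for (cx, cy) in pos:
            _pillar_stamp(pillar_dark, cx, cy, radius_px)

        worm_dark = np.zeros((h, w), dtype=float)
        if worm is not None:
            pts = centerlines[f]
            seglen = np.hypot(*np.diff(pts, axis=0).T)
            arclen = np.concatenate([[0.0], np.cumsum(seglen)])
            # disk-union spacing: scallop depth s^2/8r stays far below the
            # anti-aliasing ramp at 2.4 px spacing for a ~14 px radius
            dense_u = np.arange(0.0, arclen[-1], 2.4 * px)
            dense = np.column_stack(
                [np.interp(dense_u, arclen, pts[:, 0]),
                 np.interp(dense_u, arclen, pts[:, 1])]
            )
            # elliptical taper over the last TAPER_UM of head and tail so the
            # silhouette tips coincide with the centerline ends (a full-width
            # end cap would make the body read ~one diameter too long)
            end_dist = np.minimum(dense_u, arclen[-1] - dense_u)
            q = np.clip(end_dist / TAPER_UM, 0.0, 1.0)
            radii = (worm.diameter_um / 2.0 / px) * np.sqrt(q * (2.0 - q))
            worm_dark = _tube_darkness((h, w), dense / px, radii, WORM_DEPTH)
            if egg_offsets is not None:
                stations, lat = egg_offsets
                tangent = np.column_stack(
                    [np.interp(stations, arclen, np.gradient(pts[:, 0])),
                     np.interp(stations, arclen, np.gradient(pts[:, 1]))]
                )
                tn = np.hypot(tangent[:, 0], tangent[:, 1])
                tn[tn == 0] = 1.0
                normal = np.column_stack([-tangent[:, 1] / tn, tangent[:, 0] / tn])
                epos = np.column_stack(
                    [np.interp(stations, arclen, pts[:, 0]),
                     np.interp(stations, arclen, pts[:, 1])]
                ) + normal * lat[:, None]
                egg_dark = _tube_darkness(
                    (h, w), epos / px, 9.0 / px, WORM_DEPTH + EGG_EXTRA_DEPTH
                )
                np.maximum(worm_dark, egg_dark, out=worm_dark)
            # the body cannot overlap a pillar footprint: carve pillars out
            for (cx, cy) in pos:
                _suppress_disk(worm_dark, cx, cy, radius_px + 1.0)

        img = bg - np.maximum(pillar_dark, worm_dark)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        stack[f] = np.clip(img, 0, 255).astype(np.uint8)
    return stack


def _suppress_disk(canvas: np.ndarray, cx_px: float, cy_px: float, radius_px: float) -> None:
    """Zero a darkness map inside a disk, with a 1 px recovery ramp."""
    h, w = canvas.shape
    r_ext = radius_px + 2.0
    x0, x1 = max(int(cx_px - r_ext), 0), min(int(cx_px + r_ext) + 2, w)
    y0, y1 = max(int(cy_px - r_ext), 0), min(int(cy_px + r_ext) + 2, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(xx - cx_px, yy - cy_px)
    factor = np.clip(r - radius_px, 0.0, 1.0)
    canvas[y0:y1, x0:x1] *= factor


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

def generate_recording(
    worm: WormModel,
    geometry: DeviceGeometry,
    duration_s: float = 60.0,
    force_median_uN: float = 10.0,
    force_sigma_log: float = 0.3,
    multiplier: float = 1.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    render: bool = True,
    grid: PillarGrid | None = None,
) -> tuple[np.ndarray | None, GroundTruth, PillarGrid, np.ndarray]:
    """One animal's full synthetic recording.

    Returns (stack or None, ground truth, grid, centerlines).
    """
    if grid is None:
        grid = make_pillar_grid(geometry)
    ss = np.random.SeedSequence(seed)
    s_traj, s_force, s_noise = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)]
    centerlines = generate_trajectory(
        worm, duration_s, geometry.frame_rate_hz, geometry.fov_um, seed=s_traj
    )
    gt = assign_contact_forces(
        centerlines,
        grid,
        geometry,
        worm.diameter_um,
        force_median_uN=force_median_uN,
        force_sigma_log=force_sigma_log,
        multiplier=multiplier,
        seed=s_force,
    )
    stack = None
    if render:
        stack = render_frames(
            centerlines, grid, gt, geometry, worm, noise_sd=noise_sd, seed=s_noise
        )
    return stack, gt, grid, centerlines


def generate_cohort(
    design: CohortDesign,
    geometry: DeviceGeometry,
    noise_sd: float = 5.0,
    render: bool = True,
    out_dir: str | Path | None = None,
) -> Iterator[AnimalRecording]:
    """Yield one synthetic recording per animal of the design.

    Body diameter and length are drawn per animal from the group's normal
    distributions (clipped to +/- 3 SD); each animal also receives a
    mean-one log-normal strength factor with coefficient of variation
    ``design.animal_cv``, multiplying the group force scale.  Deterministic
    given ``design.seed``.  With ``out_dir`` set, writes a multi-page TIFF
    plus a JSON ground-truth sidecar per recording and a manifest CSV.
    """
    grid = make_pillar_grid(geometry)
    root = np.random.SeedSequence(design.seed)
    sigma_a = math.sqrt(math.log(1.0 + design.animal_cv**2))
    out_path = Path(out_dir) if out_dir is not None else None
    manifest_rows = []
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    child_seeds = root.spawn(design.n_animals)
    k = 0
    for group in design.groups:
        for i in range(group.n):
            ss = child_seeds[k]
            k += 1
            rng = np.random.default_rng(ss)
            diameter = _clipped_normal(
                rng, group.diameter_mean_um, group.diameter_sd_um, lo=20.0
            )
            length = _clipped_normal(
                rng, group.length_mean_um, group.length_sd_um, lo=400.0
            )
            scale = group.force_multiplier * math.exp(
                rng.normal(0.0, sigma_a) - sigma_a**2 / 2.0
            )
            worm = WormModel(length_um=length, diameter_um=diameter, has_eggs=True)
            rec_seed = int(ss.generate_state(1)[0] % 2**31)
            stack, gt, _grid, _cl = generate_recording(
                worm,
                geometry,
                duration_s=design.duration_s,
                force_median_uN=design.force_median_uN,
                force_sigma_log=design.force_sigma_log,
                multiplier=scale,
                noise_sd=noise_sd,
                seed=rec_seed,
                render=render,
                grid=grid,
            )
            animal_id = f"{group.strain}_{group.environment}_{i:03d}"
            rec = AnimalRecording(
                animal_id=animal_id,
                strain=group.strain,
                environment=group.environment,
                worm=worm,
                grid=grid,
                ground_truth=gt,
                stack=stack,
            )
            if out_path is not None:
                if stack is not None:
                    tifffile.imwrite(out_path / f"{animal_id}.tif", stack)
                gt.to_json(out_path / f"{animal_id}.groundtruth.json")
                manifest_rows.append(
                    {
                        "animal_id": animal_id,
                        "strain": group.strain,
                        "environment": group.environment,
                        "true_diameter_um": round(diameter, 4),
                        "true_length_um": round(length, 4),
                        "true_f95_uN": round(gt.true_f95_uN, 6),
                        "seed": rec_seed,
                    }
                )
            yield rec
    if out_path is not None and manifest_rows:
        with open(out_path / "manifest.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(manifest_rows[0]))
            writer.writeheader()
            writer.writerows(manifest_rows)


def _clipped_normal(rng, mean, sd, lo):
    value = rng.normal(mean, sd)
    value = min(max(value, mean - 3.0 * sd), mean + 3.0 * sd)
    return max(value, lo)
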