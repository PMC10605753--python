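"""Device geometry and pillar mechanics.

The strength assay images a worm crawling through a square lattice of
deformable PDMS micropillars.  Each pillar is a stubby circular cantilever
clamped at the chamber floor; the worm pushes on it at a height set by its
own body radius, and the camera reads the lateral displacement of the
pillar *top*.  Because the pillars have diameter comparable to their height
(d/L ~ 0.55), bending alone underestimates how compliant they are, so the
deflection-to-force conversion uses Timoshenko beam theory (bending plus
shear) with the standard circular-section shear coefficient
kappa = 6(1 + nu) / (7 + 6 nu).

For a point load F applied at height ``a`` on a clamped cantilever of
length L, with the displacement read at the free end (the pillar top):

    delta_top = F * [ a^2 (3L - a) / (6 E I)  +  a / (kappa G A) ]

with I = pi d^4 / 64, A = pi d^2 / 4 and G = E / (2 (1 + nu)).  Units are
micrometres, micronewtons and MPa (1 MPa = 1 uN/um^2), so compliance comes
out in um/uN directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = [
    "DeviceGeometry",
    "ContactModel",
    "contact_height",
    "pillar_compliance",
    "deflection_to_force",
    "force_to_deflection",
]


@dataclass(frozen=True)
class DeviceGeometry:
    """Pillar-arena geometry, elastomer constants and imaging parameters.

    Lengths in micrometres, modulus in MPa.  Defaults describe the
    flight-type arena: 80 um pillars in a ~100 um deep chamber cast from
    Sylgard 184 at 10:1, imaged at 4x (1.6 um/px) and 5 frames/s.
    """

    pillar_height_um: float = 80.0
    pillar_diameter_um: float = 44.0
    lattice_pitch_um: float = 120.0
    chamber_depth_um: float = 100.0
    youngs_modulus_MPa: float = 2.0
    poisson_ratio: float = 0.499
    pixel_size_um: float = 1.6
    frame_rate_hz: float = 5.0
    image_width_px: int = 1920
    image_height_px: int = 1080

    def __post_init__(self) -> None:
        for name in (
            "pillar_height_um",
            "pillar_diameter_um",
            "lattice_pitch_um",
            "chamber_depth_um",
            "youngs_modulus_MPa",
            "pixel_size_um",
            "frame_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 < self.poisson_ratio <= 0.4999999):
            raise ValueError("poisson_ratio must lie in (0, 0.5)")
        if self.pillar_height_um >= self.chamber_depth_um:
            raise ValueError("pillar_height_um must be below chamber_depth_um")
        if self.pillar_diameter_um >= self.lattice_pitch_um:
            raise ValueError("pillar_diameter_um must be below lattice_pitch_um")
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")

    # -- derived section properties -------------------------------------
    @property
    def second_moment_um4(self) -> float:
        """Area moment of inertia I = pi d^4 / 64 of the circular section."""
        return math.pi * self.pillar_diameter_um**4 / 64.0

    @property
    def section_area_um2(self) -> float:
        return math.pi * self.pillar_diameter_um**2 / 4.0

    @property
    def shear_modulus_MPa(self) -> float:
        return self.youngs_modulus_MPa / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def shear_coefficient(self) -> float:
        """Timoshenko shear coefficient for a solid circular section."""
        nu = self.poisson_ratio
        return 6.0 * (1.0 + nu) / (7.0 + 6.0 * nu)

    @property
    def fov_um(self) -> tuple[float, float]:
        """(width, height) of the imaged field of view in micrometres."""
        return (
            self.image_width_px * self.pixel_size_um,
            self.image_height_px * self.pixel_size_um,
        )

    # -- config round-trip ----------------------------------------------
    @classmethod
    def from_config(cls, path: str | Path) -> "DeviceGeometry":
        """Load geometry from a flat key/value YAML file (units in key names)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "DeviceGeometry":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class ContactModel:
    """Where along the pillar the worm applies its load.

    A worm of diameter D lying on the chamber floor pushes with its
    centerline at one body radius above the base, so the nominal load
    height is a = D/2, clamped to the pillar top for (hypothetical)
    bodies thicker than the pillar is tall.
    """

    contact_height_um: float
    worm_diameter_um: float

    def __post_init__(self) -> None:
        if self.contact_height_um <= 0:
            raise ValueError("contact_height_um must be positive")
        if self.worm_diameter_um <= 0:
            raise ValueError("worm_diameter_um must be positive")


def contact_height(worm_diameter_um: float, geometry: DeviceGeometry) -> float:
    """Load height above the pillar base for a worm of given diameter (um).

    The worm rests on the floor, so its centerline — the nominal line of
    action — sits at one body radius; the result is clamped to the pillar
    height.
    """
    if worm_diameter_um <= 0:
        raise ValueError("worm_diameter_um must be positive")
    return min(worm_diameter_um / 2.0, geometry.pillar_height_um)


def pillar_compliance(geometry: DeviceGeometry, contact_height_um: float) -> float:
    """Top-displacement compliance c (um/uN) for a point load at height a.

    delta_top = c * F with the Timoshenko clamped-cantilever model: the
    bending term a^2 (3L - a) / (6 E I) plus the shear term a / (kappa G A).
    """
    a = contact_height_um
    L = geometry.pillar_height_um
    if not (0.0 < a <= L):
        raise ValueError("contact height must satisfy 0 < a <= pillar height")
    EI = geometry.youngs_modulus_MPa * geometry.second_moment_um4
    bending = a * a * (3.0 * L - a) / (6.0 * EI)
    shear = a / (
        geometry.shear_coefficient
        * geometry.shear_modulus_MPa
        * geometry.section_area_um2
    )
    return bending + shear


def deflection_to_force(
    deflection_um: float,
    geometry: DeviceGeometry,
    worm_diameter_um: float,
) -> float:
    """Convert an observed pillar-top deflection (um) to contact force (uN).

    The conversion is linear at fixed body diameter; the diameter enters
    through the contact height, which is why force estimation must be
    adjusted for each animal's measured mid-section diameter.
    """
    deflection_um = _as_nonnegative(deflection_um, "deflection_um")
    a = contact_height(worm_diameter_um, geometry)
    return deflection_um / pillar_compliance(geometry, a)


def force_to_deflection(
    force_uN: float,
    geometry: DeviceGeometry,
    worm_diameter_um: float,
) -> float:
    """Forward model: pillar-top deflection (um) produced by a force (uN)."""
    force_uN = _as_nonnegative(force_uN, "force_uN")
    a = contact_height(worm_diameter_um, geometry)
    return force_uN * pillar_compliance(geometry, a)


def _as_nonnegative(value, name):
    import numpy as np

    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative")
    return arr if arr.ndim else float(arr)
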