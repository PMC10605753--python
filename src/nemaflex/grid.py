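"""Reference pillar lattice container shared by the simulator and tracker."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import DeviceGeometry

__all__ = ["PillarGrid", "make_pillar_grid"]


@dataclass
class PillarGrid:
    """Undeflected pillar centers plus the rigid-lattice fit behind them.

    ``centers_um`` is an (N, 2) array of (x, y) positions in micrometres in
    image-frame coordinates (x = column direction, y = row direction,
    pixel centers at integer pixel coordinates times the pixel size).
    """

    centers_um: np.ndarray
    pitch_um: float
    orientation_rad: float = 0.0
    origin_um: tuple[float, float] = (0.0, 0.0)
    valid: np.ndarray | None = None
    fit_residual_um: float = 0.0

    def __post_init__(self) -> None:
        self.centers_um = np.asarray(self.centers_um, dtype=float).reshape(-1, 2)
        if self.valid is None:
            self.valid = np.ones(len(self.centers_um), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.valid) != len(self.centers_um):
            raise ValueError("valid flags must match number of centers")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")

    def __len__(self) -> int:
        return len(self.centers_um)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centers_um": self.centers_um.tolist(),
            "pitch_um": self.pitch_um,
            "orientation_rad": self.orientation_rad,
            "origin_um": list(self.origin_um),
            "valid": self.valid.astype(int).tolist(),
            "fit_residual_um": self.fit_residual_um,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PillarGrid":
        payload = json.loads(Path(path).read_text())
        return cls(
            centers_um=np.asarray(payload["centers_um"], dtype=float),
            pitch_um=payload["pitch_um"],
            orientation_rad=payload.get("orientation_rad", 0.0),
            origin_um=tuple(payload.get("origin_um", (0.0, 0.0))),
            valid=np.asarray(payload.get("valid"), dtype=bool)
            if payload.get("valid") is not None
            else None,
            fit_residual_um=payload.get("fit_residual_um", 0.0),
        )


def make_pillar_grid(geometry: DeviceGeometry, margin_um: float | None = None) -> PillarGrid:
    """Build the true (simulated) square pillar lattice filling the field of view."""
    width_um, height_um = geometry.fov_um
    pitch = geometry.lattice_pitch_um
    if margin_um is None:
        margin_um = pitch / 2.0
    xs = np.arange(margin_um, width_um - margin_um + 1e-9, pitch)
    ys = np.arange(margin_um, height_um - margin_um + 1e-9, pitch)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("field of view too small for any pillar")
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    return PillarGrid(
        centers_um=centers,
        pitch_um=pitch,
        orientation_rad=0.0,
        origin_um=(float(xs[0]), float(ys[0])),
    )
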