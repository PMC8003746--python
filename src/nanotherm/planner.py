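"""Tile-scan treatment planner for focal two-photon photothermal therapy.

A treatment is a rectangular grid of square-ish scan fields, each irradiated
for a fixed time through a stack of focal planes stepped into the tissue.
The planner derives the treated volume, the total time budget, and a
row-major per-field schedule.

Axial depth is ``n_planes * plane_interval`` — the convention in which
38 planes stepped by 20 um treat a 0.76 mm column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

__all__ = ["TreatmentGrid", "TreatmentPlan", "FieldSlot", "plan"]

UM_TO_MM = 1e-3


@dataclass(frozen=True)
class TreatmentGrid:
    """Tile-scan geometry and per-field dwell parameters."""

    nx: int = 8
    ny: int = 5
    field_size_x: float = 1412.5  # um
    field_size_y: float = 1434.0  # um
    n_planes: int = 38
    plane_interval: float = 20.0  # um
    time_per_field: float = 1.725  # min
    wavelength: float = 720.0  # nm
    power: float = 1.75  # W

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1 or self.n_planes < 1:
            raise ValueError("counts must be >= 1")
        for name in ("field_size_x", "field_size_y", "plane_interval",
                     "time_per_field"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class FieldSlot:
    """One scheduled scan field: index, lateral origin, timing, z-range."""

    index: int
    ix: int
    iy: int
    x0_um: float
    y0_um: float
    start_min: float
    stop_min: float
    z_range_um: Tuple[float, float]


@dataclass(frozen=True)
class TreatmentPlan:
    """Derived volume/time budget plus the ordered field schedule."""

    volume_dims: Tuple[float, float, float]  # mm
    total_fields: int
    total_time: float  # min
    per_field_schedule: Tuple[FieldSlot, ...]

    @property
    def volume_mm3(self) -> float:
        x, y, z = self.volume_dims
        return x * y * z


def plan(grid: TreatmentGrid) -> TreatmentPlan:
    """Derive the treatment plan for a tile-scan grid.

    Volume = (nx * field_size_x) x (ny * field_size_y) x
    (n_planes * plane_interval), in mm; total time = nx * ny *
    time_per_field; fields scheduled contiguously in row-major order
    (x fastest), origin at the first field's corner, z positive into tissue.
    """
    dims = (
        grid.nx * grid.field_size_x * UM_TO_MM,
        grid.ny * grid.field_size_y * UM_TO_MM,
        grid.n_planes * grid.plane_interval * UM_TO_MM,
    )
    total_fields = grid.nx * grid.ny
    z_range = (0.0, grid.n_planes * grid.plane_interval)
    schedule = []
    for idx in range(total_fields):
        ix, iy = idx % grid.nx, idx // grid.nx
        schedule.append(
            FieldSlot(
                index=idx,
                ix=ix,
                iy=iy,
                x0_um=ix * grid.field_size_x,
                y0_um=iy * grid.field_size_y,
                start_min=idx * grid.time_per_field,
                stop_min=(idx + 1) * grid.time_per_field,
                z_range_um=z_range,
            )
        )
    return TreatmentPlan(
        volume_dims=dims,
        total_fields=total_fields,
        total_time=total_fields * grid.time_per_field,
        per_field_schedule=tuple(schedule),
    )
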