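"""Heat transport around a single absorbing nanoparticle.

Steady-state temperature field of a stratified sphere whose gold shell
absorbs the laser power (uniform volumetric generation confined to that
layer), plus the continuous-point-source transient solution used to fit
bulk heating curves.

For spherical symmetry the steady conduction problem has an exact piecewise
closed form, which is the primary path; a conservative finite-volume radial
solver of the same boundary problem is provided as a numerical cross-check.
Everywhere outside the particle the rise is the monopole field

    dT(r) = P / (4 pi k_medium r),

independent of the internal layering — only the internal profile and the
surface temperature depend on layer conductivities and (optional) finite
interface conductance.

Units: radii in nm at the interface (converted internally to m), power in
W, conductivity in W m^-1 K^-1, diffusivity in m^2 s^-1, temperatures as
rises (K) above ambient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import erfc

from .mie import CrossSections

__all__ = [
    "LayeredParticleThermal",
    "TemperatureProfile",
    "PointSourceFit",
    "steady_profile",
    "steady_profile_numeric",
    "point_source_delta_t",
    "absorbed_power_from_irradiance",
    "WATER_CONDUCTIVITY",
    "WATER_DIFFUSIVITY",
]

NM = 1e-9
#: Thermal conductivity of water at room temperature, W m^-1 K^-1.
WATER_CONDUCTIVITY = 0.6
#: Thermal diffusivity of water at room temperature, m^2 s^-1.
WATER_DIFFUSIVITY = 1.43e-7


@dataclass
class LayeredParticleThermal:
    """Thermal counterpart of the stratified particle.

    ``source_layer`` selects the layer that absorbs the light (0-based);
    for the magnetite/gold/polymer particle this is layer 1, the gold shell.
    ``interface_conductance`` (W m^-2 K^-1), if given, applies a Kapitza
    temperature jump q/G at every interface; ``None`` means perfect contact.
    """

    layer_outer_radii: Sequence[float]  # nm
    layer_conductivity: Sequence[float]  # W/m/K
    medium_conductivity: float = WATER_CONDUCTIVITY
    medium_diffusivity: float = WATER_DIFFUSIVITY
    interface_conductance: Optional[float] = None
    source_layer: int = 1

    def __post_init__(self) -> None:
        radii = np.asarray(self.layer_outer_radii, dtype=float)
        cond = np.asarray(self.layer_conductivity, dtype=float)
        if radii.ndim != 1 or radii.size < 1:
            raise ValueError("need at least one layer")
        if radii[0] <= 0 or np.any(np.diff(radii) <= 0):
            raise ValueError("layer radii must be strictly increasing and > 0")
        if cond.size != radii.size:
            raise ValueError("one conductivity per layer required")
        if np.any(cond <= 0) or self.medium_conductivity <= 0:
            raise ValueError("conductivities must be > 0")
        if self.medium_diffusivity <= 0:
            raise ValueError("medium diffusivity must be > 0")
        if not 0 <= self.source_layer < radii.size:
            raise ValueError("source_layer out of range")
        if self.interface_conductance is not None and self.interface_conductance <= 0:
            raise ValueError("interface_conductance must be > 0 when given")
        self.layer_outer_radii = radii
        self.layer_conductivity = cond

    @property
    def outer_radius_m(self) -> float:
        return float(self.layer_outer_radii[-1]) * NM


@dataclass(frozen=True)
class TemperatureProfile:
    """Radial temperature rise dT(r) above ambient around one particle."""

    radius_grid: np.ndarray  # nm
    delta_t: np.ndarray  # K
    surface_delta_t: float  # K, at the particle outer surface
    absorbed_power: float  # W


@dataclass(frozen=True)
class PointSourceFit:
    """Continuous-point-source fit dT(t) = dT_inf * erfc(beta / sqrt(t))."""

    delta_t_inf: float  # K
    beta: float  # s^(1/2), lumped r/(2 sqrt(alpha))
    residual_rms: float  # K

    def __post_init__(self) -> None:
        if not (self.delta_t_inf > 0 and self.beta > 0):
            raise ValueError("delta_t_inf and beta must be > 0")


def _default_grid(thermal: LayeredParticleThermal) -> np.ndarray:
    """Radial evaluation grid (nm): dense inside layers, stretched to 200 R."""
    radii = np.asarray(thermal.layer_outer_radii, dtype=float)
    pieces = [np.linspace(0.0, radii[0], 25)]
    for j in range(1, radii.size):
        pieces.append(np.linspace(radii[j - 1], radii[j], 25)[1:])
    r_out = radii[-1]
    pieces.append(np.geomspace(r_out, 200.0 * r_out, 120)[1:])
    return np.concatenate(pieces)


def steady_profile(
    thermal: LayeredParticleThermal,
    absorbed_power: float,
    radius_grid: Optional[np.ndarray] = None,
) -> TemperatureProfile:
    """Exact steady-state dT(r) with uniform generation in the source layer.

    Solves (1/r^2) d/dr (k r^2 dT/dr) = -q_v piecewise: the enclosed power
    below the source layer is zero (isothermal core), the full absorbed
    power above it, with continuity of flux everywhere and continuity of
    temperature (or a q/G jump) at the interfaces.
    """
    if not np.isfinite(absorbed_power) or absorbed_power < 0:
        raise ValueError("absorbed_power must be finite and >= 0")
    radii_m = np.asarray(thermal.layer_outer_radii, dtype=float) * NM
    cond = np.asarray(thermal.layer_conductivity, dtype=float)
    P = absorbed_power
    js = thermal.source_layer
    r_in = radii_m[js - 1] if js > 0 else 0.0
    r_src_out = radii_m[js]
    v_shell = 4.0 / 3.0 * math.pi * (r_src_out**3 - r_in**3)
    q_v = P / v_shell if P > 0 else 0.0

    def enclosed_power(r: float) -> float:
        """Heat generated inside radius r."""
        if r <= r_in:
            return 0.0
        if r >= r_src_out:
            return P
        return q_v * 4.0 / 3.0 * math.pi * (r**3 - r_in**3)

    def temp_in_region(r: np.ndarray, k: float, c: float, region: str) -> np.ndarray:
        """dT within one region given its integration constant c."""
        if region == "outside":  # no generation, enclosed power P
            return P / (4.0 * math.pi * k * np.maximum(r, 1e-300)) + c
        if region == "inside":  # no generation, zero enclosed power: constant
            return np.full_like(r, c)
        # source region: dT/dr = -q_v (r^3 - r_in^3) / (3 k r^2)
        return -q_v / (3.0 * k) * (r**2 / 2.0 + np.divide(
            r_in**3, r, out=np.zeros_like(r), where=r > 0)) + c

    # Build region constants from the outside in.
    # Medium: c = 0 (dT -> 0 at infinity).
    n_layers = radii_m.size
    constants = np.zeros(n_layers)  # per layer
    G = thermal.interface_conductance

    def region_kind(j: int) -> str:
        if j > js:
            return "outside"
        if j < js:
            return "inside"
        return "source"

    t_outer_side = P / (4.0 * math.pi * thermal.medium_conductivity * radii_m[-1])
    for j in range(n_layers - 1, -1, -1):
        r_j = radii_m[j]
        if j == n_layers - 1:
            t_out = t_outer_side
        else:
            t_out = temp_in_region(
                np.array([r_j]), cond[j + 1], constants[j + 1], region_kind(j + 1)
            )[0]
        if G is not None:
            t_out += enclosed_power(r_j) / (4.0 * math.pi * r_j**2 * G)
        # choose constant so this layer's profile meets t_out at r_j
        base = temp_in_region(np.array([r_j]), cond[j], 0.0, region_kind(j))[0]
        constants[j] = t_out - base

    if radius_grid is None:
        radius_grid = _default_grid(thermal)
    r_nm = np.asarray(radius_grid, dtype=float)
    r = r_nm * NM
    dt = np.empty_like(r)
    edges = np.concatenate([[0.0], radii_m])
    for j in range(n_layers):
        mask = (r >= edges[j]) & (r <= edges[j + 1]) if j == 0 else (
            (r > edges[j]) & (r <= edges[j + 1])
        )
        dt[mask] = temp_in_region(r[mask], cond[j], constants[j], region_kind(j))
    mask = r > radii_m[-1]
    dt[mask] = temp_in_region(r[mask], thermal.medium_conductivity, 0.0, "outside")

    surface_dt = temp_in_region(
        np.array([radii_m[-1]]), cond[-1], constants[-1], region_kind(n_layers - 1)
    )[0]
    return TemperatureProfile(
        radius_grid=r_nm,
        delta_t=dt,
        surface_delta_t=float(surface_dt),
        absorbed_power=P,
    )


@dataclass(frozen=True)
class GridSpec:
    """Radial mesh for the numeric solver: nodes per layer + stretched tail."""

    nodes_per_layer: int = 40
    outer_factor: float = 150.0  # domain extends to outer_factor * R
    outer_nodes: int = 400

    def __post_init__(self) -> None:
        if self.nodes_per_layer < 20:
            raise ValueError("need >= 20 nodes per layer")
        if self.outer_factor < 100.0:
            raise ValueError("outer boundary must be >= 100 R")


def steady_profile_numeric(
    thermal: LayeredParticleThermal,
    absorbed_power: float,
    grid_spec: GridSpec = GridSpec(),
    return_flux: bool = False,
):
    """Finite-volume solution of the same steady boundary problem.

    Conservative second-order scheme on a face-aligned radial mesh
    (layer boundaries coincide with cell faces, harmonic-mean face
    conductivities); the outer boundary carries the exact monopole value
    P/(4 pi k r_max), so the remaining error is purely discretization.
    Perfect interface contact only (the analytic path handles Kapitza jumps).
    """
    if not np.isfinite(absorbed_power) or absorbed_power < 0:
        raise ValueError("absorbed_power must be finite and >= 0")
    if thermal.interface_conductance is not None:
        raise NotImplementedError("numeric solver assumes perfect interface contact")
    radii_m = np.asarray(thermal.layer_outer_radii, dtype=float) * NM
    cond = np.asarray(thermal.layer_conductivity, dtype=float)
    k_med = thermal.medium_conductivity
    P = absorbed_power
    js = thermal.source_layer
    r_in = radii_m[js - 1] if js > 0 else 0.0
    r_src = radii_m[js]
    v_shell = 4.0 / 3.0 * math.pi * (r_src**3 - r_in**3)
    q_v = P / v_shell if P > 0 else 0.0

    # face positions: uniform within each layer, geometric tail outside
    faces = [np.linspace(0.0, radii_m[0], grid_spec.nodes_per_layer + 1)]
    for j in range(1, radii_m.size):
        faces.append(
            np.linspace(radii_m[j - 1], radii_m[j], grid_spec.nodes_per_layer + 1)[1:]
        )
    r_max = grid_spec.outer_factor * radii_m[-1]
    faces.append(np.geomspace(radii_m[-1], r_max, grid_spec.outer_nodes + 1)[1:])
    rf = np.concatenate(faces)
    nc = rf.size - 1  # cells
    rc = 0.5 * (rf[:-1] + rf[1:])

    def k_of(r: float) -> float:
        for j, rj in enumerate(radii_m):
            if r <= rj:
                return float(cond[j])
        return k_med

    k_cell = np.array([k_of(r) for r in rc])
    # source per cell: exact overlap volume with the source shell
    lo = np.clip(rf[:-1], r_in, r_src)
    hi = np.clip(rf[1:], r_in, r_src)
    src = q_v * 4.0 / 3.0 * math.pi * np.maximum(hi**3 - lo**3, 0.0)

    # interior faces i = 1..nc-1 between cells i-1 and i
    d_minus = rf[1:-1] - rc[:-1]
    d_plus = rc[1:] - rf[1:-1]
    k_face = (d_minus + d_plus) / (d_minus / k_cell[:-1] + d_plus / k_cell[1:])
    cond_face = 4.0 * math.pi * rf[1:-1] ** 2 * k_face / (rc[1:] - rc[:-1])

    # assemble tridiagonal (unknown: cell-average dT); r=0 face: zero flux
    ab = np.zeros((3, nc))
    rhs = src.copy()
    for i in range(nc - 1):
        ab[1, i] += cond_face[i]
        ab[1, i + 1] += cond_face[i]
        ab[0, i + 1] -= cond_face[i]  # upper
        ab[2, i] -= cond_face[i]  # lower
    # outer boundary: Dirichlet at r_max with exact monopole value
    t_bc = P / (4.0 * math.pi * k_med * r_max)
    d_b = r_max - rc[-1]
    cond_b = 4.0 * math.pi * r_max**2 * k_med / d_b
    ab[1, -1] += cond_b
    rhs[-1] += cond_b * t_bc

    try:
        dt_cells = solve_banded((1, 1), ab, rhs)
    except Exception as exc:  # pragma: no cover - singular systems
        raise RuntimeError(
            f"radial solve failed on {nc} cells spanning [0, {r_max:.3e}] m: {exc}"
        ) from exc
    if not np.all(np.isfinite(dt_cells)):
        raise RuntimeError(f"non-finite solution on {nc}-cell grid")

    r_surf = radii_m[-1]
    surface_dt = float(np.interp(r_surf, rc, dt_cells))
    profile = TemperatureProfile(
        radius_grid=rc / NM,
        delta_t=dt_cells,
        surface_delta_t=surface_dt,
        absorbed_power=P,
    )
    if return_flux:
        # outward heat current through every interior face, W
        flux = cond_face * (dt_cells[:-1] - dt_cells[1:])
        return profile, (rf[1:-1] / NM, flux)
    return profile


def point_source_delta_t(power: float, k: float, alpha: float, r, t):
    """Transient rise of a continuous point source (SI units).

    dT(r, t) = P / (4 pi k r) * erfc(r / (2 sqrt(alpha t)));
    t = 0 returns 0 by continuity.  Monotone increasing in t, decreasing
    in r, approaching the steady monopole P/(4 pi k r) as t -> infinity.
    """
    if power < 0 or k <= 0 or alpha <= 0:
        raise ValueError("power >= 0 and k, alpha > 0 required")
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(r <= 0) or np.any(t < 0):
        raise ValueError("r > 0 and t >= 0 required")
    with np.errstate(divide="ignore"):
        arg = np.where(t > 0, r / (2.0 * np.sqrt(alpha * np.maximum(t, 1e-300))), np.inf)
    out = power / (4.0 * math.pi * k * r) * erfc(arg)
    return out if out.ndim else float(out)


def absorbed_power_from_irradiance(cross: CrossSections, irradiance: float) -> float:
    """Absorbed power P = sigma_abs * irradiance (irradiance in W m^-2)."""
    if irradiance < 0:
        raise ValueError("irradiance must be >= 0")
    return cross.sigma_abs_m2 * irradiance
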