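"""Mie scattering by stratified (multilayer) spheres.

Computes extinction, scattering, and absorption cross-sections of a
concentric core/shell(s) sphere embedded in a non-absorbing medium — the
optical front end of the photothermal chain: the absorption cross-section
at the irradiation wavelength, times the irradiance, is the heat source
driving a single particle.

The particle here is the three-layer magnetite-core / gold-shell /
polymer-coat geometry, but any number of layers is supported.  The spiky
"turtle shell" surface of the real particles is idealised as a smooth
stratified sphere (a known limitation — see the package docs); this is the
same approximation the underlying physics model makes.

Algorithm
---------
Per multipole order the layer fields are carried as effective logarithmic
derivatives of the radial Riccati-Bessel combinations, propagated outward
layer by layer (the recursive formulation of Yang, Appl. Opt. 42, 1710,
generalised Toon-Ackerman).  Within each layer the regular log-derivative
``D1`` is generated by downward recurrence (started ``N + 15`` orders above
the Wiscombe truncation), the outgoing ``D3`` by the stable upward product
recurrence, and the bounded ratio ``Q = (psi/xi)(z_inner) / (psi/xi)(z_outer)``
iteratively — never forming the overflow-prone psi/chi values inside
absorbing layers.

Time convention is ``exp(-i omega t)``: absorbing layers have
``Im(index) >= 0``, enforced at construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DispersionTable",
    "LayeredParticleOptics",
    "MieSeries",
    "CrossSections",
    "compute_mie_series",
    "cross_sections",
    "wiscombe_terms",
    "gold_dispersion",
    "magnetite_dispersion",
    "POLYMER_INDEX",
]

_DATA_DIR = Path(__file__).parent / "data"

#: Constant refractive index used for the polymer (PVP) coat by default.
POLYMER_INDEX = 1.50 + 0.0j


class DispersionRangeError(ValueError):
    """Requested wavelength falls outside a layer's dispersion table."""


@dataclass(frozen=True)
class DispersionTable:
    """Tabulated complex refractive index n(lambda) + i k(lambda).

    n and k are interpolated linearly and independently between rows;
    evaluation outside the tabulated range raises rather than extrapolates.
    """

    wavelength_nm: np.ndarray
    n: np.ndarray
    k: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelength_nm, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("dispersion table needs >= 2 rows")
        if not np.all(np.diff(w) > 0):
            raise ValueError("dispersion table wavelengths must be strictly increasing")
        if w.size != n.size or w.size != k.size:
            raise ValueError("wavelength, n, k columns must have equal length")
        if np.any(k < 0):
            raise ValueError("k must be >= 0 (exp(-i omega t) convention)")
        object.__setattr__(self, "wavelength_nm", w)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)

    @classmethod
    def from_csv(cls, path: Union[str, Path], label: str = "") -> "DispersionTable":
        """Read a ``wavelength_nm,n,k`` CSV (comment lines start with '#')."""
        df = pd.read_csv(path, comment="#")
        return cls(
            wavelength_nm=df["wavelength_nm"].to_numpy(),
            n=df["n"].to_numpy(),
            k=df["k"].to_numpy(),
            label=label or str(path),
        )

    def __call__(self, wavelength_nm: float) -> complex:
        w = self.wavelength_nm
        if wavelength_nm < w[0] or wavelength_nm > w[-1]:
            raise DispersionRangeError(
                f"wavelength {wavelength_nm} nm outside dispersion range "
                f"[{w[0]}, {w[-1]}] nm of table {self.label!r}"
            )
        n = float(np.interp(wavelength_nm, w, self.n))
        k = float(np.interp(wavelength_nm, w, self.k))
        return complex(n, k)


LayerIndex = Union[complex, float, DispersionTable]


def gold_dispersion() -> DispersionTable:
    """Packaged default gold n,k table (approximate literature values)."""
    return DispersionTable.from_csv(_DATA_DIR / "gold_nk.csv", label="gold (packaged)")


def magnetite_dispersion() -> DispersionTable:
    """Packaged default magnetite n,k table (approximate literature values)."""
    return DispersionTable.from_csv(
        _DATA_DIR / "magnetite_nk.csv", label="magnetite (packaged)"
    )


@dataclass
class LayeredParticleOptics:
    """Concentric multilayer sphere geometry with per-layer refractive index.

    Parameters
    ----------
    layer_outer_radii : sequence of float
        Outer radius of each layer in nm, innermost first, strictly increasing.
    layer_index : sequence of complex or DispersionTable
        Complex refractive index per layer; ``Im >= 0``.
    medium_index : float
        Real refractive index of the non-absorbing host medium (>= 1).
    """

    layer_outer_radii: Sequence[float]
    layer_index: Sequence[LayerIndex]
    medium_index: float = 1.33

    def __post_init__(self) -> None:
        radii = np.asarray(self.layer_outer_radii, dtype=float)
        if radii.ndim != 1 or radii.size < 1:
            raise ValueError("need at least one layer")
        if radii[0] <= 0 or np.any(np.diff(radii) < 0):
            raise ValueError("layer radii must be > 0 and non-decreasing")
        if len(self.layer_index) != radii.size:
            raise ValueError("one refractive index per layer required")
        for j, idx in enumerate(self.layer_index):
            if not isinstance(idx, DispersionTable):
                m = complex(idx)
                if m.imag < 0:
                    raise ValueError(
                        f"layer {j}: Im(index) must be >= 0 (exp(-i omega t) convention)"
                    )
                if m.real <= 0:
                    raise ValueError(f"layer {j}: Re(index) must be > 0")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")
        self.layer_outer_radii = radii

    def indices_at(self, wavelength_nm: float) -> np.ndarray:
        """Complex index of every layer at one wavelength."""
        out = []
        for j, idx in enumerate(self.layer_index):
            if isinstance(idx, DispersionTable):
                try:
                    out.append(idx(wavelength_nm))
                except DispersionRangeError as exc:
                    raise DispersionRangeError(f"layer {j}: {exc}") from None
            else:
                out.append(complex(idx))
        return np.asarray(out, dtype=complex)

    def collapsed(self, wavelength_nm: float) -> tuple[np.ndarray, np.ndarray]:
        """Radii and indices with zero-thickness layers dropped (with warning)."""
        radii = np.asarray(self.layer_outer_radii, dtype=float)
        idx = self.indices_at(wavelength_nm)
        keep = np.ones(radii.size, dtype=bool)
        for j in range(1, radii.size):
            if radii[j] == radii[j - 1]:
                keep[j - 1] = False  # inner of the equal pair vanishes
                warnings.warn(
                    f"zero-thickness layer {j - 1} (radius {radii[j]} nm) collapsed",
                    stacklevel=3,
                )
        return radii[keep], idx[keep]


@dataclass(frozen=True)
class MieSeries:
    """Multipole scattering coefficients a_n, b_n (n = 1..N)."""

    a_n: np.ndarray
    b_n: np.ndarray
    size_parameter: float
    truncation: int

    def __post_init__(self) -> None:
        x = self.size_parameter
        n_min = math.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0)
        if self.truncation < n_min:
            raise ValueError(
                f"truncation {self.truncation} below Wiscombe criterion {n_min}"
            )
        if not (np.all(np.isfinite(self.a_n)) and np.all(np.isfinite(self.b_n))):
            raise ValueError("non-finite Mie coefficients")


@dataclass(frozen=True)
class CrossSections:
    """Cross-sections (nm^2) and efficiencies of one particle at one wavelength."""

    sigma_ext: float
    sigma_sca: float
    sigma_abs: float
    q_ext: float
    q_sca: float
    q_abs: float
    wavelength: float

    def __post_init__(self) -> None:
        # efficiencies are O(1); roundoff-negative beyond 1e-12 means a bug
        for name in ("q_ext", "q_sca", "q_abs"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} negative beyond tolerance")

    @property
    def sigma_abs_m2(self) -> float:
        """Absorption cross-section in m^2 (1 nm^2 = 1e-18 m^2)."""
        return self.sigma_abs * 1e-18


def wiscombe_terms(x: float) -> int:
    """Series truncation N >= x + 4 x^(1/3) + 2 (Wiscombe criterion)."""
    return max(3, math.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))


def _log_derivative_down(z: complex, n_max: int, n_extra: int = 15) -> np.ndarray:
    """D1_n(z) = psi_n'(z)/psi_n(z) for n = 0..n_max by downward recurrence."""
    n_start = n_max + n_extra
    d = 0.0 + 0.0j
    out = np.empty(n_max + 1, dtype=complex)
    for n in range(n_start, 0, -1):
        d = n / z - 1.0 / (d + n / z)
        if n - 1 <= n_max:
            out[n - 1] = d
    return out


def _log_derivative_up(z: complex, n_max: int) -> np.ndarray:
    """D3_n(z) = xi_n'(z)/xi_n(z) for n = 0..n_max (stable upward recurrence).

    Uses D3_n = D1_n + i/(psi_n xi_n) with the product propagated upward,
    which stays bounded for Im(z) >= 0.
    """
    d1 = _log_derivative_down(z, n_max)
    d3 = np.empty(n_max + 1, dtype=complex)
    d3[0] = 1j
    psixi = 0.5 * (1.0 - np.exp(2j * z))
    for n in range(1, n_max + 1):
        psixi = psixi * (n / z - d1[n - 1]) * (n / z - d3[n - 1])
        d3[n] = d1[n] + 1j / psixi
    return d3


def _q_ratio(z1: complex, z2: complex, n_max: int) -> np.ndarray:
    """Q_n = [psi_n(z1)/xi_n(z1)] / [psi_n(z2)/xi_n(z2)] for n = 1..n_max.

    Built iteratively from order 0 so only bounded ratios are ever formed.
    """
    d1_1 = _log_derivative_down(z1, n_max)
    d3_1 = _log_derivative_up(z1, n_max)
    d1_2 = _log_derivative_down(z2, n_max)
    d3_2 = _log_derivative_up(z2, n_max)
    r1 = 0.5 * (1.0 - np.exp(-2j * z1))  # psi_0/xi_0 at z1
    r2 = 0.5 * (1.0 - np.exp(-2j * z2))
    q = np.empty(n_max + 1, dtype=complex)
    q[0] = r1 / r2
    for n in range(1, n_max + 1):
        q[n] = (
            q[n - 1]
            * ((n / z1 - d1_1[n - 1]) * (n / z2 - d3_2[n - 1]))
            / ((n / z2 - d1_2[n - 1]) * (n / z1 - d3_1[n - 1]))
        )
    return q


def _riccati_psi_xi(x: float, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """psi_n(x), xi_n(x) for real x, n = 0..n_max, by upward recurrence."""
    psi = np.empty(n_max + 1)
    chi = np.empty(n_max + 1)
    psi[0] = math.sin(x)
    chi[0] = math.cos(x)
    psi_m1 = math.cos(x)  # psi_{-1}
    chi_m1 = -math.sin(x)  # chi_{-1}
    for n in range(1, n_max + 1):
        psi[n] = (2 * n - 1) / x * psi[n - 1] - (psi[n - 2] if n >= 2 else psi_m1)
        chi[n] = (2 * n - 1) / x * chi[n - 1] - (chi[n - 2] if n >= 2 else chi_m1)
    xi = psi - 1j * chi
    return psi, xi


def compute_mie_series(
    particle: LayeredParticleOptics, wavelength: float, n_terms: int | None = None
) -> MieSeries:
    """Multipole coefficients of a stratified sphere at one wavelength (nm).

    Layers with identical index to their neighbour are handled naturally by
    the recursion; zero-thickness layers are collapsed with a warning.
    ``n_terms`` overrides the Wiscombe truncation (must not be below it).
    """
    radii, indices = particle.collapsed(wavelength)
    n_med = particle.medium_index
    # size parameter of each layer boundary, relative indices
    x = 2.0 * math.pi * radii * n_med / wavelength
    m = indices / n_med
    n_max = wiscombe_terms(float(x[-1])) if n_terms is None else int(n_terms)
    order = np.arange(1, n_max + 1)

    # innermost layer: regular solution only
    z = m[0] * x[0]
    ha = _log_derivative_down(z, n_max)[1:]
    hb = ha.copy()

    for l in range(1, len(radii)):
        z1 = m[l] * x[l - 1]
        z2 = m[l] * x[l]
        d1_z1 = _log_derivative_down(z1, n_max)[1:]
        d3_z1 = _log_derivative_up(z1, n_max)[1:]
        d1_z2 = _log_derivative_down(z2, n_max)[1:]
        d3_z2 = _log_derivative_up(z2, n_max)[1:]
        q = _q_ratio(z1, z2, n_max)[1:]
        # TM (a-type)
        g1 = m[l] * ha - m[l - 1] * d1_z1
        g2 = m[l] * ha - m[l - 1] * d3_z1
        ha = (g2 * d1_z2 - q * g1 * d3_z2) / (g2 - q * g1)
        # TE (b-type)
        g1 = m[l - 1] * hb - m[l] * d1_z1
        g2 = m[l - 1] * hb - m[l] * d3_z1
        hb = (g2 * d1_z2 - q * g1 * d3_z2) / (g2 - q * g1)

    xL = float(x[-1])
    mL = m[-1]
    psi, xi = _riccati_psi_xi(xL, n_max)
    fa = ha / mL + order / xL
    fb = hb * mL + order / xL
    a_n = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b_n = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])
    return MieSeries(a_n=a_n, b_n=b_n, size_parameter=xL, truncation=n_max)


def cross_sections(
    particle: LayeredParticleOptics, wavelength: float, n_terms: int | None = None
) -> CrossSections:
    """Extinction/scattering/absorption cross-sections (nm^2) and efficiencies."""
    series = compute_mie_series(particle, wavelength, n_terms=n_terms)
    x = series.size_parameter
    n = np.arange(1, series.truncation + 1)
    w = 2.0 * n + 1.0
    q_ext = 2.0 / x**2 * float(np.sum(w * (series.a_n + series.b_n).real))
    q_sca = 2.0 / x**2 * float(
        np.sum(w * (np.abs(series.a_n) ** 2 + np.abs(series.b_n) ** 2))
    )
    q_abs = q_ext - q_sca
    r_outer = float(np.max(particle.layer_outer_radii))
    geom = math.pi * r_outer**2
    return CrossSections(
        sigma_ext=q_ext * geom,
        sigma_sca=q_sca * geom,
        sigma_abs=q_abs * geom,
        q_ext=q_ext,
        q_sca=q_sca,
        q_abs=q_abs,
        wavelength=wavelength,
    )


def rayleigh_q_abs(m: complex, x: float) -> float:
    """Small-particle closed form q_abs = 4 x Im[(m^2-1)/(m^2+2)]."""
    return 4.0 * x * ((m**2 - 1.0) / (m**2 + 2.0)).imag
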