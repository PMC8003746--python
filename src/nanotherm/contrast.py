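"""Dual-modal contrast-agent calibration and particle-size statistics.

Transverse relaxivity r2 (slope of 1/T2 in s^-1 against Fe concentration
in mM) from CPMG echo decays, the CT attenuation slope in HU per mM of
gold (with the ratio to a clinical reference agent, iohexol by default),
and TEM/DLS size summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "DecayCurve",
    "RelaxationSeries",
    "RelaxivityFit",
    "CTSeries",
    "CTFit",
    "SizeSummary",
    "T2FitError",
    "fit_t2",
    "relaxivity",
    "ct_calibration",
    "size_summary",
    "IOHEXOL_SLOPE_HU_PER_MM",
]

#: Clinical reference CT contrast slope (iohexol), HU per mM.
IOHEXOL_SLOPE_HU_PER_MM = 2.7


class T2FitError(RuntimeError):
    """The mono-exponential T2 fit failed or gave a non-physical result."""


@dataclass
class DecayCurve:
    """One CPMG echo-amplitude decay at a single Fe concentration."""

    te: np.ndarray  # echo times, ms
    signal: np.ndarray  # a.u.
    concentration: float = float("nan")  # mM Fe
    field: float = float("nan")  # tesla

    def __post_init__(self) -> None:
        te = np.asarray(self.te, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if te.size < 4:
            raise ValueError("need >= 4 echoes")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if te.size != s.size:
            raise ValueError("te and signal must align")
        if np.any(s <= 0):
            raise ValueError("signal must be > 0")
        self.te, self.signal = te, s

    @classmethod
    def from_csv(cls, path: Union[str, Path], **kwargs) -> "DecayCurve":
        df = pd.read_csv(path)
        return cls(te=df["te_ms"].to_numpy(), signal=df["signal"].to_numpy(), **kwargs)


@dataclass
class RelaxationSeries:
    """T2 per Fe concentration at one field strength."""

    concentration: np.ndarray  # mM
    t2: np.ndarray  # ms
    field: float = float("nan")  # tesla

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        t2 = np.asarray(self.t2, dtype=float)
        if c.size < 3:
            raise ValueError("need >= 3 concentration levels")
        if np.unique(c).size != c.size:
            raise ValueError("concentration levels must be distinct")
        if np.any(t2 <= 0):
            raise ValueError("T2 must be > 0")
        self.concentration, self.t2 = c, t2

    @classmethod
    def from_csv(cls, path: Union[str, Path], **kwargs) -> "RelaxationSeries":
        df = pd.read_csv(path)
        return cls(
            concentration=df["concentration_mM"].to_numpy(),
            t2=df["t2_ms"].to_numpy(),
            **kwargs,
        )


@dataclass(frozen=True)
class RelaxivityFit:
    """r2 (mM^-1 s^-1) with matrix relaxation-rate intercept (s^-1)."""

    r2: float
    intercept: float
    r_squared: float


@dataclass
class CTSeries:
    """X-ray attenuation (HU) per gold concentration (mM)."""

    concentration: np.ndarray  # mM Au
    hu: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration, dtype=float)
        hu = np.asarray(self.hu, dtype=float)
        if c.size < 3:
            raise ValueError("need >= 3 concentration levels")
        if c.size != hu.size:
            raise ValueError("concentration and hu must align")
        self.concentration, self.hu = c, hu

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CTSeries":
        df = pd.read_csv(path)
        return cls(
            concentration=df["concentration_mM"].to_numpy(), hu=df["hu"].to_numpy()
        )


@dataclass(frozen=True)
class CTFit:
    """CT calibration slope, intercept, and ratio to the reference agent."""

    slope: float  # HU/mM
    intercept: float  # HU
    reference_ratio: float
    r_squared: float


@dataclass(frozen=True)
class SizeSummary:
    """Mean +/- sd (n-1 denominator) of a measured diameter sample."""

    mean: float  # nm
    sd: float  # nm
    n: int
    method: str  # "TEM" or "DLS"


def fit_t2(decay: DecayCurve, with_offset: bool = False) -> float:
    """T2 (ms) from a mono-exponential fit S(TE) = S0 exp(-TE/T2).

    ``with_offset`` adds a constant noise-floor term S0 exp(-TE/T2) + c.
    Raises :class:`T2FitError` for non-decaying or divergent fits.
    """
    te, s = decay.te, decay.signal
    s0_guess = float(s[0])
    # log-linear slope: starting value and non-decay guard
    slope = np.polyfit(te, np.log(s), 1)[0]
    if slope >= 0:
        raise T2FitError("signal does not decay with echo time")
    t2_guess = -1.0 / slope

    try:
        if with_offset:
            popt, _ = curve_fit(
                lambda x, s0, t2, c: s0 * np.exp(-x / t2) + c,
                te, s, p0=(s0_guess, t2_guess, 0.0), maxfev=20000,
            )
        else:
            popt, _ = curve_fit(
                lambda x, s0, t2: s0 * np.exp(-x / t2),
                te, s, p0=(s0_guess, t2_guess), maxfev=20000,
            )
    except (RuntimeError, ValueError) as exc:
        raise T2FitError(f"T2 fit did not converge: {exc}") from exc
    t2 = float(popt[1])
    if not np.isfinite(t2) or t2 <= 0:
        raise T2FitError(f"non-physical fitted T2 = {t2}")
    return t2


def relaxivity(series: RelaxationSeries) -> RelaxivityFit:
    """r2 as the OLS slope of 1/T2 (s^-1) against concentration (mM)."""
    rate = 1000.0 / series.t2  # ms -> s
    res = linregress(series.concentration, rate)
    return RelaxivityFit(
        r2=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def ct_calibration(
    series: CTSeries, reference_slope: float = IOHEXOL_SLOPE_HU_PER_MM
) -> CTFit:
    """CT slope/intercept by OLS; reference_ratio = slope / reference_slope."""
    res = linregress(series.concentration, series.hu)
    return CTFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        reference_ratio=float(res.slope) / reference_slope,
        r_squared=float(res.rvalue**2),
    )


def size_summary(diameters: Sequence[float], method: str = "TEM") -> SizeSummary:
    """Arithmetic mean and sample sd (n-1) of measured particle diameters."""
    d = np.asarray(diameters, dtype=float)
    if d.size < 2:
        raise ValueError("need >= 2 diameters")
    return SizeSummary(
        mean=float(np.mean(d)),
        sd=float(np.std(d, ddof=1)),
        n=int(d.size),
        method=method,
    )
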