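"""Ensemble photothermal analysis of laser heating/cooling traces.

Implements the lumped energy-balance (Roper) analysis of a stirred
nanoparticle suspension irradiated in a cuvette:

* ``fit_cooling_hs`` — the container heat-loss coefficient ``hS`` from the
  log-linear cooling fit of theta = (T - T0)/(Tmax - T0),
* ``efficiency_eta`` — the light-to-heat conversion efficiency

      eta = (hS * dT_max - Q_s) / (I * (1 - 10**(-A1064))),

  with ``Q_s`` (the solvent's own NIR absorption heat) taken from a
  water-only control,
* ``osar`` — the optical specific absorption rate C V/m_NP * dT/dt,
* initial heating rate, five-minute heating efficiency, on/off cycle
  stability, the continuous-point-source curve fit, and water-control
  subtraction.

Temperatures are ingested in deg C; every derived quantity is a
temperature difference and therefore in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import erfc
from scipy.stats import linregress

from .heat import PointSourceFit

__all__ = [
    "PhotothermalTrace",
    "SampleThermalSpec",
    "CoolingFit",
    "EnergyBalanceResult",
    "SARResult",
    "CycleReport",
    "FitError",
    "fit_cooling_hs",
    "efficiency_eta",
    "osar",
    "heating_rate",
    "heating_efficiency_5min",
    "fit_point_source",
    "cycle_stability",
    "subtract_control",
]


class FitError(RuntimeError):
    """A curve fit could not be performed on the given trace."""


@dataclass
class PhotothermalTrace:
    """Timestamped suspension temperature with the laser on/off schedule."""

    time: np.ndarray  # s, strictly increasing
    temperature: np.ndarray  # deg C
    laser_on: np.ndarray  # bool per sample
    laser_power: float = 1.22  # W
    wavelength: float = 1064.0  # nm
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        temp = np.asarray(self.temperature, dtype=float)
        on = np.asarray(self.laser_on, dtype=bool)
        if t.size < 10:
            raise ValueError("trace needs >= 10 samples")
        if not (t.size == temp.size == on.size):
            raise ValueError("time, temperature, laser_on must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(temp)):
            raise ValueError("temperature must be finite")
        self.time, self.temperature, self.laser_on = t, temp, on

    # -- schedule helpers ------------------------------------------------
    def on_blocks(self) -> list[Tuple[int, int]]:
        """Contiguous laser-on runs as [start, stop) index pairs."""
        on = self.laser_on.astype(int)
        edges = np.flatnonzero(np.diff(on))
        starts = list(edges[on[edges + 1] == 1] + 1)
        stops = list(edges[on[edges] == 1] + 1)
        if on[0]:
            starts.insert(0, 0)
        if on[-1]:
            stops.append(on.size)
        return list(zip(starts, stops))

    def transition_times(self) -> np.ndarray:
        """Times of every on/off switch (used to match control schedules)."""
        out = []
        for i0, i1 in self.on_blocks():
            out.append(self.time[i0])
            if i1 < self.time.size:
                out.append(self.time[i1])
        return np.asarray(out)

    @property
    def t0(self) -> float:
        """Baseline temperature T0: the start of the first on-block."""
        blocks = self.on_blocks()
        if not blocks:
            return float(self.temperature[0])
        return float(self.temperature[blocks[0][0]])

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path: Union[str, Path], **kwargs) -> "PhotothermalTrace":
        """Read a ``time_s,temperature_C,laser_on`` CSV."""
        df = pd.read_csv(path)
        return cls(
            time=df["time_s"].to_numpy(),
            temperature=df["temperature_C"].to_numpy(),
            laser_on=df["laser_on"].to_numpy().astype(bool),
            **kwargs,
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame(
            {
                "time_s": self.time,
                "temperature_C": self.temperature,
                "laser_on": self.laser_on.astype(int),
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SampleThermalSpec:
    """Calorimetric description of the irradiated sample."""

    total_heat_capacity: float  # J/K, sum m_i C_i
    volume: float = 1.0  # mL
    np_mass: float = 1e-3  # g of nanoparticles in the cuvette
    absorbance_1064: float = 1.0  # dimensionless

    def __post_init__(self) -> None:
        for name in ("total_heat_capacity", "volume", "np_mass", "absorbance_1064"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class CoolingFit:
    """hS and time constant from the log-linear cooling fit."""

    hS: float  # W/K
    tau_s: float  # s
    fit_window: Tuple[float, float]
    r_squared: float

    def __post_init__(self) -> None:
        if self.hS <= 0 or self.tau_s <= 0:
            raise ValueError("hS and tau must be > 0")


@dataclass(frozen=True)
class EnergyBalanceResult:
    """Conversion efficiency and the quantities entering the balance."""

    eta: float
    delta_t_max: float  # K
    q_s: float  # W
    laser_power: float  # W
    absorbance_1064: float
    out_of_range: bool = False  # True if eta fell outside [0, 1] before clamping


@dataclass(frozen=True)
class SARResult:
    """Optical specific absorption rate at one evaluation time."""

    osar: float  # W/g
    slope: float  # K/s
    eval_time: float  # s


@dataclass(frozen=True)
class CycleReport:
    """Per-cycle maximum rise for repeated on/off irradiation."""

    per_cycle_delta_t_max: Tuple[float, ...]
    spread: float  # K, max - min
    n_cycles: int


def _cooling_segment(trace: PhotothermalTrace) -> Tuple[int, int]:
    """Indices [start, stop) of the cooling segment after the first on-block."""
    blocks = trace.on_blocks()
    if not blocks:
        raise FitError("trace has no laser-on block")
    _, stop = blocks[0]
    if stop >= trace.time.size:
        raise FitError("laser never switched off: no cooling segment")
    if len(blocks) > 1:
        next_start = blocks[1][0]
    else:
        next_start = trace.time.size
    return stop, next_start


def fit_cooling_hs(
    trace: PhotothermalTrace,
    spec: SampleThermalSpec,
    window: Optional[Tuple[float, float]] = None,
    settle_s: float = 5.0,
    theta_min: float = 0.05,
) -> CoolingFit:
    """hS from OLS of ln theta against t on the cooling segment.

    theta = (T - T0)/(Tmax - T0) with Tmax the maximum temperature reached
    before switch-off and T0 the baseline; slope = -1/tau, hS = C_tot/tau.
    The first ``settle_s`` seconds after switch-off are discarded (sensor
    lag) and the default window ends where theta first drops below
    ``theta_min`` (the log fit degenerates once the decay meets the noise
    floor); an explicit ``window`` (s, relative to switch-off) overrides
    both and is used as given.
    """
    i0, i1 = _cooling_segment(trace)
    t0 = trace.t0
    # the first off sample is the switch-off instant, i.e. the true peak
    t_max = float(np.max(trace.temperature[: i0 + 1]))
    if t_max <= t0:
        raise FitError("no heating before switch-off")
    t_off = trace.time[i0 - 1]
    t_rel = trace.time[i0:i1] - t_off
    temp = trace.temperature[i0:i1]
    if window is not None:
        lo, hi = window
        if lo > hi:
            raise ValueError("window must be (lo, hi) with lo <= hi")
        sel = (t_rel >= lo) & (t_rel <= hi)
    else:
        sel = t_rel >= settle_s
        theta_all = (temp - t0) / (t_max - t0)
        low = np.flatnonzero(sel & (theta_all <= theta_min))
        if low.size:
            sel &= np.arange(t_rel.size) < low[0]
    t_sel, temp_sel = t_rel[sel], temp[sel]
    if t_sel.size < 5:
        raise FitError(f"only {t_sel.size} usable cooling points (need >= 5)")
    theta = (temp_sel - t0) / (t_max - t0)
    if np.any(theta <= 0):
        raise FitError("theta <= 0 inside the cooling window; shrink the window")
    res = linregress(t_sel, np.log(theta))
    if res.slope >= 0:
        raise FitError("cooling fit produced a non-decaying slope")
    tau = -1.0 / res.slope
    return CoolingFit(
        hS=spec.total_heat_capacity / tau,
        tau_s=tau,
        fit_window=(float(t_sel[0]), float(t_sel[-1])),
        r_squared=float(res.rvalue**2),
    )


def estimate_qs(
    water_control: PhotothermalTrace, control_spec: SampleThermalSpec
) -> float:
    """Solvent heat Q_s = hS_control * dT_max,control from a water-only run."""
    fit = fit_cooling_hs(water_control, control_spec)
    i0, _ = _cooling_segment(water_control)
    dt_max = float(np.max(water_control.temperature[: i0 + 1])) - water_control.t0
    return fit.hS * dt_max


def efficiency_eta(
    trace: PhotothermalTrace,
    spec: SampleThermalSpec,
    cooling: CoolingFit,
    water_control: Optional[PhotothermalTrace] = None,
    control_spec: Optional[SampleThermalSpec] = None,
    q_s: Optional[float] = None,
) -> EnergyBalanceResult:
    """Photothermal conversion efficiency from the lumped energy balance.

    Q_s comes from ``q_s`` directly, else from the water control (using
    ``control_spec`` or, failing that, ``spec`` for its calorimetry), else 0.
    A result outside [0, 1] is clamped *visibly*: ``out_of_range`` is set.
    """
    if spec.absorbance_1064 <= 0:
        raise ValueError("absorbance_1064 must be > 0")
    blocks = trace.on_blocks()
    if not blocks:
        raise FitError("trace has no laser-on block")
    i0, i1 = blocks[0]
    stop = min(i1 + 1, trace.time.size)  # include the switch-off sample
    dt_max = float(np.max(trace.temperature[i0:stop])) - trace.t0
    if dt_max <= 0:
        raise FitError("delta_t_max <= 0")
    if q_s is None:
        if water_control is not None:
            q_s = estimate_qs(water_control, control_spec or spec)
        else:
            q_s = 0.0
    denom = trace.laser_power * (1.0 - 10.0 ** (-spec.absorbance_1064))
    eta = (cooling.hS * dt_max - q_s) / denom
    out = not (0.0 <= eta <= 1.0)
    return EnergyBalanceResult(
        eta=float(min(max(eta, 0.0), 1.0)),
        delta_t_max=dt_max,
        q_s=float(q_s),
        laser_power=trace.laser_power,
        absorbance_1064=spec.absorbance_1064,
        out_of_range=out,
    )


def osar(
    trace: PhotothermalTrace,
    spec: SampleThermalSpec,
    eval_time: float = 120.0,
    half_window: float = 30.0,
) -> SARResult:
    """Optical SAR (W/g): C_tot/m_NP times dT/dt at ``eval_time``.

    dT/dt is the slope of a local linear fit centred on ``eval_time``
    (seconds after laser-on), window +/- ``half_window`` s, clipped to the
    first on-block.
    """
    blocks = trace.on_blocks()
    if not blocks:
        raise FitError("trace has no laser-on block")
    i0, i1 = blocks[0]
    i1 = min(i1 + 1, trace.time.size)  # include the switch-off sample
    t_on = trace.time[i0]
    t_rel = trace.time[i0:i1] - t_on
    if not (t_rel[0] <= eval_time <= t_rel[-1]):
        raise ValueError(
            f"eval_time {eval_time} s outside the first on-block "
            f"[{t_rel[0]}, {t_rel[-1]}] s"
        )
    sel = (t_rel >= eval_time - half_window) & (t_rel <= eval_time + half_window)
    if sel.sum() < 3:
        raise FitError("fewer than 3 samples in the oSAR window")
    res = linregress(t_rel[sel], trace.temperature[i0:i1][sel])
    return SARResult(
        osar=spec.total_heat_capacity * res.slope / spec.np_mass,
        slope=float(res.slope),
        eval_time=eval_time,
    )


def heating_rate(
    trace: PhotothermalTrace, window: Tuple[float, float] = (0.0, 120.0)
) -> float:
    """Initial heating rate in K/min: OLS slope of T vs t over ``window``.

    The window is in seconds measured from laser-on and must lie inside the
    first on-block.
    """
    blocks = trace.on_blocks()
    if not blocks:
        raise FitError("trace has no laser-on block")
    i0, i1 = blocks[0]
    i1 = min(i1 + 1, trace.time.size)  # include the switch-off sample
    t_rel = trace.time[i0:i1] - trace.time[i0]
    lo, hi = window
    if hi > t_rel[-1] + 1e-9:
        raise ValueError("window extends beyond the first on-block")
    sel = (t_rel >= lo) & (t_rel <= hi)
    if sel.sum() < 5:
        raise FitError(f"only {int(sel.sum())} points in window (need >= 5)")
    res = linregress(t_rel[sel], trace.temperature[i0:i1][sel])
    return float(res.slope) * 60.0


def heating_efficiency_5min(
    trace: PhotothermalTrace, spec: SampleThermalSpec, duration: float = 300.0
) -> float:
    """Stored heat over delivered optical energy after ``duration`` seconds.

    C_tot * dT(duration) / (I * duration) — the fraction of the laser energy
    retained by the sample at the five-minute mark.
    """
    blocks = trace.on_blocks()
    if not blocks:
        raise FitError("trace has no laser-on block")
    i0, i1 = blocks[0]
    i1 = min(i1 + 1, trace.time.size)  # include the switch-off sample
    t_rel = trace.time[i0:i1] - trace.time[i0]
    if t_rel[-1] + 1e-9 < duration:
        raise ValueError(
            f"on-block ({t_rel[-1]:.1f} s) shorter than duration {duration} s"
        )
    dt = float(np.interp(duration, t_rel, trace.temperature[i0:i1])) - trace.t0
    return spec.total_heat_capacity * dt / (trace.laser_power * duration)


def fit_point_source(trace: PhotothermalTrace) -> PointSourceFit:
    """Fit dT(t) = dT_inf * erfc(beta / sqrt(t)) to the first on-segment.

    t is measured from laser-on; dT relative to the block's start
    temperature.  Nonlinear least squares from five deterministic starts;
    the best converged fit wins.
    """
    blocks = trace.on_blocks()
    if not blocks:
        raise FitError("trace has no laser-on block")
    i0, i1 = blocks[0]
    if i1 - i0 < 20:
        raise FitError("need >= 20 on-segment samples for the point-source fit")
    t = trace.time[i0:i1] - trace.time[i0]
    dt = trace.temperature[i0:i1] - trace.temperature[i0]
    pos = t > 0
    t, dt = t[pos], dt[pos]

    def model(tt, dt_inf, beta):
        return dt_inf * erfc(beta / np.sqrt(tt))

    dt_end = max(float(dt[-1]), 1e-6)
    t_mid = float(np.median(t))
    starts = [
        (dt_end, 0.5 * math.sqrt(t_mid)),
        (dt_end, 2.0 * math.sqrt(t_mid)),
        (2.0 * dt_end, math.sqrt(t_mid)),
        (1.2 * dt_end, 0.1 * math.sqrt(t_mid)),
        (5.0 * dt_end, 5.0 * math.sqrt(t_mid)),
    ]
    best = None
    diagnostics = []
    for p0 in starts:
        try:
            popt, _ = curve_fit(
                model, t, dt, p0=p0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            diagnostics.append(f"start {p0}: {exc}")
            continue
        rms = float(np.sqrt(np.mean((model(t, *popt) - dt) ** 2)))
        if best is None or rms < best[1]:
            best = (popt, rms)
    if best is None:
        raise FitError("point-source fit failed from all starts: " + "; ".join(diagnostics))
    (dt_inf, beta), rms = best
    return PointSourceFit(delta_t_inf=float(dt_inf), beta=float(beta), residual_rms=rms)


def cycle_stability(trace: PhotothermalTrace) -> CycleReport:
    """Per-on-block maximum rise (relative to each block's start) and spread."""
    blocks = trace.on_blocks()
    if len(blocks) < 2:
        raise ValueError(f"need >= 2 on-blocks, got {len(blocks)}")
    maxima = []
    for i0, i1 in blocks:
        seg = trace.temperature[i0:i1]
        maxima.append(float(np.max(seg) - seg[0]))
    return CycleReport(
        per_cycle_delta_t_max=tuple(maxima),
        spread=float(max(maxima) - min(maxima)),
        n_cycles=len(blocks),
    )


def subtract_control(
    trace: PhotothermalTrace,
    water_control: PhotothermalTrace,
    schedule_tol: float = 1.0,
) -> PhotothermalTrace:
    """Temperature-difference trace: sample minus (interpolated) control.

    Requires matching laser schedules (every on/off transition within
    ``schedule_tol`` seconds); the control is resampled to the sample's
    timestamps by linear interpolation.
    """
    tt = trace.transition_times()
    tc = water_control.transition_times()
    if tt.size != tc.size or np.any(np.abs(tt - tc) > schedule_tol):
        raise ValueError("laser schedules of trace and control do not match")
    ctrl = np.interp(trace.time, water_control.time, water_control.temperature)
    return replace(
        trace,
        temperature=trace.temperature - ctrl,
        label=(trace.label + " - control").strip(),
    )
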