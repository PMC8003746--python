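"""TOML run configuration and the simulate -> fit -> report orchestrator.

A run config describes a characterization scenario end to end: particle
geometry and materials, thermal constants, the calorimetric sample spec,
the lumped-model operating point (for simulated traces) or paths to
measured trace CSVs, MRI/CT calibration designs, and the treatment grid.
``run_characterization`` executes the requested stages and writes one CSV
per stage plus a flat ``summary.csv``.
"""

from __future__ import annotations

import hashlib
import logging
import sys
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from . import contrast, heat, mie, photothermal, planner, synthetic

logger = logging.getLogger("nanotherm")

ALL_STAGES = ("mie", "heat", "photothermal", "mri", "ct", "size", "plan")

_MATERIALS = {
    "gold": mie.gold_dispersion,
    "magnetite": mie.magnetite_dispersion,
    "polymer": lambda: mie.POLYMER_INDEX,
}


@dataclass
class RunConfig:
    """Validated in-memory form of a scenario TOML file."""

    name: str = "scenario"
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    raw: dict = field(default_factory=dict)
    base_dir: Path = Path(".")

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for key in ("trace_csv", "control_csv"):
            rel = self.raw.get("photothermal", {}).get(key)
            if rel is not None and not (self.base_dir / rel).exists():
                raise FileNotFoundError(f"{key} points to missing file: {rel}")

    # -- section builders ------------------------------------------------
    def particle_optics(self) -> mie.LayeredParticleOptics:
        sec = self.raw.get("particle", {})
        radii = sec.get("layer_radii_nm", [55.0, 65.0, 71.0])
        mats = sec.get("materials", ["magnetite", "gold", "polymer"])
        indices: list[Any] = []
        for m in mats:
            if isinstance(m, str):
                if m not in _MATERIALS:
                    raise ValueError(f"unknown material {m!r}")
                indices.append(_MATERIALS[m]())
            else:  # [n, k] pair
                indices.append(complex(m[0], m[1]))
        return mie.LayeredParticleOptics(
            layer_outer_radii=radii,
            layer_index=indices,
            medium_index=sec.get("medium_index", 1.33),
        )

    def particle_thermal(self) -> heat.LayeredParticleThermal:
        psec = self.raw.get("particle", {})
        tsec = self.raw.get("thermal", {})
        return heat.LayeredParticleThermal(
            layer_outer_radii=psec.get("layer_radii_nm", [55.0, 65.0, 71.0]),
            layer_conductivity=tsec.get("layer_conductivity", [7.0, 317.0, 0.2]),
            medium_conductivity=tsec.get("medium_conductivity", heat.WATER_CONDUCTIVITY),
            medium_diffusivity=tsec.get("medium_diffusivity", heat.WATER_DIFFUSIVITY),
            source_layer=tsec.get("source_layer", 1),
        )

    def lumped_params(self) -> synthetic.LumpedModelParams:
        sec = self.raw.get("lumped", {})
        base = synthetic.paper_operating_point()
        fields = {
            k: sec[k]
            for k in (
                "eta", "laser_power", "absorbance_1064", "hS",
                "total_heat_capacity", "q_s", "ambient", "degradation_per_cycle",
            )
            if k in sec
        }
        return replace(base, **fields)

    def sample_spec(self) -> photothermal.SampleThermalSpec:
        sec = self.raw.get("sample", {})
        params = self.lumped_params()
        return photothermal.SampleThermalSpec(
            total_heat_capacity=sec.get(
                "total_heat_capacity", params.total_heat_capacity
            ),
            volume=sec.get("volume_mL", 1.0),
            np_mass=sec.get("np_mass_g", 1e-3),
            absorbance_1064=sec.get("absorbance_1064", params.absorbance_1064),
        )

    def treatment_grid(self) -> planner.TreatmentGrid:
        sec = self.raw.get("grid", {})
        defaults = planner.TreatmentGrid()
        kwargs = {
            k: sec[k]
            for k in (
                "nx", "ny", "field_size_x", "field_size_y", "n_planes",
                "plane_interval", "time_per_field", "wavelength", "power",
            )
            if k in sec
        }
        return replace(defaults, **kwargs)

    def config_hash(self) -> str:
        return hashlib.sha256(repr(sorted(self.raw.items())).encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a scenario TOML file."""
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sec = raw.get("scenario", {})
    return RunConfig(
        name=sec.get("name", path.stem),
        seed=sec.get("seed", 0),
        stages=sec.get("stages", list(ALL_STAGES)),
        raw=raw,
        base_dir=path.parent,
    )


def packaged_scenario() -> RunConfig:
    """The shipped end-to-end example scenario ('paper-defaults')."""
    return load_config(Path(__file__).parent / "data" / "paper_defaults.toml")


def _stage_photothermal(cfg: RunConfig, out_dir: Path, summary: dict) -> None:
    sec = cfg.raw.get("photothermal", {})
    spec = cfg.sample_spec()
    params = cfg.lumped_params()
    if sec.get("trace_csv"):
        trace = photothermal.PhotothermalTrace.from_csv(
            cfg.base_dir / sec["trace_csv"], laser_power=params.laser_power
        )
        control = (
            photothermal.PhotothermalTrace.from_csv(
                cfg.base_dir / sec["control_csv"], laser_power=params.laser_power
            )
            if sec.get("control_csv")
            else None
        )
    else:
        on_s = sec.get("on_s", 1800.0)
        off_s = sec.get("off_s", 2400.0)
        dt = sec.get("dt_s", 1.0)
        noise_sd = sec.get("noise_sd_K", 0.0)
        schedule = ((on_s, True), (off_s, False))
        trace = synthetic.generate_photothermal_trace(
            params, schedule, dt=dt,
            noise=synthetic.NoiseSpec(noise_sd, cfg.seed), label=cfg.name,
        )
        control = synthetic.generate_photothermal_trace(
            synthetic.water_control_params(params), schedule, dt=dt,
            noise=synthetic.NoiseSpec(noise_sd, cfg.seed + 1), label="water",
        )
    cooling = photothermal.fit_cooling_hs(trace, spec)
    balance = photothermal.efficiency_eta(trace, spec, cooling, water_control=control)
    sar = photothermal.osar(trace, spec)
    rate = photothermal.heating_rate(trace)
    ps = photothermal.fit_point_source(trace)
    rows = {
        "eta": balance.eta,
        "eta_percent": 100.0 * balance.eta,
        "hS_W_per_K": cooling.hS,
        "tau_s": cooling.tau_s,
        "delta_t_max_K": balance.delta_t_max,
        "q_s_W": balance.q_s,
        "osar_W_per_g": sar.osar,
        "heating_rate_K_per_min": rate,
        "point_source_delta_t_inf_K": ps.delta_t_inf,
        "point_source_beta_sqrt_s": ps.beta,
    }
    pd.DataFrame([rows]).to_csv(out_dir / "photothermal.csv", index=False)
    summary.update(rows)


def _stage_mie(cfg: RunConfig, out_dir: Path, summary: dict) -> None:
    wl = cfg.raw.get("particle", {}).get("wavelength_nm", 1064.0)
    cs = mie.cross_sections(cfg.particle_optics(), wl)
    rows = {
        "wavelength_nm": wl,
        "sigma_abs_nm2": cs.sigma_abs,
        "sigma_sca_nm2": cs.sigma_sca,
        "sigma_ext_nm2": cs.sigma_ext,
        "q_abs": cs.q_abs,
        "q_sca": cs.q_sca,
        "q_ext": cs.q_ext,
    }
    pd.DataFrame([rows]).to_csv(out_dir / "mie.csv", index=False)
    summary["sigma_abs_nm2"] = cs.sigma_abs


def _stage_heat(cfg: RunConfig, out_dir: Path, summary: dict) -> None:
    wl = cfg.raw.get("particle", {}).get("wavelength_nm", 1064.0)
    cs = mie.cross_sections(cfg.particle_optics(), wl)
    irr = cfg.raw.get("thermal", {}).get("irradiance_W_per_cm2", 1.22) * 1e4
    power = heat.absorbed_power_from_irradiance(cs, irr)
    profile = heat.steady_profile(cfg.particle_thermal(), power)
    pd.DataFrame(
        {"radius_nm": profile.radius_grid, "delta_t_K": profile.delta_t}
    ).to_csv(out_dir / "heat_profile.csv", index=False)
    summary["absorbed_power_W"] = power
    summary["surface_delta_t_K"] = profile.surface_delta_t


def _stage_mri(cfg: RunConfig, out_dir: Path, summary: dict) -> None:
    sec = cfg.raw.get("mri", {})
    intercept = sec.get("intercept_s", 2.0)
    noise_sd = sec.get("noise_sd", 0.0)
    rows = []
    for name, r2_true in (("high", sec.get("r2_high", 61.5)),
                          ("low", sec.get("r2_low", 14.0))):
        curves = synthetic.generate_cpmg_series(
            r2_true, intercept, noise=synthetic.NoiseSpec(noise_sd, cfg.seed + 10)
        )
        series = contrast.RelaxationSeries(
            concentration=np.array([c.concentration for c in curves]),
            t2=np.array([contrast.fit_t2(c) for c in curves]),
            field=9.4 if name == "high" else 1.44,
        )
        fit = contrast.relaxivity(series)
        rows.append({"field": name, "r2_mM_s": fit.r2, "intercept_s": fit.intercept,
                     "r_squared": fit.r_squared})
        summary[f"r2_{name}_mM_s"] = fit.r2
    pd.DataFrame(rows).to_csv(out_dir / "relaxivity.csv", index=False)


def _stage_ct(cfg: RunConfig, out_dir: Path, summary: dict) -> None:
    sec = cfg.raw.get("ct", {})
    series = synthetic.generate_ct_series(
        sec.get("slope", 30.0), sec.get("intercept", 0.0),
        noise=synthetic.NoiseSpec(sec.get("noise_sd", 0.0), cfg.seed + 20),
    )
    fit = contrast.ct_calibration(series)
    pd.DataFrame(
        [{"slope_HU_mM": fit.slope, "intercept_HU": fit.intercept,
          "iohexol_ratio": fit.reference_ratio}]
    ).to_csv(out_dir / "ct.csv", index=False)
    summary["ct_slope_HU_mM"] = fit.slope
    summary["ct_iohexol_ratio"] = fit.reference_ratio


def _stage_size(cfg: RunConfig, out_dir: Path, summary: dict) -> None:
    sec = cfg.raw.get("size", {})
    sample = synthetic.generate_size_sample(
        sec.get("mean_nm", 142.0), sec.get("sd_nm", 26.0),
        sec.get("n", 100), seed=cfg.seed + 30,
    )
    s = contrast.size_summary(sample, method="TEM")
    pd.DataFrame([{"mean_nm": s.mean, "sd_nm": s.sd, "n": s.n}]).to_csv(
        out_dir / "size.csv", index=False
    )
    summary["tem_mean_nm"] = s.mean
    summary["tem_sd_nm"] = s.sd


def _stage_plan(cfg: RunConfig, out_dir: Path, summary: dict) -> None:
    p = planner.plan(cfg.treatment_grid())
    pd.DataFrame(
        [
            {
                "field": s.index, "ix": s.ix, "iy": s.iy,
                "x0_um": s.x0_um, "y0_um": s.y0_um,
                "start_min": s.start_min, "stop_min": s.stop_min,
                "z0_um": s.z_range_um[0], "z1_um": s.z_range_um[1],
            }
            for s in p.per_field_schedule
        ]
    ).to_csv(out_dir / "plan_schedule.csv", index=False)
    summary["plan_volume_mm3"] = p.volume_mm3
    summary["plan_depth_mm"] = p.volume_dims[2]
    summary["plan_total_time_min"] = p.total_time


_STAGE_FNS = {
    "mie": _stage_mie,
    "heat": _stage_heat,
    "photothermal": _stage_photothermal,
    "mri": _stage_mri,
    "ct": _stage_ct,
    "size": _stage_size,
    "plan": _stage_plan,
}


def run_characterization(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages; write per-stage CSVs and summary.csv.

    Returns the summary dict.  Any stage failure raises after logging the
    stage name; results of completed stages remain on disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "scenario %s | seed %d | config %s | numpy %s | python %s",
        cfg.name, cfg.seed, cfg.config_hash(),
        np.__version__, sys.version.split()[0],
    )
    if not cfg.stages:
        logger.warning("empty stage list: nothing to do")
        return {}
    summary: dict = {"scenario": cfg.name, "seed": cfg.seed}
    for stage in cfg.stages:
        logger.info("stage %s", stage)
        try:
            _STAGE_FNS[stage](cfg, out_dir, summary)
        except Exception:
            logger.error("stage %s failed", stage)
            raise
    pd.DataFrame([summary]).to_csv(out_dir / "summary.csv", index=False)
    return summary
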