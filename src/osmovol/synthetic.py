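"""Synthetic single-cell volumetry studies.

Generates per-cell diameter time series with the statistical structure the
analysis pipeline assumes, so every downstream stage can be tested without
any experimental data:

* a population of spherical cells with truncated-normal isotonic diameters
  (default mean 18.5 µm, bounds 9–33 µm) and a fixed non-osmotic fraction;
* abrupt transfer into a hypo- or hypertonic medium at a set temperature,
  simulated per cell with the osmotic transport ODE and a direction-dependent
  true Lp following an Arrhenius law (rectification is generated by
  direction-dependent Lp; an osmolality-dependent alternative mode is
  provided because equilibrium data cannot distinguish the two hypotheses);
* the imaging protocol: a 25–40 s mixing dead time before the first frame,
  10-s sampling for 5 min, then 30-s sampling;
* Gaussian measurement noise on the DIAMETERS (what is actually measured),
  applied after the volume→diameter conversion;
* a small flagged dead-cell fraction (constant volume plus noise).

Ground-truth parameters live only in the bundle metadata, never in the data
tables, so blind parameter-recovery tests are honest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import geometry
from .bvh import BvhPoint
from .constants import ISOTONIC_OSMOLALITY, Condition, OsmoticCellParams
from .lp import CellSeries, write_cell_series_csv, read_cell_series_csv
from .simulator import SimulationParams, simulate
from .thermal import lp_at_temperature

__all__ = [
    "PopulationConfig",
    "TrueParams",
    "ProtocolConfig",
    "SyntheticStudyConfig",
    "CellState",
    "StudyBundle",
    "generate_cells",
    "generate_experiment",
    "generate_study",
    "DEFAULT_CONDITIONS",
]

#: The six-condition kinetic design: half- and double-isotonic media at three
#: temperatures.
DEFAULT_CONDITIONS = tuple(
    Condition(osmolality=m, temperature_c=t)
    for m in (0.157, 0.602)
    for t in (0.0, 10.0, 22.0)
)

#: Equilibrium (Boyle–van't Hoff) series osmolalities, Osm/kg.
DEFAULT_BVH_OSMOLALITIES = (0.157, 0.242, 0.308, 0.602, 0.986)


@dataclass(frozen=True)
class PopulationConfig:
    """Cell population statistics."""

    n_cells: int = 50
    diameter_mean: float = 18.5  # µm
    diameter_sd: float = 4.0  # µm
    diameter_bounds: tuple[float, float] = (9.0, 33.0)
    vb_fraction: float = 0.29
    dead_fraction: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.diameter_bounds
        if lo >= hi:
            raise ValueError("diameter_bounds must be an increasing pair")
        if (lo > self.diameter_mean + 6 * self.diameter_sd
                or hi < self.diameter_mean - 6 * self.diameter_sd):
            raise ValueError("diameter bounds exclude mean ± 6 sd; infeasible truncation")
        if not 0 <= self.dead_fraction < 1:
            raise ValueError("dead_fraction must be in [0, 1)")
        if not 0 <= self.vb_fraction < 1:
            raise ValueError("vb_fraction must be in [0, 1)")


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth membrane parameters of the simulated cells.

    Influx (hypotonic) and efflux (hypertonic) Lp at the reference
    temperature, each extrapolated to other temperatures along its own
    Arrhenius law with activation energy ea_in/ea_out (cal/mol).
    """

    lp_in_ref: float = 1.73  # µm/(min·atm) at reference_T
    lp_out_ref: float = 0.21
    ea_in: float = 12000.0  # cal/mol
    ea_out: float = 10700.0
    reference_T: float = 283.15  # K
    mode: str = "direction"  # or "osmolality"
    lp_by_osmolality: dict | None = None  # {Osm/kg: Lp at reference_T}
    rvd_rate: float = 0.0  # 1/min relaxation of swelling excess (22 °C artefact)
    equilibrium_offset_frac: float = 0.0  # fractional Ve mismatch vs BVH

    def lp_for(self, condition: Condition) -> float:
        """True Lp at this condition's temperature and direction."""
        T = condition.temperature_k
        if self.mode == "osmolality":
            if not self.lp_by_osmolality:
                raise ValueError("osmolality mode requires lp_by_osmolality")
            key = min(self.lp_by_osmolality, key=lambda m: abs(float(m) - condition.osmolality))
            return lp_at_temperature(self.lp_by_osmolality[key], self.reference_T, T, self.ea_in)
        if condition.direction == "hypertonic":
            return lp_at_temperature(self.lp_out_ref, self.reference_T, T, self.ea_out)
        return lp_at_temperature(self.lp_in_ref, self.reference_T, T, self.ea_in)


@dataclass(frozen=True)
class ProtocolConfig:
    """Imaging protocol: dead time, sampling cadence, noise."""

    dead_time_range: tuple[float, float] = (25.0, 40.0)  # s
    fast_interval: float = 10.0  # s
    fast_duration: float = 300.0  # s
    slow_interval: float = 30.0  # s
    total_duration: float = 1200.0  # s
    diameter_noise_sd: float = 0.3  # µm

    def __post_init__(self) -> None:
        if self.fast_interval <= 0 or self.slow_interval <= 0:
            raise ValueError("sampling intervals must be positive")
        if self.dead_time_range[0] > self.dead_time_range[1]:
            raise ValueError("dead_time_range must be ordered")
        if self.diameter_noise_sd < 0:
            raise ValueError("diameter_noise_sd must be non-negative")

    def sample_grid(self) -> np.ndarray:
        """Frame times (s) relative to the first image."""
        fast = np.arange(0.0, self.fast_duration + 1e-9, self.fast_interval)
        slow = np.arange(
            self.fast_duration + self.slow_interval,
            self.total_duration + 1e-9,
            self.slow_interval,
        )
        return np.concatenate([fast, slow])


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Full specification of a simulated study."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    true_params: TrueParams = field(default_factory=TrueParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    bvh_osmolalities: tuple[float, ...] = DEFAULT_BVH_OSMOLALITIES
    bvh_temperature_c: float = 22.0
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticStudyConfig":
        pop = PopulationConfig(**d.get("population", {}))
        tp_d = dict(d.get("true_params", {}))
        tp = TrueParams(**tp_d)
        proto_d = dict(d.get("protocol", {}))
        if "dead_time_range" in proto_d:
            proto_d["dead_time_range"] = tuple(proto_d["dead_time_range"])
        proto = ProtocolConfig(**proto_d)
        conds = tuple(
            Condition(osmolality=c["osmolality"], temperature_c=c["temperature_c"])
            for c in d["conditions"]
        ) if "conditions" in d else DEFAULT_CONDITIONS
        return cls(
            population=pop,
            true_params=tp,
            protocol=proto,
            conditions=conds,
            bvh_osmolalities=tuple(d.get("bvh_osmolalities", DEFAULT_BVH_OSMOLALITIES)),
            bvh_temperature_c=d.get("bvh_temperature_c", 22.0),
            seed=int(d.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [
            {"osmolality": c.osmolality, "temperature_c": c.temperature_c}
            for c in self.conditions
        ]
        return d


@dataclass(frozen=True)
class CellState:
    """One cell's isotonic geometry and viability."""

    cell_id: str
    diameter_iso: float  # µm
    alive: bool
    vb_fraction: float

    @property
    def V_c_iso(self) -> float:
        return geometry.sphere_volume(self.diameter_iso)

    @property
    def V_b(self) -> float:
        return self.vb_fraction * self.V_c_iso

    def osmotic_params(self, M_iso: float = ISOTONIC_OSMOLALITY) -> OsmoticCellParams:
        return OsmoticCellParams.from_isotonic(self.V_c_iso, self.V_b, M_iso)


def generate_cells(pop: PopulationConfig, seed_or_rng) -> list[CellState]:
    """Draw a reproducible cell population.

    Isotonic diameters are truncated-normal within ``diameter_bounds``;
    dead flags are independent Bernoulli(dead_fraction).
    """
    rng = np.random.default_rng(seed_or_rng)
    lo, hi = pop.diameter_bounds
    a = (lo - pop.diameter_mean) / pop.diameter_sd
    b = (hi - pop.diameter_mean) / pop.diameter_sd
    diam = sps.truncnorm.rvs(
        a, b, loc=pop.diameter_mean, scale=pop.diameter_sd,
        size=pop.n_cells, random_state=rng,
    )
    dead = rng.random(pop.n_cells) < pop.dead_fraction
    return [
        CellState(
            cell_id=f"cell{i:04d}",
            diameter_iso=float(d),
            alive=not bool(k),
            vb_fraction=pop.vb_fraction,
        )
        for i, (d, k) in enumerate(zip(diam, dead))
    ]


def generate_experiment(
    cells: Sequence[CellState],
    condition: Condition,
    true_params: TrueParams,
    protocol: ProtocolConfig,
    seed_or_rng,
) -> list[CellSeries]:
    """Simulate one imaging run: all cells under one osmotic step.

    A single dead time (uniform in ``dead_time_range``) offsets the whole
    run's frame times, as in a real mixing experiment.  Alive cells follow
    the transport ODE with the condition-appropriate true Lp; dead cells
    keep their isotonic volume.  Gaussian noise is added to the diameters.
    """
    rng = np.random.default_rng(seed_or_rng)
    lo, hi = protocol.dead_time_range
    dead_time = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    times_s = dead_time + protocol.sample_grid()
    times_min = times_s / 60.0

    lp_true = true_params.lp_for(condition)
    out: list[CellSeries] = []
    for cell in cells:
        if cell.alive and condition.direction != "isotonic":
            p = cell.osmotic_params()
            N_eff = p.N * (1.0 + true_params.equilibrium_offset_frac)
            sim = simulate(
                SimulationParams(
                    Lp=lp_true,
                    A=p.A,
                    N=N_eff,
                    T=condition.temperature_k,
                    M_ext=condition.osmolality,
                    V_b=p.V_b,
                    V0_water=p.V_iso,
                ),
                times_min,
            )
            water = sim.water_volumes
            if true_params.rvd_rate > 0 and condition.direction == "hypotonic":
                # regulatory volume decrease: the swelling excess relaxes back
                excess = water - p.V_iso
                water = p.V_iso + excess * np.exp(-true_params.rvd_rate * times_min)
            volumes = water + p.V_b
        else:
            volumes = np.full(len(times_s), cell.V_c_iso)
        diam = geometry.sphere_diameter(volumes)
        if protocol.diameter_noise_sd > 0:
            diam = diam + rng.normal(0.0, protocol.diameter_noise_sd, size=diam.shape)
            diam = np.maximum(diam, 0.5)  # physical floor, µm
        out.append(
            CellSeries(
                cell_id=cell.cell_id,
                condition=condition,
                times=times_s,
                diameters=diam,
                alive=cell.alive,
            )
        )
    return out


@dataclass
class StudyBundle:
    """A complete synthetic study: kinetics, equilibrium series, ground truth."""

    config: SyntheticStudyConfig
    experiments: dict[str, list[CellSeries]]  # condition label -> series
    bvh_points: list[BvhPoint]
    isotonic_volumes: dict[str, dict]  # temperature label -> {mean, se, n}
    truth: dict

    def condition_for(self, label: str) -> Condition:
        for cond in self.config.conditions:
            if cond.label() == label:
                return cond
        raise KeyError(label)

    def write(self, directory: str | Path) -> None:
        """Write per-condition CSVs, the equilibrium-series CSV and metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for label, cells in self.experiments.items():
            write_cell_series_csv(cells, directory / f"kinetics_{label}.csv", label)
        pd.DataFrame(
            {
                "osmolality_mosm": [p.osmolality * 1000 for p in self.bvh_points],
                "mean_volume_um3": [p.mean_volume for p in self.bvh_points],
                "n_cells": [p.n_cells for p in self.bvh_points],
                "se_um3": [p.se for p in self.bvh_points],
            }
        ).to_csv(directory / "bvh_series.csv", index=False)
        meta = {
            "config": self.config.to_dict(),
            "isotonic_volumes": self.isotonic_volumes,
            "ground_truth": self.truth,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "StudyBundle":
        from .bvh import read_bvh_csv

        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        config = SyntheticStudyConfig.from_dict(meta["config"])
        experiments = {}
        for cond in config.conditions:
            label = cond.label()
            path = directory / f"kinetics_{label}.csv"
            if path.exists():
                experiments[label] = read_cell_series_csv(path)
        return cls(
            config=config,
            experiments=experiments,
            bvh_points=read_bvh_csv(directory / "bvh_series.csv"),
            isotonic_volumes=meta["isotonic_volumes"],
            truth=meta["ground_truth"],
        )


def generate_study(config: SyntheticStudyConfig) -> StudyBundle:
    """Generate the full study: kinetic runs at every configured condition,
    an equilibrium (Boyle–van't Hoff) osmolality series, and per-temperature
    isotonic reference volumes.  Byte-identical for identical configs."""
    ss = np.random.SeedSequence(config.seed)
    keys = (
        [f"exp:{c.label()}" for c in config.conditions]
        + [f"bvh:{m}" for m in config.bvh_osmolalities]
        + ["population", "isotonic"]
    )
    children = {k: s for k, s in zip(keys, ss.spawn(len(keys)))}

    cells = generate_cells(config.population, children["population"])

    experiments = {}
    truth_lp = {}
    for cond in config.conditions:
        label = cond.label()
        experiments[label] = generate_experiment(
            cells, cond, config.true_params, config.protocol, children[f"exp:{label}"]
        )
        truth_lp[label] = config.true_params.lp_for(cond)

    # Equilibrium series: per osmolality, equilibrate each alive cell and
    # measure its diameter once, with noise; the point is the mean VOLUME.
    noise_sd = config.protocol.diameter_noise_sd
    bvh_points = []
    for m in config.bvh_osmolalities:
        rng = np.random.default_rng(children[f"bvh:{m}"])
        vols = []
        for cell in cells:
            if not cell.alive:
                continue
            p = cell.osmotic_params()
            w_eq = p.V_iso * p.M_iso / m
            d = geometry.sphere_diameter(w_eq + p.V_b)
            if noise_sd > 0:
                d += rng.normal(0.0, noise_sd)
            vols.append(geometry.sphere_volume(max(d, 0.5)))
        vols = np.asarray(vols)
        bvh_points.append(
            BvhPoint(
                osmolality=m,
                mean_volume=float(vols.mean()),
                n_cells=len(vols),
                se=float(vols.std(ddof=1) / np.sqrt(len(vols))),
            )
        )

    rng_iso = np.random.default_rng(children["isotonic"])
    isotonic = {}
    temps = sorted({c.temperature_c for c in config.conditions})
    for tc in temps:
        vols = []
        for cell in cells:
            if not cell.alive:
                continue
            d = cell.diameter_iso + (
                rng_iso.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            )
            vols.append(geometry.sphere_volume(max(d, 0.5)))
        vols = np.asarray(vols)
        diams = geometry.sphere_diameter(vols)
        # both averaging conventions: mean of volumes (equilibrium statics)
        # and volume of the mean diameter (the kinetics-curve convention)
        isotonic[f"{tc:g}"] = {
            "mean_volume_um3": float(vols.mean()),
            "mean_diameter_um": float(diams.mean()),
            "volume_of_mean_diameter_um3": float(geometry.sphere_volume(diams.mean())),
            "se_um3": float(vols.std(ddof=1) / np.sqrt(len(vols))),
            "n_cells": int(len(vols)),
        }

    truth = {
        "lp_by_condition": truth_lp,
        "lp_in_ref": config.true_params.lp_in_ref,
        "lp_out_ref": config.true_params.lp_out_ref,
        "ea_in_cal_per_mol": config.true_params.ea_in,
        "ea_out_cal_per_mol": config.true_params.ea_out,
        "reference_T_K": config.true_params.reference_T,
        "vb_fraction": config.population.vb_fraction,
        "seed": config.seed,
    }
    return StudyBundle(
        config=config,
        experiments=experiments,
        bvh_points=bvh_points,
        isotonic_volumes=isotonic,
        truth=truth,
    )
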