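"""End-to-end study analysis: data (synthetic or ingested) → report.

The report mirrors how an osmotic volumetry study is written up: a
Boyle–van't Hoff fit and non-osmotic fraction, per-condition Lp estimates
from the averaged shrink/swell curves, rectification ratios per temperature,
Arrhenius activation energies per flow direction (room-temperature points
excluded by default, explicitly logged), and the simulated-vs-observed
curve-shift validation.

Per-temperature physical parameters are assembled the conventional way: the
measured mean isotonic volume at each temperature, the non-osmotic fraction
from the (single) BVH fit applied to that volume, sphere surface area from
the isotonic volume, and osmoles from the isotonic water volume.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .alignment import ShiftFit, shift_fit
from .bvh import BvhFit, fit_bvh
from .constants import OsmoticCellParams
from .exceptions import InsufficientDataError, OsmovolError, SchemaError
from .lp import (
    CELL_CSV_COLUMNS,
    AveragedCurve,
    LpEstimate,
    average_lp,
    build_average_curve,
)
from .simulator import SimulationParams, simulate
from .synthetic import StudyBundle, SyntheticStudyConfig, generate_study
from .thermal import ArrheniusFit, RectificationResult, arrhenius_ea, rectification_ratio

logger = logging.getLogger("osmovol")

__all__ = ["StudyReport", "run_report", "validate_input"]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class StudyReport:
    """All results of one study analysis, with provenance."""

    bvh: BvhFit | None
    v_b_fraction: float | None
    lp_table: dict[str, LpEstimate]
    rectification: dict[str, RectificationResult]
    ea_in: ArrheniusFit | None
    ea_out: ArrheniusFit | None
    shifts: dict[str, ShiftFit]
    warnings: list[str]
    provenance: dict

    def to_dict(self) -> dict:
        return _jsonable(
            {
                "bvh": self.bvh,
                "v_b_fraction": self.v_b_fraction,
                "lp_table": self.lp_table,
                "rectification": self.rectification,
                "ea_in": self.ea_in,
                "ea_out": self.ea_out,
                "shifts": self.shifts,
                "warnings": self.warnings,
                "provenance": self.provenance,
            }
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _config_hash(config: dict) -> str:
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_report(
    config: dict,
    include_shift_fit: bool = True,
) -> StudyReport:
    """Execute the full pipeline and return a :class:`StudyReport`.

    ``config`` must contain either ``"synthetic"`` (a
    :class:`SyntheticStudyConfig` mapping) or ``"input_dir"`` (a study-bundle
    directory).  Analysis options:

    * ``ve_mode``: "measured" (default) or "bvh" equilibrium volume;
    * ``exclude_22c_from_ea``: drop 22 °C Lp from the Arrhenius fits
      (default True; the exclusion is logged and recorded on the fit);
    * ``plateau_window`` / ``plateau_rel_tol``: equilibrium detection.
    """
    if "synthetic" in config:
        syn = SyntheticStudyConfig.from_dict(config["synthetic"])
        if "seed" in config:
            syn = dataclasses.replace(syn, seed=int(config["seed"]))
        bundle = generate_study(syn)
        seed = syn.seed
    elif "input_dir" in config:
        bundle = StudyBundle.load(config["input_dir"])
        seed = bundle.config.seed
    else:
        raise ValueError("config needs either 'synthetic' or 'input_dir'")

    ve_mode = config.get("ve_mode", "measured")
    exclude_22c = bool(config.get("exclude_22c_from_ea", True))
    plateau_window = int(config.get("plateau_window", 4))
    plateau_rel_tol = float(config.get("plateau_rel_tol", 0.03))

    notes: list[str] = []

    # --- Boyle-van't Hoff stage -------------------------------------------
    bvh_fit = None
    v_b_fraction = None
    iso = bundle.isotonic_volumes
    bvh_temp_label = f"{bundle.config.bvh_temperature_c:g}"
    try:
        v_ref = iso.get(bvh_temp_label, {}).get("mean_volume_um3")
        bvh_fit = fit_bvh(bundle.bvh_points, V_ref=v_ref)
        v_b_fraction = bvh_fit.v_b
    except InsufficientDataError as exc:
        notes.append(f"BVH stage skipped: {exc}")
        logger.warning("BVH stage skipped: %s", exc)

    # --- per-condition Lp --------------------------------------------------
    lp_table: dict[str, LpEstimate] = {}
    curves: dict[str, AveragedCurve] = {}
    for label, cells in bundle.experiments.items():
        cond = cells[0].condition
        temp_label = f"{cond.temperature_c:g}"
        if temp_label not in iso:
            notes.append(f"{label}: no isotonic reference volume; condition skipped")
            continue
        # kinetics parameters live on the averaged-curve scale: the curve is
        # the volume of the MEAN diameter, so the pseudo-cell's isotonic
        # volume must follow the same convention (falls back to the mean of
        # volumes when only that is recorded)
        iso_t = iso[temp_label]
        V_c_iso = iso_t.get("volume_of_mean_diameter_um3", iso_t["mean_volume_um3"])
        vb_frac = v_b_fraction if v_b_fraction is not None else 0.29
        params = OsmoticCellParams.from_isotonic(V_c_iso, vb_frac * V_c_iso)
        try:
            curve = build_average_curve(cells)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                est = average_lp(
                    curve,
                    params,
                    cond.temperature_k,
                    Ve_mode=ve_mode,
                    plateau_window=plateau_window,
                    plateau_rel_tol=plateau_rel_tol,
                )
            for w in caught:
                notes.append(f"{label}: {w.message}")
            lp_table[label] = est
            curves[label] = curve
        except OsmovolError as exc:
            notes.append(f"{label}: Lp estimation failed: {exc}")
            logger.warning("%s: Lp estimation failed: %s", label, exc)

    # --- rectification & Arrhenius ----------------------------------------
    by_temp: dict[float, dict[str, LpEstimate]] = {}
    for est in lp_table.values():
        by_temp.setdefault(est.condition.temperature_c, {})[
            est.condition.direction
        ] = est

    rectification: dict[str, RectificationResult] = {}
    for tc, d in sorted(by_temp.items()):
        if "hypotonic" in d and "hypertonic" in d:
            lp_in, lp_out = d["hypotonic"].lp_mean, d["hypertonic"].lp_mean
            rectification[f"{tc:g}"] = RectificationResult(
                temperature_c=tc,
                lp_hypo=lp_in,
                lp_hyper=lp_out,
                ratio=rectification_ratio(lp_in, lp_out),
            )

    exclude = [22.0] if exclude_22c else []
    if exclude_22c:
        notes.append("Arrhenius fits exclude 22 °C Lp values (config default)")
        logger.info("Arrhenius fits exclude 22 °C Lp values")

    ea_fits: dict[str, ArrheniusFit | None] = {"hypotonic": None, "hypertonic": None}
    for direction in ea_fits:
        pts = [
            (tc + 273.15, d[direction].lp_mean)
            for tc, d in by_temp.items()
            if direction in d
        ]
        try:
            ea_fits[direction] = arrhenius_ea(pts, exclude_temps_c=exclude)
        except (InsufficientDataError, ValueError) as exc:
            notes.append(f"Ea ({direction}) not computed: {exc}")
            logger.warning("Ea (%s) not computed: %s", direction, exc)

    # --- shift-fit validation ----------------------------------------------
    shifts: dict[str, ShiftFit] = {}
    if include_shift_fit:
        for label, est in lp_table.items():
            cond = est.condition
            curve = curves[label]
            p = est.params_used
            t_end = float(curve.times[-1]) + 2.0
            dense_t = np.arange(0.0, t_end, 1.0 / 60.0)  # 1-s grid
            traj = simulate(
                SimulationParams(
                    Lp=est.lp_mean,
                    A=p.A,
                    N=p.N,
                    T=cond.temperature_k,
                    M_ext=cond.osmolality,
                    V_b=p.V_b,
                    V0_water=p.V_iso,
                ),
                dense_t,
            )
            try:
                shifts[label] = shift_fit(traj, curve)
            except OsmovolError as exc:
                notes.append(f"{label}: shift fit failed: {exc}")

    return StudyReport(
        bvh=bvh_fit,
        v_b_fraction=v_b_fraction,
        lp_table=lp_table,
        rectification=rectification,
        ea_in=ea_fits["hypotonic"],
        ea_out=ea_fits["hypertonic"],
        shifts=shifts,
        warnings=notes,
        provenance={
            "config_hash": _config_hash(config),
            "seed": seed,
            "package_version": __version__,
        },
    )


def validate_input(path: str | Path) -> dict:
    """Schema-check a per-cell kinetics CSV.

    Verifies column presence, positive diameters and strictly increasing
    times per cell.  Returns ``{"ok": bool, "errors": [...], "n_rows": int,
    "n_cells": int}`` with row-level diagnostics (1-based data row numbers).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - report as schema failure
        raise SchemaError(f"{path}: unreadable as CSV: {exc}") from exc

    errors: list[str] = []
    missing = set(CELL_CSV_COLUMNS) - set(df.columns)
    if missing:
        errors.append(f"missing columns: {sorted(missing)}")
        return {"ok": False, "errors": errors, "n_rows": len(df), "n_cells": 0}

    bad_d = df.index[df["diameter_um"] <= 0]
    for i in bad_d[:10]:
        errors.append(f"row {i + 1}: non-positive diameter {df.loc[i, 'diameter_um']}")
    neg_osm = df.index[df["condition_mosm"] <= 0]
    for i in neg_osm[:10]:
        errors.append(f"row {i + 1}: non-positive osmolality")

    n_cells = 0
    for (cond, temp, cid), grp in df.groupby(
        ["condition_mosm", "temperature_c", "cell_id"], sort=False
    ):
        n_cells += 1
        t = grp["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            j = int(np.flatnonzero(np.diff(t) <= 0)[0])
            errors.append(
                f"cell {cid} ({cond} mOsm, {temp} °C): times not strictly "
                f"increasing at sample {j + 1} (t={t[j]} → {t[j + 1]})"
            )
    return {
        "ok": not errors,
        "errors": errors,
        "n_rows": len(df),
        "n_cells": n_cells,
    }
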