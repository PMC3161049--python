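"""Boyle–van't Hoff (BVH) analysis.

An ideal osmometer equilibrates so that its cell volume is linear in the
reciprocal of the external osmolality,

    V_c = a / M + V_b,

where the intercept V_b (the volume at infinite osmolality) is the
non-osmotic volume: solids plus tightly bound water.  The fit is performed
on ABSOLUTE volumes, which keeps slope and intercept genuinely independent
parameters — fitting normalised volumes couples them and biases v_b.

The non-osmotic fraction v_b = V_b / V_ref is reported against a caller-
chosen reference volume: either the directly measured mean isotonic volume
(default, preferred when many cells were measured) or the fitted line's own
volume at isotonic osmolality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError

__all__ = [
    "BvhPoint",
    "BvhFit",
    "fit_bvh",
    "nonosmotic_fraction",
    "bvh_equilibrium_water",
    "bvh_predicted_cell_volume",
    "read_bvh_csv",
]


@dataclass(frozen=True)
class BvhPoint:
    """One equilibrium measurement: mean cell volume at one osmolality."""

    osmolality: float  # Osm/kg
    mean_volume: float  # µm³
    n_cells: int = 1
    se: float = float("nan")  # µm³

    def __post_init__(self) -> None:
        if self.osmolality <= 0:
            raise ValueError("osmolality must be positive")
        if self.mean_volume <= 0:
            raise ValueError("mean_volume must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass(frozen=True)
class BvhFit:
    """Least-squares BVH line: V_c = slope_a / M + V_b."""

    slope_a: float  # µm³·Osm
    V_b: float  # µm³ (intercept)
    v_b: float  # V_b normalised by the reference volume
    r_squared: float
    n_points: int
    V_ref: float  # normalisation reference volume, µm³
    negative_intercept: bool = False
    weighted: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BvhFit":
        return cls(**json.loads(Path(path).read_text()))


def fit_bvh(
    points: Sequence[BvhPoint],
    V_ref: float | None = None,
    weights: str | None = None,
) -> BvhFit:
    """Ordinary least squares of mean volume on reciprocal osmolality.

    Parameters
    ----------
    points : sequence of BvhPoint
        At least two points with distinct osmolalities.
    V_ref : float, optional
        Reference volume for v_b normalisation.  Defaults to the fitted
        line's own prediction at isotonic osmolality (0.308 Osm/kg); pass
        the measured mean isotonic volume to reproduce the conventional
        normalisation.
    weights : {None, "n_cells", "inv_se2"}
        Optional weighting.  The default (None) is the unweighted fit.

    A negative fitted intercept is reported with ``negative_intercept=True``
    and a warning — never clamped — so simulation studies can detect bias.
    """
    from .constants import ISOTONIC_OSMOLALITY

    osm = np.array([p.osmolality for p in points], dtype=float)
    vol = np.array([p.mean_volume for p in points], dtype=float)
    if len(np.unique(osm)) < 2:
        raise InsufficientDataError(
            "BVH fit needs at least 2 points with distinct osmolalities"
        )
    x = 1.0 / osm

    if weights is None:
        res = stats.linregress(x, vol)
        slope, intercept = res.slope, res.intercept
        r2 = res.rvalue**2
    else:
        if weights == "n_cells":
            w = np.array([p.n_cells for p in points], dtype=float)
        elif weights == "inv_se2":
            w = np.array([1.0 / p.se**2 for p in points], dtype=float)
        else:
            raise ValueError(f"unknown weighting scheme {weights!r}")
        X = np.column_stack([x, np.ones_like(x)])
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], vol * sw, rcond=None)
        slope, intercept = coef
        pred = X @ coef
        ybar = np.average(vol, weights=w)
        ss_res = np.sum(w * (vol - pred) ** 2)
        ss_tot = np.sum(w * (vol - ybar) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    negative = intercept < 0
    if negative:
        warnings.warn(
            f"BVH intercept (non-osmotic volume) fitted negative: {intercept:.1f} µm³",
            stacklevel=2,
        )
    if V_ref is None:
        V_ref = slope / ISOTONIC_OSMOLALITY + intercept
    v_b = intercept / V_ref
    return BvhFit(
        slope_a=float(slope),
        V_b=float(intercept),
        v_b=float(v_b),
        r_squared=float(r2),
        n_points=len(points),
        V_ref=float(V_ref),
        negative_intercept=bool(negative),
        weighted=weights is not None,
    )


def nonosmotic_fraction(V_b: float, V_ref: float) -> float:
    """Non-osmotic volume fraction v_b = V_b / V_ref."""
    if V_ref <= 0:
        raise ValueError("reference volume must be positive")
    if not 0 <= V_b <= V_ref:
        raise ValueError("V_b must lie in [0, V_ref]")
    return V_b / V_ref


def bvh_equilibrium_water(
    V_iso_water: float,
    M_iso: float,
    M_ext: float,
    ratio_decimals: int | None = None,
) -> float:
    """Equilibrium water volume after exposure to osmolality M_ext.

    The equilibrium water volume scales with the osmolality ratio:
    Ve = V_iso_water · M_iso / M_ext.  ``ratio_decimals`` optionally rounds
    the osmolality ratio before multiplying, matching hand calculations that
    quote the ratio at fixed precision (e.g. 0.308/0.157 → 1.96).
    """
    if V_iso_water <= 0 or M_iso <= 0:
        raise ValueError("volumes and osmolalities must be positive")
    if M_ext <= 0:
        raise ValueError("external osmolality must be positive")
    ratio = M_iso / M_ext
    if ratio_decimals is not None:
        ratio = round(ratio, ratio_decimals)
    return V_iso_water * ratio


def bvh_predicted_cell_volume(fit: BvhFit, M: float) -> float:
    """Cell volume predicted by the fitted BVH line at osmolality M."""
    if M <= 0:
        raise ValueError("osmolality must be positive")
    return fit.slope_a / M + fit.V_b


def read_bvh_csv(path: str | Path) -> list[BvhPoint]:
    """Read BVH points from CSV.

    Expected columns: ``osmolality_mosm``, ``mean_volume_um3`` and optional
    ``n_cells``, ``se_um3``.
    """
    df = pd.read_csv(path)
    required = {"osmolality_mosm", "mean_volume_um3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"BVH CSV missing columns: {sorted(missing)}")
    points = []
    for _, row in df.iterrows():
        points.append(
            BvhPoint(
                osmolality=row["osmolality_mosm"] / 1000.0,
                mean_volume=row["mean_volume_um3"],
                n_cells=int(row.get("n_cells", 1)),
                se=float(row.get("se_um3", float("nan"))),
            )
        )
    return points
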