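"""Arrhenius activation energy of Lp, and rectification ratios.

Water permeability follows an Arrhenius law, ln Lp = ln Lp0 - Ea/(R'·T), so
the activation energy comes from the slope of ln Lp against 1/T:
Ea = -R'·slope with R' = 1.987 cal/(mol·K).  Rectification — direction
dependence of water permeability — is quantified as the ratio of the
hypotonic (influx) to the hypertonic (efflux) Lp at one temperature.

Room-temperature (22 °C) Lp estimates in cells with an active regulatory
volume decrease are biased low (passive inflow is partly opposed by
regulatory outflow), so they are excluded from the Arrhenius fit by default;
the exclusion is an explicit, logged flag, never silent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .constants import CONSTANTS
from .exceptions import InsufficientDataError

__all__ = [
    "ArrheniusFit",
    "RectificationResult",
    "arrhenius_ea",
    "rectification_ratio",
    "lp_at_temperature",
    "format_ea_kcal",
]


@dataclass(frozen=True)
class ArrheniusFit:
    """Least-squares Arrhenius fit of ln Lp on 1/T."""

    Ea: float  # cal/mol
    ln_prefactor: float
    slope: float  # K
    temps_used: tuple[float, ...]  # K
    lp_used: tuple[float, ...]
    excluded_temps: tuple[float, ...] = ()

    @property
    def Ea_kcal(self) -> float:
        return self.Ea / 1000.0

    def predict_lp(self, T: float) -> float:
        return math.exp(self.ln_prefactor + self.slope / T)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


@dataclass(frozen=True)
class RectificationResult:
    """Hypotonic/hypertonic Lp ratio at one temperature."""

    temperature_c: float
    lp_hypo: float
    lp_hyper: float
    ratio: float


def arrhenius_ea(
    points: Sequence[tuple[float, float]],
    exclude_temps_c: Sequence[float] = (),
) -> ArrheniusFit:
    """Fit Ea from (T in K, Lp) pairs.

    Least squares of ln(Lp) on 1/T; with exactly two points this reduces to
    the closed form slope = ln(Lp2/Lp1)/(1/T2 - 1/T1).  Ea = -R'·slope.
    Temperatures listed in ``exclude_temps_c`` (°C) are dropped before the
    fit and recorded on the result.
    """
    excluded = []
    kept = []
    for T, lp in points:
        if lp <= 0:
            raise ValueError(f"Lp must be positive, got {lp}")
        if any(
            abs(T - (tc + CONSTANTS.kelvin_offset)) < 0.5 for tc in exclude_temps_c
        ):
            excluded.append(T)
        else:
            kept.append((T, lp))
    if len(kept) < 2:
        raise InsufficientDataError("Arrhenius fit needs at least 2 temperature points")
    T = np.array([p[0] for p in kept], dtype=float)
    lp = np.array([p[1] for p in kept], dtype=float)
    if len(np.unique(T)) < len(T):
        raise ValueError("duplicate temperatures make the Arrhenius fit degenerate")
    x = 1.0 / T
    y = np.log(lp)
    if len(kept) == 2:
        slope = (y[1] - y[0]) / (x[1] - x[0])
        intercept = y[0] - slope * x[0]
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
    return ArrheniusFit(
        Ea=float(-CONSTANTS.R_cal * slope),
        ln_prefactor=float(intercept),
        slope=float(slope),
        temps_used=tuple(float(t) for t in T),
        lp_used=tuple(float(v) for v in lp),
        excluded_temps=tuple(float(t) for t in excluded),
    )


def rectification_ratio(lp_hypo: float, lp_hyper: float) -> float:
    """Direction asymmetry of water permeability: Lp(influx)/Lp(efflux)."""
    if lp_hypo <= 0 or lp_hyper <= 0:
        raise ValueError("both Lp values must be positive")
    return lp_hypo / lp_hyper


def lp_at_temperature(
    lp_ref: float, T_ref: float, T: float, Ea: float
) -> float:
    """Extrapolate Lp along an Arrhenius law with activation energy Ea (cal/mol).

    Lp(T) = lp_ref · exp(-(Ea/R')·(1/T - 1/T_ref)).
    """
    if lp_ref <= 0 or T_ref <= 0 or T <= 0:
        raise ValueError("Lp and temperatures must be positive")
    return lp_ref * math.exp(-(Ea / CONSTANTS.R_cal) * (1.0 / T - 1.0 / T_ref))


def format_ea_kcal(Ea_cal: float, decimals: int = 1) -> str:
    """Format an activation energy in kcal/mol at the conventional precision."""
    return f"{Ea_cal / 1000.0:.{decimals}f} kcal/mol"
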