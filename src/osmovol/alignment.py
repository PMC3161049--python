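"""Overlay of simulated shrink/swell curves on observed averaged curves.

A simulated trajectory started at the isotonic volume at t = 0 differs from
an observed averaged curve in two systematic ways: the observation clock
starts only after a mixing dead time (a rightward time shift), and the
observed equilibrium volume does not exactly obey the Boyle–van't Hoff
prediction (a vertical volume offset).  Rather than shifting curves by eye,
:func:`shift_fit` finds the least-squares (dt, dv):

    minimise  Σ_i [ V_obs(t_i) - V_sim(t_i - dt) - dv ]²

For a fixed dt the optimal dv is the mean residual, so the search is a 1-D
problem in dt: a coarse grid scan followed by bounded local refinement.
The dense simulated curve is linearly interpolated at the shifted observed
times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .exceptions import InfeasibleShiftError
from .lp import AveragedCurve
from .simulator import Trajectory

__all__ = ["ShiftFit", "shift_fit"]


@dataclass(frozen=True)
class ShiftFit:
    """Best-fit time/volume shift of a simulated curve onto observed points."""

    dt: float  # min (positive = simulation shifted right / later)
    dv: float  # µm³ (added to the simulated volumes)
    rss: float  # µm⁶
    n_points: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _residual_stats(
    t_obs: np.ndarray,
    v_obs: np.ndarray,
    t_sim: np.ndarray,
    v_sim: np.ndarray,
    dt: float,
) -> tuple[float, float]:
    """Optimal dv and resulting RSS for a fixed time shift."""
    v_at = np.interp(t_obs - dt, t_sim, v_sim)
    dv = float(np.mean(v_obs - v_at))
    rss = float(np.sum((v_obs - v_at - dv) ** 2))
    return dv, rss


def shift_fit(
    trajectory: Trajectory,
    observed: AveragedCurve,
    dt_bounds: tuple[float, float] = (0.0, 1.5),
    dv_bounds: tuple[float, float] | None = None,
    n_grid: int = 151,
) -> ShiftFit:
    """Fit the (dt, dv) shift overlaying a simulation on observed points.

    ``dt_bounds`` default to [0, 1.5] min, covering the plausible mixing
    dead time; ``dv_bounds``, if given, constrain the volume offset (the
    default leaves it free).  Every candidate dt must keep the shifted
    observed times inside the simulated time span (linear interpolation
    only, no extrapolation).
    """
    t_obs = np.asarray(observed.times, dtype=float)
    v_obs = np.asarray(observed.mean_volume, dtype=float)
    if len(t_obs) < 3:
        raise ValueError("need at least 3 observed points")
    t_sim = np.asarray(trajectory.times, dtype=float)
    v_sim = np.asarray(trajectory.cell_volumes, dtype=float)

    # feasible dt: observed times shifted back must stay within the sim span,
    # i.e. t_sim[0] <= t_obs[0] - dt and t_obs[-1] - dt <= t_sim[-1]
    lo = max(dt_bounds[0], t_obs[-1] - t_sim[-1])
    hi = min(dt_bounds[1], t_obs[0] - t_sim[0])
    if not lo <= hi:
        raise InfeasibleShiftError(
            f"no dt in [{dt_bounds[0]}, {dt_bounds[1]}] keeps the observed span "
            "inside the simulated trajectory"
        )

    def objective(dt: float) -> float:
        dv, rss = _residual_stats(t_obs, v_obs, t_sim, v_sim, dt)
        if dv_bounds is not None:
            dv = float(np.clip(dv, *dv_bounds))
            v_at = np.interp(t_obs - dt, t_sim, v_sim)
            rss = float(np.sum((v_obs - v_at - dv) ** 2))
        return rss

    grid = np.linspace(lo, hi, n_grid)
    rss_grid = np.array([objective(d) for d in grid])
    i = int(np.argmin(rss_grid))

    if lo == hi:
        best_dt = lo
    else:
        a = grid[max(i - 1, 0)]
        b = grid[min(i + 1, n_grid - 1)]
        res = minimize_scalar(objective, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-6})
        best_dt = float(res.x) if res.fun <= rss_grid[i] else float(grid[i])

    dv, rss = _residual_stats(t_obs, v_obs, t_sim, v_sim, best_dt)
    if dv_bounds is not None:
        dv = float(np.clip(dv, *dv_bounds))
        v_at = np.interp(t_obs - best_dt, t_sim, v_sim)
        rss = float(np.sum((v_obs - v_at - dv) ** 2))
    return ShiftFit(dt=best_dt, dv=dv, rss=rss, n_points=len(t_obs))
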