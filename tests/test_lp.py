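"""Curve averaging, plateau detection and pairwise Lp estimation."""

import numpy as np
import pytest

from osmovol import (
    AveragedCurve,
    CellSeries,
    Condition,
    SimulationParams,
    average_lp,
    build_average_curve,
    detect_equilibrium,
    lp_from_pair,
    simulate,
    sphere_diameter,
    sphere_volume,
)
from osmovol.exceptions import (
    GridAlignmentError,
    InconsistentPairError,
    InsufficientDataError,
    NearEquilibriumError,
    NoPlateauError,
)
from osmovol.lp import read_cell_series_csv, write_cell_series_csv

COND_SHRINK = Condition(osmolality=0.602, temperature_c=10.0)
COND_SWELL = Condition(osmolality=0.157, temperature_c=10.0)


def curve_from_sim(sim_params, cond, t_end_min=20.0, dt_s=10.0):
    """Noise-free averaged curve sampled from a single simulated cell."""
    t = np.arange(0.0, t_end_min * 60.0 + 1e-9, dt_s) / 60.0
    traj = simulate(sim_params, t)
    return AveragedCurve(
        condition=cond,
        times=t,
        mean_volume=traj.cell_volumes,
        se=np.zeros_like(t),
        n_cells=1,
    )


class TestBuildAverageCurve:
    def _cells(self, diam_rows, alive=None):
        t = np.arange(0.0, 60.0, 10.0)
        alive = alive or [True] * len(diam_rows)
        return [
            CellSeries(f"c{i}", COND_SHRINK, t, np.full(len(t), d), alive=a)
            for i, (d, a) in enumerate(zip(diam_rows, alive))
        ]

    def test_identical_cells_reproduce_single_series(self):
        cells = self._cells([20.0, 20.0, 20.0])
        curve = build_average_curve(cells)
        assert curve.mean_volume == pytest.approx(
            sphere_volume(cells[0].diameters), rel=1e-12
        )
        assert curve.times == pytest.approx(cells[0].times / 60.0)

    def test_mean_diameter_then_cube(self):
        """Two cells at 10 and 20 µm average to 15 µm → π·15³/6 µm³."""
        curve = build_average_curve(self._cells([10.0, 20.0]))
        assert curve.mean_volume[0] == pytest.approx(1767.15, abs=0.01)

    def test_dead_cells_excluded_from_count(self):
        cells = self._cells([18.0] * 10, alive=[True] * 8 + [False] * 2)
        curve = build_average_curve(cells)
        assert curve.n_cells == 8

    def test_no_alive_cells_is_an_error(self):
        with pytest.raises(InsufficientDataError):
            build_average_curve(self._cells([18.0], alive=[False]))

    def test_ragged_grid_rejected(self):
        t = np.arange(0.0, 60.0, 10.0)
        a = CellSeries("a", COND_SHRINK, t, np.full(6, 18.0))
        b = CellSeries("b", COND_SHRINK, t + 2.0, np.full(6, 18.0))
        with pytest.raises(GridAlignmentError):
            build_average_curve([a, b])


class TestDetectEquilibrium:
    def _curve(self, volumes, dt_min=1.0 / 6.0):
        t = np.arange(len(volumes)) * dt_min
        return AveragedCurve(COND_SHRINK, t, np.asarray(volumes, float),
                             np.zeros(len(volumes)), 5)

    def test_constant_curve_plateaus_immediately(self):
        t_eq, V_eq = detect_equilibrium(self._curve([3000.0] * 12))
        assert t_eq == 0.0
        assert V_eq == pytest.approx(3000.0)

    def test_linear_ramp_has_no_plateau(self):
        with pytest.raises(NoPlateauError):
            detect_equilibrium(self._curve(np.linspace(3000.0, 2000.0, 25)))

    def test_detected_plateau_matches_analytic_equilibrium(self, shrink_sim_10c):
        curve = curve_from_sim(shrink_sim_10c, COND_SHRINK)
        _, V_eq = detect_equilibrium(curve)
        assert V_eq == pytest.approx(
            shrink_sim_10c.Ve + shrink_sim_10c.V_b, rel=0.01
        )

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            detect_equilibrium(self._curve([1.0, 2.0, 3.0]))


class TestLpFromPair:
    def test_equal_volumes_give_zero(self, params_10c):
        lp = lp_from_pair(2000.0, 1.0, 2000.0, 2.0, 1500.0, params_10c, 283.15)
        assert lp == 0.0

    def test_recovers_generating_lp_from_any_pair(self, params_10c):
        """Every interior pair of a noise-free simulated curve returns the
        generating Lp — the integrated and differential forms are duals."""
        sp = SimulationParams(
            Lp=1.50, A=params_10c.A, N=params_10c.N, T=283.15, M_ext=0.157,
            V_b=params_10c.V_b, V0_water=params_10c.V_iso,
        )
        t = np.linspace(0.0, 2.0, 30)
        traj = simulate(sp, t)
        w = traj.water_volumes
        for i, j in [(0, 5), (2, 9), (4, 20), (10, 25)]:
            lp = lp_from_pair(w[i], t[i], w[j], t[j], sp.Ve, params_10c, 283.15)
            assert lp == pytest.approx(1.50, rel=1e-6)

    def test_time_rescaling_consistency(self, params_10c):
        """A curve simulated with Lp/2 sampled at doubled times yields Lp/2."""
        base = SimulationParams(
            Lp=0.8, A=params_10c.A, N=params_10c.N, T=283.15, M_ext=0.602,
            V_b=params_10c.V_b, V0_water=params_10c.V_iso,
        )
        slow = SimulationParams(
            Lp=0.4, A=params_10c.A, N=params_10c.N, T=283.15, M_ext=0.602,
            V_b=params_10c.V_b, V0_water=params_10c.V_iso,
        )
        t = np.array([0.05, 0.1, 0.2, 0.3])
        w = simulate(slow, 2.0 * t).water_volumes
        lp = lp_from_pair(w[0], 2 * t[0], w[2], 2 * t[2], slow.Ve, params_10c, 283.15)
        assert lp == pytest.approx(0.4, rel=1e-6)

    def test_opposite_sides_of_equilibrium_rejected(self, params_10c):
        with pytest.raises(InconsistentPairError):
            lp_from_pair(2000.0, 0.0, 1000.0, 1.0, 1500.0, params_10c, 283.15)

    def test_near_equilibrium_guard(self, params_10c):
        with pytest.raises(NearEquilibriumError):
            lp_from_pair(2000.0, 0.0, 1501.0, 1.0, 1500.0, params_10c, 283.15)


class TestAverageLp:
    def test_noise_free_swell_recovery(self, params_10c, swell_sim_10c):
        """Noise-free hypotonic curve at 10 °C: lp_mean recovers 1.73 almost
        exactly and the pair scatter collapses (single-Lp consistency)."""
        curve = curve_from_sim(swell_sim_10c, COND_SWELL)
        est = average_lp(curve, params_10c, 283.15, Ve_mode="bvh")
        assert est.lp_mean == pytest.approx(1.73, rel=1e-4)
        assert est.lp_se < 1e-4
        assert np.std(est.pair_values) < 1e-6 * est.lp_mean

    def test_noise_free_shrink_recovery(self, params_10c, shrink_sim_10c):
        curve = curve_from_sim(shrink_sim_10c, COND_SHRINK)
        est = average_lp(curve, params_10c, 283.15, Ve_mode="bvh")
        assert est.lp_mean == pytest.approx(0.21, rel=1e-4)

    def test_measured_ve_mode_close_to_bvh_on_clean_data(
        self, params_10c, shrink_sim_10c
    ):
        curve = curve_from_sim(shrink_sim_10c, COND_SHRINK)
        est = average_lp(curve, params_10c, 283.15, Ve_mode="measured")
        assert est.lp_mean == pytest.approx(0.21, rel=5e-3)

    def test_start_time_invariance(self, params_10c, shrink_sim_10c):
        """Only time differences matter: offsetting the clock by a constant
        (mixing dead time) leaves the estimate unchanged."""
        curve = curve_from_sim(shrink_sim_10c, COND_SHRINK)
        shifted = AveragedCurve(
            curve.condition, curve.times + 0.6, curve.mean_volume, curve.se,
            curve.n_cells,
        )
        a = average_lp(curve, params_10c, 283.15, Ve_mode="bvh")
        b = average_lp(shifted, params_10c, 283.15, Ve_mode="bvh")
        assert b.lp_mean == pytest.approx(a.lp_mean, rel=1e-9)

    def test_direction_duality_of_estimator(self, params_10c):
        """Swell and shrink curves generated with the SAME Lp yield equal
        estimates: rectification can only come from the data."""
        common = dict(A=params_10c.A, N=params_10c.N, T=283.15,
                      V_b=params_10c.V_b, V0_water=params_10c.V_iso)
        swell = SimulationParams(Lp=0.9, M_ext=0.157, **common)
        shrink = SimulationParams(Lp=0.9, M_ext=0.602, **common)
        est_in = average_lp(curve_from_sim(swell, COND_SWELL, 10.0, 2.0),
                            params_10c, 283.15, Ve_mode="bvh")
        est_out = average_lp(curve_from_sim(shrink, COND_SHRINK, 10.0, 2.0),
                             params_10c, 283.15, Ve_mode="bvh")
        assert est_in.lp_mean == pytest.approx(est_out.lp_mean, rel=2e-4)

    def test_pairs_avoid_near_equilibrium_band(self, params_10c, shrink_sim_10c):
        """No pair value may use samples inside the eps-band around Ve."""
        curve = curve_from_sim(shrink_sim_10c, COND_SHRINK)
        eps = 0.05
        est = average_lp(curve, params_10c, 283.15, Ve_mode="bvh", eps=eps)
        water = curve.mean_volume - params_10c.V_b
        Ve = est.Ve_used
        # reconstruct: every pair's implied volumes are outside the band
        for lp in est.pair_values:
            assert lp > 0
        dyn_band = np.abs(water - Ve) > eps * abs(water[0] - Ve)
        assert est.n_pairs <= 15

    def test_noisy_recovery_within_ten_percent(self, params_10c):
        """50-cell noisy averaged curve (σ_d = 0.3 µm): Lp within 10%."""
        rng = np.random.default_rng(7)
        sp = SimulationParams(
            Lp=0.21, A=params_10c.A, N=params_10c.N, T=283.15, M_ext=0.602,
            V_b=params_10c.V_b, V0_water=params_10c.V_iso,
        )
        t = np.arange(0.0, 1200.0 + 1e-9, 10.0) / 60.0
        traj = simulate(sp, t)
        d_true = sphere_diameter(traj.cell_volumes)
        D = d_true + rng.normal(0.0, 0.3, size=(50, len(t)))
        mean_d = D.mean(axis=0)
        curve = AveragedCurve(COND_SHRINK, t, sphere_volume(mean_d),
                              np.zeros_like(t), 50)
        est = average_lp(curve, params_10c, 283.15)
        assert est.lp_mean == pytest.approx(0.21, rel=0.10)

    def test_insufficient_dynamics_error(self, params_10c):
        flat = AveragedCurve(
            COND_SHRINK, np.arange(10) / 6.0, np.full(10, 2626.0),
            np.zeros(10), 5,
        )
        with pytest.raises(InsufficientDataError):
            average_lp(flat, params_10c, 283.15, Ve_mode="bvh")


def test_cell_series_csv_round_trip(tmp_path):
    t = np.arange(0.0, 100.0, 10.0)
    cells = [
        CellSeries("c0", COND_SHRINK, t, np.linspace(18.0, 16.0, 10), alive=True),
        CellSeries("c1", COND_SHRINK, t, np.linspace(19.0, 17.0, 10), alive=False),
    ]
    path = tmp_path / "cells.csv"
    write_cell_series_csv(cells, path)
    loaded = read_cell_series_csv(path)
    assert len(loaded) == 2
    assert loaded[0].diameters == pytest.approx(cells[0].diameters)
    assert loaded[1].alive is False
    assert loaded[0].condition.osmolality == pytest.approx(0.602)
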