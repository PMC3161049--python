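"""Synthetic volumetry study generator."""

import numpy as np
import pytest

from osmovol import (
    Condition,
    PopulationConfig,
    ProtocolConfig,
    StudyBundle,
    SyntheticStudyConfig,
    TrueParams,
    generate_cells,
    generate_experiment,
    generate_study,
    simulate,
    sphere_diameter,
)
from osmovol.simulator import SimulationParams

HYPO_10 = Condition(osmolality=0.157, temperature_c=10.0)


class TestGenerateCells:
    def test_same_seed_identical_population(self):
        pop = PopulationConfig(n_cells=40)
        a = generate_cells(pop, 11)
        b = generate_cells(pop, 11)
        assert [c.diameter_iso for c in a] == [c.diameter_iso for c in b]
        assert [c.alive for c in a] == [c.alive for c in b]

    def test_population_statistics(self):
        pop = PopulationConfig(n_cells=500)
        cells = generate_cells(pop, 3)
        d = np.array([c.diameter_iso for c in cells])
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() - 18.5) < 3 * se
        assert d.min() >= 9.0 and d.max() <= 33.0

    def test_dead_fraction_zero_means_all_alive(self):
        cells = generate_cells(PopulationConfig(n_cells=100, dead_fraction=0.0), 5)
        assert all(c.alive for c in cells)

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            PopulationConfig(diameter_mean=50.0, diameter_sd=1.0,
                             diameter_bounds=(9.0, 33.0))


class TestGenerateExperiment:
    def test_noise_free_single_cell_matches_simulator(self):
        """With zero noise and zero dead time, a generated series is the
        simulated trajectory converted to diameters."""
        pop = PopulationConfig(n_cells=1, diameter_sd=1e-9, dead_fraction=0.0)
        cells = generate_cells(pop, 0)
        proto = ProtocolConfig(dead_time_range=(0.0, 0.0), diameter_noise_sd=0.0)
        tp = TrueParams()
        series = generate_experiment(cells, HYPO_10, tp, proto, 1)[0]
        p = cells[0].osmotic_params()
        ref = simulate(
            SimulationParams(
                Lp=tp.lp_for(HYPO_10), A=p.A, N=p.N, T=283.15, M_ext=0.157,
                V_b=p.V_b, V0_water=p.V_iso,
            ),
            series.times / 60.0,
        )
        assert series.diameters == pytest.approx(
            sphere_diameter(ref.cell_volumes), rel=1e-8
        )

    def test_hypotonic_swelling_direction(self):
        cells = generate_cells(PopulationConfig(n_cells=10, dead_fraction=0.0), 2)
        proto = ProtocolConfig(diameter_noise_sd=0.0)
        series = generate_experiment(cells, HYPO_10, TrueParams(), proto, 3)
        for s in series:
            assert s.diameters[-1] > s.diameters[0]

    def test_dead_time_offsets_first_sample(self):
        cells = generate_cells(PopulationConfig(n_cells=2, dead_fraction=0.0), 2)
        proto = ProtocolConfig(dead_time_range=(30.0, 30.0))
        series = generate_experiment(cells, HYPO_10, TrueParams(), proto, 3)
        assert series[0].times[0] == pytest.approx(30.0)

    def test_sampling_grid_cadence(self):
        grid = ProtocolConfig().sample_grid()
        assert grid[0] == 0.0
        assert np.all(np.diff(grid[:31]) == 10.0)  # fast phase: 10-s frames
        assert np.all(np.diff(grid[31:]) == 30.0)  # slow phase: 30-s frames

    def test_dead_cells_stay_at_isotonic_volume(self):
        pop = PopulationConfig(n_cells=20, dead_fraction=0.5)
        cells = generate_cells(pop, 8)
        proto = ProtocolConfig(diameter_noise_sd=0.0)
        series = generate_experiment(cells, HYPO_10, TrueParams(), proto, 3)
        dead = [s for s in series if not s.alive]
        assert dead, "expected some dead cells at 50% dead fraction"
        for s in dead:
            assert np.ptp(s.diameters) == pytest.approx(0.0, abs=1e-12)


class TestGenerateStudy:
    def test_seeded_regeneration_is_identical(self, tmp_path):
        cfg = SyntheticStudyConfig(
            population=PopulationConfig(n_cells=8), seed=21
        )
        a, b = generate_study(cfg), generate_study(cfg)
        for label in a.experiments:
            for ca, cb in zip(a.experiments[label], b.experiments[label]):
                assert ca.diameters == pytest.approx(cb.diameters, rel=0, abs=0)
        assert [p.mean_volume for p in a.bvh_points] == [
            p.mean_volume for p in b.bvh_points
        ]

    def test_six_conditions_plus_bvh_series(self):
        cfg = SyntheticStudyConfig(population=PopulationConfig(n_cells=5), seed=2)
        bundle = generate_study(cfg)
        assert len(bundle.experiments) == 6
        assert len(bundle.bvh_points) == 5
        assert set(bundle.isotonic_volumes) == {"0", "10", "22"}

    def test_ground_truth_rectification_by_construction(self):
        cfg = SyntheticStudyConfig(population=PopulationConfig(n_cells=3), seed=2)
        bundle = generate_study(cfg)
        tp = cfg.true_params
        lp_in = bundle.truth["lp_by_condition"]["157mOsm_10C"]
        lp_out = bundle.truth["lp_by_condition"]["602mOsm_10C"]
        assert lp_in / lp_out == pytest.approx(tp.lp_in_ref / tp.lp_out_ref)

    def test_ground_truth_not_leaked_into_data_files(self, tmp_path):
        cfg = SyntheticStudyConfig(population=PopulationConfig(n_cells=4), seed=9)
        bundle = generate_study(cfg)
        bundle.write(tmp_path)
        for csv in tmp_path.glob("*.csv"):
            text = csv.read_text()
            assert "lp" not in text.lower()
            assert "truth" not in text.lower()

    def test_bundle_round_trip(self, tmp_path):
        cfg = SyntheticStudyConfig(population=PopulationConfig(n_cells=4), seed=9)
        bundle = generate_study(cfg)
        bundle.write(tmp_path)
        loaded = StudyBundle.load(tmp_path)
        assert loaded.truth["seed"] == 9
        assert len(loaded.experiments) == 6
        orig = bundle.experiments["602mOsm_0C"][0]
        back = loaded.experiments["602mOsm_0C"][0]
        assert back.diameters == pytest.approx(orig.diameters)
        assert back.condition.osmolality == pytest.approx(orig.condition.osmolality)

    def test_noise_increases_estimate_uncertainty(self):
        """More diameter noise → larger SE of the recovered Lp (seed-averaged)."""
        from osmovol import average_lp, build_average_curve, OsmoticCellParams

        ses = []
        for noise in (0.1, 0.6):
            se_acc = []
            for seed in (1, 2, 3):
                cfg = SyntheticStudyConfig(
                    population=PopulationConfig(n_cells=30, dead_fraction=0.0),
                    protocol=ProtocolConfig(diameter_noise_sd=noise),
                    seed=seed,
                )
                bundle = generate_study(cfg)
                curve = build_average_curve(bundle.experiments["602mOsm_0C"])
                iso = bundle.isotonic_volumes["0"]["volume_of_mean_diameter_um3"]
                params = OsmoticCellParams.from_isotonic(iso, 0.29 * iso)
                est = average_lp(curve, params, 273.15)
                se_acc.append(est.lp_se)
            ses.append(np.mean(se_acc))
        assert ses[1] > ses[0]
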