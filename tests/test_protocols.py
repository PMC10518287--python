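"""Protocol construction, osmotic feasibility, and grid optimization."""

import numpy as np
import pytest

from cryoperf import (
    LoadingProtocol,
    OptimizationGrid,
    OsmoticConstraints,
    build_protocol,
    check_osmotic,
    existing_protocol,
    optimize_protocol,
    optimized_protocol,
    simulate_loading,
)


class TestBuildProtocol:
    def test_reference_protocol_shape(self):
        p = build_protocol(50.0, 100.0, 10.0)
        assert p.plateau_conc == pytest.approx(5.0)
        assert p.step_time_min == pytest.approx(130.0)  # incl. 20-min flush
        assert p.arterial_concentration(19.0) == 0.0
        assert p.arterial_concentration(70.0) == pytest.approx(2.5)
        assert p.arterial_concentration(125.0) == pytest.approx(5.0)
        assert p.arterial_concentration(140.0) == pytest.approx(8.4)
        assert p.pressure_mmHg(60.0) == 40.0
        assert p.pressure_mmHg(131.0) == 60.0

    def test_fractional_plateau_concentration(self):
        assert build_protocol(62.0, 80.0, 5.0).plateau_conc == pytest.approx(4.96)

    def test_flush_only_protocol(self):
        p = build_protocol(0.0, 0.0, 0.0, full_strength_duration=0.0)
        for t in (0.0, 10.0, 19.9):
            assert p.arterial_concentration(t) == 0.0

    def test_overstrength_plateau_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_protocol(100.0, 100.0, 5.0)  # implies 10 M > 8.4 M


class _FakeSim:
    """Minimal stand-in exposing the fields check_osmotic reads."""

    def __init__(self, t_min, v_frac_baseline):
        self.time_min = np.asarray(t_min, dtype=float)
        self.v_frac_baseline = np.asarray(v_frac_baseline, dtype=float)


class TestCheckOsmotic:
    def test_no_excursion(self):
        t = np.linspace(0.0, 100.0, 101)
        ok, mn, stress = check_osmotic(_FakeSim(t, np.ones_like(t)))
        assert ok and mn == 1.0 and stress == 0.0

    def test_hard_floor_violation(self):
        t = np.linspace(0.0, 100.0, 101)
        v = np.ones_like(t)
        v[50] = 0.40
        ok, mn, _ = check_osmotic(_FakeSim(t, v))
        assert not ok and mn == pytest.approx(0.40)

    def test_stress_duration_violation(self):
        t = np.linspace(0.0, 100.0, 1001)
        v = np.where((t >= 30) & (t < 60), 0.70, 1.0)  # 30 min below 73%
        ok, mn, stress = check_osmotic(_FakeSim(t, v))
        assert not ok
        assert stress == pytest.approx(30.0, abs=0.2)

    def test_short_stress_is_tolerated(self):
        t = np.linspace(0.0, 100.0, 1001)
        v = np.where((t >= 30) & (t < 50), 0.70, 1.0)  # 20 min < 25 min cap
        ok, _, stress = check_osmotic(_FakeSim(t, v))
        assert ok
        assert stress == pytest.approx(20.0, abs=0.2)

    def test_contiguous_mode_counts_longest_run(self):
        t = np.linspace(0.0, 100.0, 1001)
        v = np.ones_like(t)
        v[(t >= 10) & (t < 25)] = 0.70  # 15 min
        v[(t >= 60) & (t < 75)] = 0.70  # 15 min, separated
        cum = OsmoticConstraints()
        cont = OsmoticConstraints(contiguous=True)
        assert not check_osmotic(_FakeSim(t, v), cum)[0]  # 30 min cumulative
        assert check_osmotic(_FakeSim(t, v), cont)[0]  # 15 min per stretch


class TestAutoHold:
    def test_hold_terminates_at_target(self, geom, mem, tox, settings):
        ref = simulate_loading(existing_protocol(), geom, mem, tox, settings)
        sim = simulate_loading(optimized_protocol(), geom, mem, tox, settings,
                               target_conc_M=ref.final_C_tissue_M)
        assert sim.target_reached
        assert sim.final_C_tissue_M == pytest.approx(ref.final_C_tissue_M, rel=1e-4)

    def test_target_already_exceeded_gives_zero_hold(self, geom, mem, tox, settings):
        sim = simulate_loading(optimized_protocol(), geom, mem, tox, settings,
                               target_conc_M=0.5)
        assert sim.full_strength_duration_min == pytest.approx(0.0, abs=1e-9)

    def test_asymptotic_target_hits_cap(self, geom, mem, tox, settings):
        # target equal to the arterial concentration is approached asymptotically
        proto = build_protocol(62.0, 80.0, 5.0, hold_cap_min=30.0)
        sim = simulate_loading(proto, geom, mem, tox, settings, target_conc_M=8.4)
        assert not sim.target_reached
        assert sim.full_strength_duration_min == pytest.approx(30.0, rel=1e-6)


@pytest.fixture(scope="module")
def tiny_sweep(geom, mem, tox, settings):
    grid = OptimizationGrid(
        ramp_rates=np.array([50.0, 62.0]),
        ramp_durations=np.array([80.0, 100.0]),
        plateau_durations=np.array([5.0, 10.0]),
    )
    return optimize_protocol(grid, geom, mem, tox, settings=settings)


class TestOptimizeProtocol:
    def test_records_cover_grid_and_argmin_is_feasible(self, tiny_sweep):
        res = tiny_sweep
        assert len(res.records) == 8
        best = res.records[
            (res.records.ramp_rate_mM_min == res.best.ramp_rate)
            & (res.records.ramp_dur_min == res.best.ramp_duration)
            & (res.records.plateau_dur_min == res.best.plateau_duration)
        ]
        assert bool(best.feasible.iloc[0])
        assert 3.0 <= res.best.plateau_conc <= 7.0

    def test_faster_ramp_beats_reference(self, tiny_sweep):
        rec = tiny_sweep.records.set_index(
            ["ramp_rate_mM_min", "ramp_dur_min", "plateau_dur_min"]
        )
        assert rec.loc[(62.0, 80.0, 5.0), "Jtox"] < rec.loc[(50.0, 100.0, 10.0), "Jtox"]

    def test_deterministic_reruns(self, tiny_sweep, geom, mem, tox, settings):
        grid = OptimizationGrid(
            ramp_rates=np.array([50.0, 62.0]),
            ramp_durations=np.array([80.0, 100.0]),
            plateau_durations=np.array([5.0, 10.0]),
        )
        again = optimize_protocol(grid, geom, mem, tox, settings=settings)
        assert np.array_equal(
            tiny_sweep.records["Jtox"].to_numpy(), again.records["Jtox"].to_numpy()
        )

    def test_out_of_band_plateau_concentration_excluded(self, geom, mem, tox, settings):
        grid = OptimizationGrid(
            ramp_rates=np.array([40.0, 62.0]),
            ramp_durations=np.array([70.0, 80.0]),
            plateau_durations=np.array([5.0]),
        )
        res = optimize_protocol(grid, geom, mem, tox, settings=settings)
        rec = res.records.set_index(["ramp_rate_mM_min", "ramp_dur_min"])
        assert rec.loc[(40.0, 70.0), "reason"] == "plateau_conc_out_of_bounds"  # 2.8 M
        assert bool(rec.loc[(62.0, 80.0), "feasible"])

    def test_refinement_never_raises_the_minimum(self, tiny_sweep, geom, mem, tox, settings):
        finer = OptimizationGrid(
            ramp_rates=np.array([50.0, 56.0, 62.0]),
            ramp_durations=np.array([80.0, 90.0, 100.0]),
            plateau_durations=np.array([5.0, 7.0, 10.0]),
        )
        res = optimize_protocol(finer, geom, mem, tox, settings=settings)
        assert res.best_J_tox <= tiny_sweep.best_J_tox + 1e-12

    def test_empty_feasible_set_raises(self, geom, mem, tox, settings):
        grid = OptimizationGrid(
            ramp_rates=np.array([40.0]),
            ramp_durations=np.array([70.0]),  # 2.8 M plateau, out of band
            plateau_durations=np.array([4.0]),
        )
        with pytest.raises(RuntimeError, match="no feasible"):
            optimize_protocol(grid, geom, mem, tox, settings=settings)
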