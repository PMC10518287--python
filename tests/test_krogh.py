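"""Krogh-unit primitives and the loading simulator."""

import math

import numpy as np
import pytest

from cryoperf import (
    BoundaryState,
    KroghGeometry,
    MembraneParams,
    OsmoticCollapseError,
    SimSettings,
    TissueState,
    capillary_radius,
    existing_protocol,
    kk_fluxes,
    perfusion_resistance_norm,
    simulate_loading,
    structural_resistance_norm,
)
from cryoperf.protocols import build_protocol


class TestGeometry:
    def test_initial_volume(self, geom):
        # V0 = l_c (2 sqrt3 r_a^2 - pi r_c0^2) with the reference dimensions
        assert geom.V0 == pytest.approx(1.28367e-15, rel=1e-4)

    def test_invariant_ordering_enforced(self):
        with pytest.raises(ValueError):
            KroghGeometry(r_c0=4e-6, r_a=3.9e-6)
        with pytest.raises(ValueError):
            KroghGeometry(r_a=8e-6, r_k=7.5e-6)

    @pytest.mark.parametrize(
        "v_frac, rc_um",
        [(1.0, 3.000), (0.5, 3.566), (1e-12, 4.053)],  # shrink widens the lumen
    )
    def test_capillary_radius(self, geom, v_frac, rc_um):
        assert capillary_radius(v_frac * geom.V0, geom) * 1e6 == pytest.approx(
            rc_um, abs=5e-4
        )

    def test_radius_volume_round_trip(self, geom):
        for f in (0.3, 0.7, 1.0, 1.2):
            rc = capillary_radius(f * geom.V0, geom)
            v_back = geom.l_c * (2 * math.sqrt(3) * geom.r_a**2 - math.pi * rc**2)
            assert v_back == pytest.approx(f * geom.V0, rel=1e-12)

    def test_collapsed_geometry_rejected(self, geom):
        with pytest.raises(OsmoticCollapseError):
            capillary_radius(-1e-18, geom)
        with pytest.raises(OsmoticCollapseError):
            capillary_radius(geom.V_max * 1.01, geom)


class TestResistance:
    def test_fourth_power_law(self, geom):
        assert structural_resistance_norm(geom.r_c0, geom) == pytest.approx(1.0)
        assert structural_resistance_norm(3.566e-6, geom) == pytest.approx(0.501, abs=1e-3)
        assert structural_resistance_norm(geom.r_c0 / 2, geom) == pytest.approx(16.0)

    def test_perfusion_resistance_is_viscosity_scaled(self):
        assert perfusion_resistance_norm(1.0, 1.0) == 1.0
        assert perfusion_resistance_norm(0.501, 1.0) == pytest.approx(0.501)
        assert perfusion_resistance_norm(1.0, 3.0) == pytest.approx(3.0)


class TestKKFluxes:
    def test_no_driving_force_no_flux(self, geom, mem):
        st = TissueState(V=geom.V0, n_cpa=0.0, n_is=290.0 * geom.V0)
        bd = BoundaryState(C_cpa_f=0.0, C_is_f=290.0)
        jv, jc = kk_fluxes(st, bd, mem, geom)
        assert jv == pytest.approx(0.0, abs=1e-30)
        assert jc == pytest.approx(0.0, abs=1e-30)

    def test_impermeant_gradient_draws_water_out(self, geom, mem):
        # 300 mol/m^3 hypertonic challenge at 277 K, fixed area 2 pi r_c0 l_c
        st = TissueState(V=geom.V0, n_cpa=0.0, n_is=290.0 * geom.V0)
        bd = BoundaryState(C_cpa_f=0.0, C_is_f=590.0)
        s = SimSettings(temperature=277.0)
        jv, _ = kk_fluxes(st, bd, mem, geom, s)
        assert jv == pytest.approx(-1.074e-17, rel=1e-3)

    def test_cpa_flux_terms(self, geom):
        # diffusive term S omega RT dC, plus solvent drag (1-sigma) * mean C
        mem = MembraneParams(L_p=1.5e-14, omega=7.0e-13, sigma=0.10)
        st = TissueState(V=geom.V0, n_cpa=0.0, n_is=330.0 * geom.V0)
        bd = BoundaryState(C_cpa_f=2100.0, C_is_f=330.0)
        s = SimSettings(temperature=277.0)
        jv, jc = kk_fluxes(st, bd, mem, geom, s)
        diffusive = 3.5095e-15
        drag = jv * 0.9 * 1050.0
        assert jc == pytest.approx(diffusive + drag, rel=1e-3)

    def test_invalid_state_rejected(self, geom):
        with pytest.raises(ValueError):
            TissueState(V=-1e-16, n_cpa=0.0, n_is=1e-13)
        with pytest.raises(ValueError):
            TissueState(V=float("nan"), n_cpa=0.0, n_is=1e-13)


class TestSimulateLoading:
    def test_constant_boundary_converges_to_bvh_volume(self, geom, mem, tox, settings):
        # long perfusion with CPA-free carrier: V -> (M_iso/M) V0 within 0.1%
        proto = build_protocol(0.0, 0.0, 0.0, flush_duration=300.0,
                               full_strength_duration=0.0, carrier_osmolarity=330.0)
        sim = simulate_loading(proto, geom, mem, tox, settings)
        assert sim.v_frac[-1] == pytest.approx(290.0 / 330.0, rel=1e-3)
        assert sim.C_tissue_M[-1] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("solute_update", ["concentration", "moles"])
    def test_equilibrium_with_cpa_boundary(self, geom, mem, tox, solute_update):
        # constant 1 M arterial CPA: C_t -> C_f and V -> n_is/C_is,f
        s = SimSettings(solute_update=solute_update)
        proto = build_protocol(1000.0, 1.0, 600.0, flush_duration=30.0,
                               full_strength_duration=0.0)
        sim = simulate_loading(proto, geom, mem, tox, s)
        assert sim.C_tissue_M[-1] == pytest.approx(1.0, rel=1e-3)
        assert sim.v_frac[-1] == pytest.approx(290.0 / 330.0, rel=1e-3)

    def test_toxicity_accumulation_monotone_and_gated(self, geom, mem, tox, settings):
        sim = simulate_loading(existing_protocol(), geom, mem, tox, settings)
        assert np.all(np.diff(sim.J_tox_cum) >= -1e-15)
        flush = sim.time_min < 20.0
        assert np.all(sim.J_tox_cum[flush] == 0.0)
        assert sim.J_tox > 0

    def test_resistance_consistent_with_volume(self, geom, mem, tox, settings):
        sim = simulate_loading(existing_protocol(), geom, mem, tox, settings)
        expected = (geom.r_c0 / capillary_radius(sim.V, geom)) ** 4
        np.testing.assert_allclose(sim.R_norm, expected, rtol=1e-12)

    def test_output_grid_independence(self, geom, mem, tox):
        coarse = simulate_loading(existing_protocol(), geom, mem, tox,
                                  SimSettings(output_dt=2.0))
        fine = simulate_loading(existing_protocol(), geom, mem, tox,
                                SimSettings(output_dt=1.0))
        assert fine.final_C_tissue_M == pytest.approx(
            coarse.final_C_tissue_M, rel=1e-4
        )
        assert fine.J_tox == pytest.approx(coarse.J_tox, rel=1e-4)

    def test_baseline_resistance_is_unity(self, geom, mem, tox, settings):
        sim = simulate_loading(existing_protocol(), geom, mem, tox, settings)
        assert sim.Rp_norm[sim.baseline_index] == pytest.approx(1.0, rel=1e-9)
        assert sim.R_norm[0] == pytest.approx(1.0, rel=1e-9)

    def test_auto_hold_requires_target(self, geom, mem, tox, settings):
        with pytest.raises(ValueError, match="target"):
            simulate_loading(build_protocol(62.0, 80.0, 5.0), geom, mem, tox, settings)

    def test_export_columns(self, geom, mem, tox, settings, tmp_path):
        sim = simulate_loading(existing_protocol(), geom, mem, tox, settings)
        out = tmp_path / "run.csv"
        sim.to_csv(out)
        header = out.read_text().splitlines()[0]
        assert header == "time_min,C_art_M,V_frac,C_tissue_M,rc_um,R_norm,Rp_norm,Jtox_cum"
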