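"""Pennes bioheat solver: analytic limits, linearity, transients, summaries."""

import dataclasses

import numpy as np
import pytest

import tnirsim as t
from tnirsim.errors import DomainError, GeometryError, SolverError
from tnirsim.phantom import TISSUE_CODES

BRAIN_EQUILIBRIUM = 37.0 + 10437.0 / (1050.0 * 0.08 * 3600.0)  # 37.0345 °C


def _uniform(props, **replacements):
    """Copy per-cell property fields with some replaced by constants."""
    updates = {}
    for name, value in replacements.items():
        current = getattr(props, name)
        updates[name] = (
            np.full_like(current, value) if isinstance(current, np.ndarray) else value
        )
    return dataclasses.replace(props, **updates)


class TestHeatSource:
    def test_pointwise_product(self):
        mu_a = np.array([[2.0, 0.0], [1.0, 3.0]])
        phi = np.array([[3.0, 5.0], [0.0, 2.0]])
        assert np.array_equal(t.heat_source(mu_a, phi),
                              np.array([[6.0, 0.0], [0.0, 6.0]]))

    def test_zero_fluence_gives_zero(self, coarse_props_810, coarse_phantom):
        phi = np.zeros(coarse_phantom.shape)
        assert np.all(t.heat_source(coarse_props_810.mu_a, phi) == 0.0)

    def test_shape_mismatch_raises(self):
        with pytest.raises(GeometryError):
            t.heat_source(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_total_deposited_power_conserves_energy(
        self, coarse_phantom, coarse_props_810, coarse_field_810
    ):
        """Integrated Q_r plus boundary escape equals the injected power."""
        Qr = t.heat_source(coarse_props_810.mu_a, coarse_field_810)
        vol = coarse_phantom.cell_volumes()
        deposited = (Qr * vol).sum()
        escaped = t.energy_balance(coarse_field_810)["escaped"]
        assert deposited + escaped == pytest.approx(0.5, rel=1e-2)


class TestSteadyState:
    def test_isothermal_equilibrium(self, gm_slab):
        """No metabolic or optical heat, no surface loss: T = T_a everywhere."""
        props = _uniform(t.assign_properties(gm_slab, 810), q_met=0.0)
        field = t.solve_steady_bioheat(
            gm_slab, props, None, t.SurfaceBoundary(h=0.0)
        )
        assert np.allclose(field.values, props.T_a, atol=1e-9)

    def test_perfusion_metabolic_equilibrium_deep_tissue(self, gm_slab):
        """Far from the cooled surface, perfused brain settles at
        T_a + Q_met / (rho_b omega_b c_b) = 37.0345 °C."""
        props = t.assign_properties(gm_slab, 810)
        field = t.solve_steady_bioheat(gm_slab, props, None)
        deep = gm_slab.z_centers() > 50e-3
        assert np.allclose(field.values[deep], BRAIN_EQUILIBRIUM, atol=1e-3)

    def test_zero_conduction_limit(self, gm_slab):
        """With K -> 0 and no surface loss, every perfused cell satisfies
        T = T_a + (Q_met + Q_r) / (rho_b omega_b c_b) exactly."""
        props = _uniform(t.assign_properties(gm_slab, 810), K=1e-12)
        Qr = np.linspace(0.0, 5000.0, gm_slab.shape[0])
        field = t.solve_steady_bioheat(gm_slab, props, Qr, t.SurfaceBoundary(h=0.0))
        sink = props.rho_b * props.c_b * props.omega_b
        expected = props.T_a + (props.q_met + Qr) / sink
        assert np.allclose(field.values, expected, rtol=1e-9)

    def test_rise_linear_in_source_power(self, coarse_phantom, coarse_props_810,
                                         coupled_run_810):
        _, temps = coupled_run_810
        fld_half = t.solve_diffusion(
            coarse_phantom, coarse_props_810, t.SourceSpec(irradiance=2500.0)
        )
        Qr_half = t.heat_source(coarse_props_810.mu_a, fld_half)
        temps_half = t.solve_steady_bioheat(coarse_phantom, coarse_props_810, Qr_half)
        assert np.allclose(temps_half.rise, 0.5 * temps.rise, rtol=1e-9,
                           atol=1e-12)

    def test_rise_nonnegative_and_decaying_beyond_peak(self, coupled_run_810,
                                                       coarse_phantom):
        _, temps = coupled_run_810
        assert np.all(temps.rise >= -1e-12)
        axis_rise = temps.rise[coarse_phantom.axis_index()]
        peak = int(np.argmax(axis_rise))
        assert np.all(np.diff(axis_rise[peak:]) <= 1e-12)

    def test_singular_without_perfusion_or_convection(self, gm_slab):
        props = _uniform(t.assign_properties(gm_slab, 810), omega_b=0.0)
        with pytest.raises(SolverError):
            t.solve_steady_bioheat(gm_slab, props, None, t.SurfaceBoundary(h=0.0))

    def test_gm_rise_ordering_follows_gm_absorbed_power(self, coarse_phantom):
        """With the heat source restricted to gray matter, the volume-mean
        gray-matter rise orders across wavelengths like the power absorbed
        there — the perfusion sink makes mean rise proportional to deposited
        power.  (The *peak* rise tracks heat concentration, and in the full
        coupled run the gray-matter maximum tracks heat conducted down from
        the scalp, which absorbs most at 630 nm.)"""
        gm = coarse_phantom.labels == TISSUE_CODES["gray_matter"]
        vol = coarse_phantom.cell_volumes()
        absorbed, rise = {}, {}
        for wl in t.WAVELENGTHS:
            props = t.assign_properties(coarse_phantom, wl)
            fld = t.solve_diffusion(coarse_phantom, props)
            Qr = t.heat_source(props.mu_a, fld) * gm
            absorbed[wl] = float((Qr * vol).sum())
            temps = t.solve_steady_bioheat(coarse_phantom, props, Qr)
            rise[wl] = float(np.average(temps.rise[gm], weights=vol[gm]))
        assert absorbed[810] == max(absorbed.values())  # NIR deposits most in GM
        power_order = sorted(t.WAVELENGTHS, key=absorbed.get)
        rise_order = sorted(t.WAVELENGTHS, key=rise.get)
        assert power_order == rise_order


class TestTransient:
    def test_steady_state_is_a_fixed_point(self, coarse_phantom, coarse_props_810,
                                           coupled_run_810):
        fld, temps = coupled_run_810
        Qr = t.heat_source(coarse_props_810.mu_a, fld)
        tr = t.solve_transient_bioheat(
            coarse_phantom, coarse_props_810, Qr, t_end=20.0, dt=2.0,
            T0=temps.values,
        )
        assert np.abs(tr.final - temps.values).max() < 1e-9

    def test_long_horizon_reaches_steady_state(self, coarse_props_810):
        """Implicit march from the baseline converges to the steady solution
        within 1e-3 °C."""
        ph = t.build_phantom(grid_kind="slab_1d", spacing=1e-3, total_depth=40e-3)
        props = t.assign_properties(ph, 810)
        fld = t.solve_diffusion(ph, props)
        Qr = t.heat_source(props.mu_a, fld)
        steady = t.solve_steady_bioheat(ph, props, Qr)
        tr = t.solve_transient_bioheat(ph, props, Qr, t_end=20000.0, dt=20.0,
                                       store_every=100)
        assert np.abs(tr.final - steady.values).max() < 1e-3
        # and the march is monotone toward steady at a probe cell
        errs = np.abs(tr.values[:, 5] - steady.values[5])
        assert errs[-1] <= errs[0]

    def test_uniform_perturbation_relaxes_at_perfusion_rate(self, gm_slab):
        """In a homogeneous perfused medium with no surface loss, a uniform
        offset decays exponentially at rho_b omega_b c_b / (rho c)."""
        props = t.assign_properties(gm_slab, 810)
        steady = t.solve_steady_bioheat(gm_slab, props, None,
                                        t.SurfaceBoundary(h=0.0))
        dt = 0.25
        tr = t.solve_transient_bioheat(
            gm_slab, props, None, t.SurfaceBoundary(h=0.0),
            t_end=10.0, dt=dt, T0=steady.values + 1.0,
        )
        offs = tr.values[:, 10] - steady.values[10]
        k = np.log(offs[1] / offs[9]) / (tr.times[9] - tr.times[1])
        expected = 1050.0 * 0.08 * 3600.0 / (1040.0 * 3630.0)
        # implicit Euler underestimates the rate by ~ k*dt/2
        assert k == pytest.approx(expected, rel=0.02)

    def test_invalid_time_step_rejected(self, gm_slab):
        props = t.assign_properties(gm_slab, 810)
        with pytest.raises(DomainError):
            t.solve_transient_bioheat(gm_slab, props, None, dt=-1.0)


class TestSummary:
    def test_zero_source_rise_is_zero(self, coarse_phantom, coarse_props_810):
        temps = t.solve_steady_bioheat(coarse_phantom, coarse_props_810, None)
        summary = t.temperature_rise_summary(temps)
        assert summary["max_dT"] == 0.0
        for stats in summary["per_tissue"].values():
            assert stats["max_dT"] == 0.0
            assert stats["mean_dT"] == 0.0

    def test_summary_covers_all_tissues_and_axis(self, coupled_run_810):
        _, temps = coupled_run_810
        summary = t.temperature_rise_summary(temps)
        assert set(summary["per_tissue"]) == set(t.TISSUES)
        prof = summary["axis_profile"]
        assert len(prof["depth_m"]) == len(prof["T_C"]) == len(prof["dT_C"])
        assert summary["surface_max_dT"] <= summary["max_dT"]

    def test_white_matter_average_near_perfusion_equilibrium(self, coupled_run_810):
        _, temps = coupled_run_810
        summary = t.temperature_rise_summary(temps)
        wm_avg = summary["per_tissue"]["white_matter"]["volume_avg_T"]
        assert wm_avg == pytest.approx(BRAIN_EQUILIBRIUM, abs=0.01)


def test_strict_thermal_mode_warns_and_keeps_printed_densities(coarse_phantom):
    with pytest.warns(UserWarning, match="printed densities"):
        props = t.assign_properties(coarse_phantom, 810, strict_thermal=True)
    csf = coarse_phantom.labels == TISSUE_CODES["csf"]
    gm = coarse_phantom.labels == TISSUE_CODES["gray_matter"]
    assert np.all(props.rho[csf] == 0.0)
    assert np.all(props.rho[gm] == 0.08)
    # steady solve is independent of density; it still works in strict mode
    field = t.solve_steady_bioheat(coarse_phantom, props, None)
    assert np.all(np.isfinite(field.values))
    # transients are rejected (densities unusable)
    with pytest.raises(SolverError):
        t.solve_transient_bioheat(coarse_phantom, props, None, t_end=1.0, dt=1.0)
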