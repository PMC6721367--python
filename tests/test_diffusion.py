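"""Diffusion solver: analytic oracles, conservation, and profile extraction."""

import numpy as np
import pytest

import tnirsim as t
from tnirsim.errors import ConfigurationError, GeometryError
from tnirsim.phantom import TISSUE_CODES

from conftest import axis_distance

GM = dict(mu_a=57.09, mu_s_prime=746.0)


def test_zero_power_source_gives_zero_field(coarse_phantom, coarse_props_810):
    src = t.SourceSpec(irradiance=0.0)
    fld = t.solve_diffusion(coarse_phantom, coarse_props_810, src)
    assert np.all(fld.values == 0.0)


def test_doubling_power_doubles_fluence(coarse_phantom, coarse_props_810,
                                        coarse_field_810):
    fld2 = t.solve_diffusion(
        coarse_phantom, coarse_props_810, t.SourceSpec(irradiance=10000.0)
    )
    assert np.allclose(fld2.values, 2.0 * coarse_field_810.values, rtol=1e-12)


def test_fluence_nonnegative_everywhere(coarse_field_810, default_phantom):
    assert np.all(coarse_field_810.values >= 0.0)
    props = t.assign_properties(default_phantom, 810)
    fld = t.solve_diffusion(default_phantom, props)
    assert np.all(fld.values >= 0.0)
    assert np.all(np.isfinite(fld.values))


def test_matches_infinite_medium_greens_function():
    """A buried point source in homogeneous gray matter follows
    P exp(-mu_eff r) / (4 pi D r) within 2% between one transport mean free
    path and 10/mu_eff."""
    h = 0.2e-3
    ph = t.build_phantom(
        layers=[t.LayerSpec("gray_matter", None)],
        grid_kind="axisymmetric_2d",
        spacing=h,
        lateral_extent=40e-3,
        total_depth=70e-3,
    )
    props = t.assign_properties(ph, 810)
    src = t.SourceSpec()
    z_src = 35e-3
    fld = t.solve_diffusion(ph, props, src, burial_depth=z_src)
    D = t.diffusion_coefficient(**GM)
    mu_eff = t.effective_attenuation(**GM)
    dist = axis_distance(ph, z_src)
    green = src.total_power * np.exp(-mu_eff * dist) / (4 * np.pi * D * dist)
    dz = np.abs(ph.z_centers() - z_src)
    sel = (dz >= 1.0 / GM["mu_s_prime"]) & (dz <= 10.0 / mu_eff)
    rel = np.abs(fld.values[0][sel] / green[sel] - 1.0)
    assert rel.max() < 0.02


def test_energy_balance_closes(coarse_field_810, default_phantom):
    """Absorbed power plus boundary escape equals injected power."""
    bal = t.energy_balance(coarse_field_810)
    assert bal["injected"] == pytest.approx(0.5)
    assert bal["closure"] == pytest.approx(1.0, abs=1e-2)
    props = t.assign_properties(default_phantom, 810)
    fine = t.solve_diffusion(default_phantom, props)
    assert t.energy_balance(fine)["closure"] == pytest.approx(1.0, abs=1e-3)


def test_slab_log_fluence_slope_is_minus_mu_eff(gm_slab):
    """In a homogeneous slab the interior fluence decays as exp(-mu_eff z)."""
    props = t.assign_properties(gm_slab, 810)
    fld = t.solve_diffusion(gm_slab, props)
    z = gm_slab.z_centers()
    sel = (z > 5e-3) & (z < 40e-3)
    slope = np.polyfit(z[sel], np.log(fld.values[sel]), 1)[0]
    assert slope == pytest.approx(-t.effective_attenuation(**GM), rel=0.05)


def test_grid_convergence_beyond_transport_mfp():
    """Fluence changes < 2% between spacings h and h/2 in the diffusive
    region: sampled at matched physical points a couple of transport mean
    free paths below the source, away from layer-interface kinks (where
    linear interpolation across the mu_a jump dominates the comparison)."""
    from scipy.interpolate import RegularGridInterpolator

    fields = {}
    for h in (0.5e-3, 0.25e-3):
        ph = t.build_phantom(spacing=h, lateral_extent=30e-3, total_depth=40e-3)
        props = t.assign_properties(ph, 810)
        fields[h] = (ph, t.solve_diffusion(ph, props))

    def at(ph, fld, pts):
        r = (np.arange(ph.shape[0]) + 0.5) * ph.spacing
        return RegularGridInterpolator((r, ph.z_centers()), fld.values)(pts)

    probe_z = np.arange(4e-3, 34e-3, 0.5e-3)
    keep = np.ones_like(probe_z, dtype=bool)
    for iface in (13e-3, 20e-3, 24e-3):
        keep &= np.abs(probe_z - iface) > 1e-3
    probe_z = probe_z[keep]
    pts = np.c_[np.full_like(probe_z, 0.5e-3), probe_z]
    rel = at(*fields[0.25e-3], pts) / at(*fields[0.5e-3], pts) - 1.0
    assert np.max(np.abs(rel)) < 0.02


class TestFractionProfile:
    def test_reference_is_one_at_surface(self, coarse_field_810):
        """Fraction is 1 at the entry cell and in (0, 1] below the buried
        source (cells between the surface and the burial depth can exceed 1
        because the regularized source sits one transport mfp deep)."""
        prof = t.fluence_fraction_profile(coarse_field_810)
        assert prof.values[0] == pytest.approx(1.0)
        assert np.all(prof.values > 0.0)
        below_source = prof.depths > 2.0 / 760.0
        assert np.all(prof.values[below_source] <= 1.0)
        # monotone decay below the source
        assert np.all(np.diff(prof.values[below_source]) <= 0.0)

    def test_gray_matter_fraction_order_of_magnitude(self, default_phantom):
        """~0.2% of the entry fluence reaches the gray-matter interface."""
        props = t.assign_properties(default_phantom, 810)
        fld = t.solve_diffusion(default_phantom, props)
        prof = t.fluence_fraction_profile(fld)
        frac = np.interp(20e-3, prof.depths, prof.values)
        assert 0.0005 < frac < 0.01

    def test_labels_follow_layer_order(self, coarse_field_810):
        prof = t.fluence_fraction_profile(coarse_field_810)
        names = list(dict.fromkeys(prof.domain_labels))
        assert names == ["scalp_skull", "csf", "gray_matter", "white_matter"]

    def test_single_layer_phantom_rejected(self, gm_slab):
        props = t.assign_properties(gm_slab, 810)
        fld = t.solve_diffusion(gm_slab, props)
        with pytest.raises(GeometryError):
            t.fluence_fraction_profile(fld)


def test_penetration_orders_with_wavelength(coarse_phantom):
    """Fraction reaching the gray matter: 810 nm > 700 nm > 630 nm."""
    frac = {}
    for wl in t.WAVELENGTHS:
        props = t.assign_properties(coarse_phantom, wl)
        prof = t.fluence_fraction_profile(t.solve_diffusion(coarse_phantom, props))
        frac[wl] = np.interp(20e-3, prof.depths, prof.values)
    assert frac[810] > frac[700] > frac[630]


class TestPerChromophore:
    def test_single_chromophore_field_dominates_whole_tissue(
        self, coarse_phantom, coarse_field_810
    ):
        """Less absorption (one chromophore instead of all six) means more
        fluence everywhere in the brain layers."""
        fld = t.per_chromophore_run(coarse_phantom, 810, "water")
        brain = coarse_phantom.labels >= TISSUE_CODES["gray_matter"]
        assert np.all(fld.values[brain] >= coarse_field_810.values[brain])

    def test_deoxyhemoglobin_attenuates_more_than_reduced_cco_at_630(
        self, coarse_phantom
    ):
        deoxy = t.per_chromophore_run(coarse_phantom, 630, "deoxyhemoglobin")
        red = t.per_chromophore_run(coarse_phantom, 630, "reduced_cco")
        gm = coarse_phantom.labels == TISSUE_CODES["gray_matter"]
        assert np.all(deoxy.values[gm] <= red.values[gm])

    def test_chromophore_mu_a_maps_sum_to_whole_tissue(self, coarse_phantom, tables):
        """Summing the six single-chromophore mu_a maps recovers the
        whole-tissue map in the brain layers (up to printed rounding)."""
        whole = t.assign_properties(coarse_phantom, 810).mu_a
        total = np.zeros_like(whole)
        for name in t.CHROMOPHORES:
            per = tables.chromophore_mu_a_map(810)
            ov = {
                "gray_matter": {"mu_a": per["gray_matter"][name]},
                "white_matter": {"mu_a": per["white_matter"][name]},
            }
            total += t.assign_properties(coarse_phantom, 810, overrides=ov).mu_a
        brain = coarse_phantom.labels >= TISSUE_CODES["gray_matter"]
        assert np.allclose(total[brain], whole[brain], atol=0.05)

    def test_unknown_chromophore_raises(self, coarse_phantom):
        with pytest.raises(ConfigurationError):
            t.per_chromophore_run(coarse_phantom, 810, "melanin")


class TestExtractCutline:
    def test_constant_field_gives_constant_profile(self, coarse_phantom):
        vals = np.full(coarse_phantom.shape, 7.5)
        prof = t.extract_cutline(
            vals, start=(2e-3, 1e-3), direction=(0.0, 1.0), step=1e-3,
            phantom=coarse_phantom,
        )
        assert np.allclose(prof.values, 7.5)

    def test_linear_field_interpolated_exactly(self, coarse_phantom):
        r = (np.arange(coarse_phantom.shape[0]) + 0.5) * coarse_phantom.spacing
        z = coarse_phantom.z_centers()
        vals = 3.0 * r[:, None] + 2.0 * z[None, :] + 1.0
        prof = t.extract_cutline(
            vals, start=(5e-3, 1e-3), direction=(1.0, 2.0), step=0.7e-3,
            phantom=coarse_phantom,
        )
        # r along the line: r = 5e-3 + (z - 1e-3) / 2
        r_line = 5e-3 + (prof.depths - 1e-3) / 2.0
        assert np.allclose(prof.values, 3.0 * r_line + 2.0 * prof.depths + 1.0,
                           rtol=1e-12, atol=1e-12)

    def test_degenerate_direction_raises(self, coarse_field_810):
        with pytest.raises(GeometryError):
            t.extract_cutline(coarse_field_810, (0.0, 0.0), (0.0, 0.0), 1e-3)

    def test_line_outside_grid_raises(self, coarse_field_810):
        with pytest.raises(GeometryError):
            t.extract_cutline(coarse_field_810, (1.0, 1.0), (0.0, 1.0), 1e-3)

    def test_default_cutline_crosses_all_layers(self, coarse_field_810):
        prof = t.extract_cutline(
            coarse_field_810, start=(0.5e-3, 0.5e-3), direction=(0.0, 1.0),
            step=0.5e-3,
        )
        names = list(dict.fromkeys(prof.domain_labels))
        assert names == ["scalp_skull", "csf", "gray_matter", "white_matter"]


def test_disc_source_spreads_power(coarse_phantom, coarse_props_810):
    disc = t.solve_diffusion(
        coarse_phantom, coarse_props_810, t.SourceSpec(kind="disc")
    )
    point = t.solve_diffusion(
        coarse_phantom, coarse_props_810, t.SourceSpec(kind="point")
    )
    # same injected power, lower peak when spread over the aperture
    assert t.energy_balance(disc)["injected"] == pytest.approx(0.5)
    assert disc.values.max() < point.values.max()
    assert t.energy_balance(disc)["closure"] == pytest.approx(1.0, abs=1e-2)
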