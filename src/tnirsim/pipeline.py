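"""End-to-end experiment orchestration.

Runs the study protocol on a phantom: whole-tissue diffusion at each
wavelength, optional per-chromophore runs (brain absorption from a single
chromophore, scattering unchanged), the coupled bioheat run, and a Monte
Carlo cross-check — and writes CSV/JSON (optionally VTK) artifacts plus a
machine-readable report.

Outputs are deterministic for a fixed config and seed (no timestamps; the
Monte Carlo generator is seeded from the config seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .bioheat import (
    SurfaceBoundary,
    heat_source,
    solve_steady_bioheat,
    temperature_rise_summary,
)
from .diffusion import (
    FluenceField,
    SourceSpec,
    energy_balance,
    fluence_fraction_profile,
    per_chromophore_run,
    solve_diffusion,
)
from .errors import ConfigurationError
from .montecarlo import MCConfig, radial_mean_profile, run_mc
from .phantom import LayerSpec, assign_properties, build_phantom
from .tables import CHROMOPHORES, load_reference_tables
from .vtkio import write_cutline_csv, write_vtk

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "rank_chromophore_attenuation"]

MODES = ("whole_tissue", "per_chromophore", "thermal", "mc_compare")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one experiment run."""

    wavelengths: tuple = (630, 700, 810)
    modes: tuple = ("whole_tissue",)
    irradiance: float = 5000.0          # W/m² (5000 = 500 mW/cm²)
    aperture_area: float = 1e-4         # m²
    source_kind: str = "point"
    layer_thicknesses: tuple = (13e-3, 7e-3, 4e-3)  # scalp_skull, csf, gray
    spacing: float = 0.5e-3
    lateral_extent: float = 50e-3
    total_depth: float = 60e-3
    chromophores: tuple = CHROMOPHORES
    h_convective: float = 4.0
    T_ambient: float = 25.0
    mc_photons: int = 200_000
    mc_spacing: float = 1e-3
    seed: int = 0
    outdir: str | None = None
    write_vtk: bool = False

    def __post_init__(self) -> None:
        if len(self.wavelengths) == 0:
            raise ConfigurationError("at least one wavelength is required")
        if len(self.modes) == 0:
            raise ConfigurationError("at least one mode is required")
        for m in self.modes:
            if m not in MODES:
                raise ConfigurationError(f"unknown mode {m!r}")
        if len(self.chromophores) == 0 and "per_chromophore" in self.modes:
            raise ConfigurationError("per_chromophore mode needs chromophores")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("wavelengths", "modes", "layer_thicknesses", "chromophores"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def content_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = asdict(self)
        payload.pop("outdir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def layers(self) -> list[LayerSpec]:
        t = self.layer_thicknesses
        return [
            LayerSpec("scalp_skull", t[0]),
            LayerSpec("csf", t[1]),
            LayerSpec("gray_matter", t[2]),
            LayerSpec("white_matter", None),
        ]

    def source(self) -> SourceSpec:
        return SourceSpec(kind=self.source_kind, irradiance=self.irradiance,
                          aperture_area=self.aperture_area)


@dataclass
class ExperimentReport:
    """Machine-readable summary of an experiment run."""

    config_hash: str
    seed: int
    version: str
    per_wavelength: dict = field(default_factory=dict)
    chromophore_rankings: dict = field(default_factory=dict)
    mc_compare: dict = field(default_factory=dict)
    artifacts: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "per_wavelength": self.per_wavelength,
            "chromophore_rankings": self.chromophore_rankings,
            "mc_compare": self.mc_compare,
            "artifacts": self.artifacts,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))


def rank_chromophore_attenuation(
    fields: Mapping[str, FluenceField], depth: float
) -> list[str]:
    """Rank chromophores by attenuation at ``depth`` on the source axis.

    Lower fluence at the probe depth means the chromophore removed more light
    on the way down, i.e. it is the stronger attenuator; the returned list is
    ordered strongest first.  Ties are broken by the tabulated gray-matter
    ``mu_a`` (descending), then by name.
    """
    if len(fields) < 1:
        raise ConfigurationError("need at least one chromophore field to rank")
    wavelengths = {f.wavelength for f in fields.values()}
    if len(wavelengths) != 1:
        raise ConfigurationError(
            f"all fields must share one wavelength (got {sorted(wavelengths)})"
        )
    wl = wavelengths.pop()
    tab = load_reference_tables()
    gm_mu_a = tab.chromophore_mu_a_map(wl)["gray_matter"]

    def key(item):
        name, fld = item
        z = fld.phantom.z_centers()
        phi = np.interp(depth, z, fld.axis_profile())
        return (phi, -gm_mu_a.get(name, 0.0), name)

    return [name for name, _ in sorted(fields.items(), key=key)]


def _fraction_at(profile, depth: float) -> float:
    return float(np.interp(depth, profile.depths, profile.values))


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the configured experiment stages and collect a report."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    phantom = build_phantom(
        layers=config.layers(),
        grid_kind="axisymmetric_2d",
        spacing=config.spacing,
        lateral_extent=config.lateral_extent,
        total_depth=config.total_depth,
    )
    source = config.source()
    boundary = SurfaceBoundary(h=config.h_convective, T_ambient=config.T_ambient)
    z_gm = phantom.gray_matter_interface_depth()
    report = ExperimentReport(
        config_hash=config.content_hash(), seed=config.seed, version=_pkg_version
    )

    def _artifact(name: str):
        if outdir is None:
            return None
        report.artifacts.append(name)  # relative to outdir, for determinism
        return outdir / name

    for wl in config.wavelengths:
        wl_report: dict = {}
        props = assign_properties(phantom, wl)
        fld = solve_diffusion(phantom, props, source)
        frac = fluence_fraction_profile(fld)
        bal = energy_balance(fld)
        wl_report["gray_matter_fluence_fraction"] = _fraction_at(frac, z_gm)
        wl_report["energy_closure"] = bal["closure"]
        if (p := _artifact(f"fluence_cutline_{wl}nm.csv")) is not None:
            phi_axis = fld.axis_profile()
            write_cutline_csv(
                p, frac, value_name="fraction",
                extra={
                    "fluence_W_per_m2": phi_axis,
                    "log_fluence": np.log(np.maximum(phi_axis, 1e-300)),
                },
            )
        if config.write_vtk and (p := _artifact(f"fluence_{wl}nm.vtk")) is not None:
            write_vtk(p, phantom, {"fluence": fld.values,
                                   "tissue": phantom.labels.astype(float)})

        if "thermal" in config.modes:
            Qr = heat_source(props.mu_a, fld)
            temps = solve_steady_bioheat(phantom, props, Qr, boundary)
            summary = temperature_rise_summary(temps)
            axis = summary.pop("axis_profile")
            wl_report["thermal"] = summary
            if (p := _artifact(f"temperature_cutline_{wl}nm.csv")) is not None:
                import pandas as pd

                pd.DataFrame(axis).to_csv(p, index=False)
            if config.write_vtk and (p := _artifact(f"temperature_{wl}nm.vtk")) is not None:
                write_vtk(p, phantom, {"T": temps.values, "dT": temps.rise})

        if "per_chromophore" in config.modes:
            fields = {}
            per_chromo: dict = {}
            for name in config.chromophores:
                cf = per_chromophore_run(phantom, wl, name, source)
                fields[name] = cf
                prof = fluence_fraction_profile(cf)
                per_chromo[name] = {
                    "gray_matter_fluence_fraction": _fraction_at(prof, z_gm),
                }
                if (p := _artifact(f"chromophore_{name}_{wl}nm.csv")) is not None:
                    write_cutline_csv(p, prof, value_name="fraction")
            ranking = rank_chromophore_attenuation(fields, z_gm)
            report.chromophore_rankings[str(wl)] = ranking
            wl_report["per_chromophore"] = per_chromo

        if "mc_compare" in config.modes:
            wl_report["mc_compare"] = _mc_compare_stage(
                config, wl, source, report, _artifact
            )

        report.per_wavelength[str(wl)] = wl_report

    if outdir is not None:
        report.save(outdir / "report.json")
        (outdir / "config.yaml").write_text(
            yaml.safe_dump(asdict(config), sort_keys=True)
        )
    return report


def _mc_compare_stage(config: ExperimentConfig, wl: float, source: SourceSpec,
                      report: ExperimentReport, _artifact) -> dict:
    """Diffusion vs Monte Carlo on a voxel grid; relative error per depth bin."""
    import pandas as pd

    vox = build_phantom(
        layers=config.layers(),
        grid_kind="voxel_3d",
        spacing=config.mc_spacing,
        lateral_extent=min(config.lateral_extent, 25e-3),
        total_depth=min(config.total_depth, 40e-3),
    )
    props = assign_properties(vox, wl)
    mc = run_mc(vox, props, source,
                MCConfig(n_photons=config.mc_photons, seed=config.seed))
    diff = solve_diffusion(vox, props, source)
    z = vox.z_centers()
    avg_radius = 4e-3  # lateral averaging suppresses voxel tally noise
    phi_mc = radial_mean_profile(mc.fluence, vox, avg_radius)
    phi_diff = radial_mean_profile(diff.values, vox, avg_radius)
    ok = phi_mc > 0
    rel = np.where(ok, (phi_diff - phi_mc) / np.where(ok, phi_mc, 1.0), np.nan)
    df = pd.DataFrame({
        "depth_m": z,
        "tissue": vox.tissue_names(vox.axis_labels()),
        "fluence_mc_W_per_m2": phi_mc,
        "fluence_diffusion_W_per_m2": phi_diff,
        "relative_difference": rel,
    })
    if (p := _artifact(f"mc_compare_{wl}nm.csv")) is not None:
        df.to_csv(p, index=False)
    per_tissue = {
        t: float(np.nanmedian(np.abs(sub.relative_difference)))
        for t, sub in df.groupby("tissue")
        if sub.relative_difference.notna().any()
    }
    return {
        "absorbed_fraction": mc.absorbed_fraction,
        "reflected_fraction": mc.reflected_fraction,
        "median_abs_relative_difference_by_tissue": per_tissue,
    }
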