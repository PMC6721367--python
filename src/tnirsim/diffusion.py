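"""Steady-state diffusion approximation of photon transport in layered tissue.

Solves ``-div(D grad phi) + mu_a phi = Q0`` for the fluence rate ``phi``
(W/m²) on a phantom grid, with the partial-current Robin closure
``phi + 2D dphi/dn = 0`` on tissue–air boundaries (index matched; surface
reflection is not modeled).  A surface "point" source of total power P is
regularized the standard way: an isotropic source buried one transport mean
free path ``1/mu_s'`` below the entry point, apportioned linearly between the
two nearest cell planes so the injection depth does not snap to the grid.

For ``slab_1d`` phantoms the solution is per unit surface area: the source
is planar and the injected power equals the irradiance (W/m²).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from . import _fv
from .errors import ConfigurationError, DomainError, GeometryError
from .phantom import CellProperties, Phantom, assign_properties
from .tables import load_reference_tables

__all__ = [
    "SourceSpec",
    "FluenceField",
    "CutlineProfile",
    "solve_diffusion",
    "fluence_fraction_profile",
    "per_chromophore_run",
    "extract_cutline",
    "energy_balance",
]


@dataclass(frozen=True)
class SourceSpec:
    """Surface light source.

    ``irradiance`` (W/m²; 5000 = 500 mW/cm² default) times ``aperture_area``
    (m²) gives the total injected power.  ``position`` is the lateral surface
    coordinate of the beam center (ignored for slab and axisymmetric grids,
    where the source sits on the axis).
    """

    kind: str = "point"
    irradiance: float = 5000.0
    aperture_area: float = 1e-4
    position: tuple = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("point", "disc"):
            raise ConfigurationError(f"unknown source kind {self.kind!r}")
        if self.irradiance < 0 or self.aperture_area <= 0:
            raise DomainError("irradiance must be >= 0 and aperture_area > 0")

    @property
    def total_power(self) -> float:
        """Injected power, W."""
        return self.irradiance * self.aperture_area

    @property
    def radius(self) -> float:
        """Disc radius implied by the aperture area, m."""
        return float(np.sqrt(self.aperture_area / np.pi))


@dataclass(frozen=True)
class FluenceField:
    """Fluence rate per cell (W/m²) with its provenance."""

    values: np.ndarray
    phantom: Phantom
    source: SourceSpec
    wavelength: float
    props: CellProperties
    system: object = None  # FVSystem, kept for energy accounting

    def axis_profile(self) -> np.ndarray:
        """Fluence along the source axis, one value per depth cell."""
        return self.values[self.phantom.axis_index()]


@dataclass(frozen=True)
class CutlineProfile:
    """Field samples along a line through the phantom."""

    depths: np.ndarray
    values: np.ndarray
    domain_labels: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"depth_m": self.depths, "value": self.values,
             "tissue": self.domain_labels}
        )


def _entry_column(phantom: Phantom, source: SourceSpec) -> tuple:
    """Lateral index of the column containing the source entry point."""
    if phantom.grid_kind == "slab_1d":
        return ()
    if phantom.grid_kind == "axisymmetric_2d":
        return (0,)
    cx, cy = phantom.axis_index()
    ix = cx + int(round(source.position[0] / phantom.spacing))
    iy = cy + int(round(source.position[1] / phantom.spacing))
    if not (0 <= ix < phantom.shape[0] and 0 <= iy < phantom.shape[1]):
        raise GeometryError("source position lies outside the grid")
    return (ix, iy)


def _source_vector(phantom: Phantom, props: CellProperties,
                   source: SourceSpec,
                   burial_depth: float | None = None) -> np.ndarray:
    """Integrated source per cell, W (W/m² for slab grids)."""
    h = phantom.spacing
    col = _entry_column(phantom, source)
    surf_cell = col + (0,)
    if burial_depth is None:
        mu_sp = float(props.mu_s_prime[surf_cell])
        if mu_sp <= 0:
            raise DomainError(
                "surface tissue must scatter (mu_s' > 0) to bury the source"
            )
        z0 = 1.0 / mu_sp
    else:
        if not 0 <= burial_depth <= phantom.total_depth:
            raise GeometryError("burial depth outside the grid")
        z0 = float(burial_depth)

    nz = phantom.nz
    kf = z0 / h - 0.5
    k0 = max(int(np.floor(kf)), 0)
    k1 = min(k0 + 1, nz - 1)
    w = min(max(kf - k0, 0.0), 1.0)

    b = np.zeros(phantom.shape)
    power = source.total_power if phantom.grid_kind != "slab_1d" else source.irradiance

    if source.kind == "point" or phantom.grid_kind == "slab_1d":
        b[col + (k0,)] += power * (1.0 - w)
        b[col + (k1,)] += power * w
        return b

    # disc source: distribute over the beam footprint at depth z0
    radius = source.radius
    if phantom.grid_kind == "axisymmetric_2d":
        if radius > phantom.lateral_extent / 2:
            raise GeometryError(
                "disc source radius too large for the lateral extent"
            )
        rf = phantom.r_faces()
        overlap = np.pi * (
            np.minimum(rf[1:], radius) ** 2 - np.minimum(rf[:-1], radius) ** 2
        )
        weights = np.clip(overlap, 0.0, None)
    else:
        cx, cy = col
        x = (np.arange(phantom.shape[0]) - cx) * h
        y = (np.arange(phantom.shape[1]) - cy) * h
        inside = (x[:, None] ** 2 + y[None, :] ** 2) <= radius**2
        if not inside.any():
            inside[cx, cy] = True
        weights = inside.astype(float)
    weights = weights / weights.sum()
    if phantom.grid_kind == "axisymmetric_2d":
        b[:, k0] += power * (1.0 - w) * weights
        b[:, k1] += power * w * weights
    else:
        b[:, :, k0] += power * (1.0 - w) * weights
        b[:, :, k1] += power * w * weights
    return b


def _photon_boundaries(phantom: Phantom) -> dict:
    ndim = len(phantom.shape)
    return {(ax, side): ("photon",) for ax in range(ndim) for side in (0, 1)}


def solve_diffusion(phantom: Phantom, props: CellProperties,
                    source: SourceSpec | None = None,
                    burial_depth: float | None = None) -> FluenceField:
    """Solve the steady diffusion equation on the phantom.

    The source is injected at ``burial_depth`` below the entry point
    (default: one transport mean free path, ``1/mu_s'`` of the surface
    tissue; a deep value emulates an interior/infinite-medium source).
    Returns the fluence-rate field; the assembled system is retained on the
    field for energy accounting (:func:`energy_balance`).
    """
    source = source or SourceSpec()
    if props.mu_a.shape != phantom.shape:
        raise GeometryError("property arrays do not match the phantom grid")
    system = _fv.assemble(phantom, props.D, props.mu_a, _photon_boundaries(phantom))
    b = _source_vector(phantom, props, source, burial_depth)
    phi = system.solve(b)
    return FluenceField(values=phi, phantom=phantom, source=source,
                        wavelength=props.wavelength, props=props, system=system)


def energy_balance(field: FluenceField) -> dict:
    """Absorbed + escaped power versus injected power.

    Returns a dict with ``absorbed``, ``escaped``, ``injected`` (W) and
    ``closure`` = (absorbed + escaped) / injected.
    """
    phantom = field.phantom
    vol = phantom.cell_volumes()
    absorbed = float(np.sum(field.props.mu_a * field.values * vol))
    escaped = field.system.boundary_outflow(field.values)
    injected = (
        field.source.total_power
        if phantom.grid_kind != "slab_1d"
        else field.source.irradiance
    )
    return {
        "absorbed": absorbed,
        "escaped": escaped,
        "injected": injected,
        "closure": (absorbed + escaped) / injected if injected else np.nan,
    }


def fluence_fraction_profile(field: FluenceField) -> CutlineProfile:
    """Fluence along the source axis, normalized to the source entry cell.

    The reference is the surface cell of the entry column, so the profile is
    1.0 at depth zero and dimensionless below.
    """
    phantom = field.phantom
    if len(phantom.layers) < 2:
        raise GeometryError("fraction profile needs a phantom with >= 2 layers")
    col = _entry_column(phantom, field.source)
    values = field.values[col]
    ref = values[0]
    if ref <= 0:
        raise GeometryError("entry-cell fluence is zero; nothing to normalize to")
    labels = phantom.tissue_names(phantom.labels[col])
    return CutlineProfile(
        depths=phantom.z_centers(), values=values / ref, domain_labels=labels
    )


def per_chromophore_run(
    phantom: Phantom,
    wavelength: float,
    chromophore: str,
    source: SourceSpec | None = None,
) -> FluenceField:
    """Whole-head run with brain absorption from a single chromophore.

    Gray- and white-matter ``mu_a`` are replaced by the chromophore's tabulated
    contribution while their scattering — and the full optical properties of
    scalp/skull and CSF — stay at whole-tissue values, isolating the
    attenuation attributable to that chromophore.
    """
    tab = load_reference_tables()
    per = tab.chromophore_mu_a_map(wavelength)
    if chromophore not in per["gray_matter"]:
        raise ConfigurationError(f"chromophore {chromophore!r} not tabulated")
    overrides = {
        "gray_matter": {"mu_a": per["gray_matter"][chromophore]},
        "white_matter": {"mu_a": per["white_matter"][chromophore]},
    }
    props = assign_properties(phantom, wavelength, overrides=overrides)
    return solve_diffusion(phantom, props, source)


def extract_cutline(
    field: FluenceField | np.ndarray,
    start,
    direction,
    step: float,
    phantom: Phantom | None = None,
) -> CutlineProfile:
    """Sample a field along a straight line by linear interpolation.

    ``start`` and ``direction`` are grid coordinates: ``(z,)`` for slabs,
    ``(r, z)`` for axisymmetric grids, ``(x, y, z)`` for voxel grids (origin
    at the grid corner).  Sampling proceeds from ``start`` in uniform steps
    until the line leaves the cell-center lattice.  Linear fields are
    reproduced exactly at interior sample points.
    """
    if isinstance(field, FluenceField):
        values, phantom = field.values, field.phantom
    else:
        values = np.asarray(field)
        if phantom is None:
            raise GeometryError("phantom required when passing a bare array")
    direction = np.asarray(direction, dtype=float)
    start = np.asarray(start, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise GeometryError("degenerate (zero) direction vector")
    direction = direction / norm
    if start.shape != direction.shape or start.size != values.ndim:
        raise GeometryError("start/direction dimensionality must match the grid")

    h = phantom.spacing
    axes = [((np.arange(n) + 0.5) * h) for n in values.shape]
    lo = np.array([a[0] for a in axes])
    hi = np.array([a[-1] for a in axes])

    # walk until out of the lattice hull
    points = []
    t = 0.0
    max_t = float(np.linalg.norm(hi - lo)) + step
    while t <= max_t:
        p = start + t * direction
        if np.all(p >= lo - 1e-12) and np.all(p <= hi + 1e-12):
            points.append(p)
        elif points:
            break
        t += step
    if not points:
        raise GeometryError("cutline does not intersect the grid")
    pts = np.clip(np.asarray(points), lo, hi)

    interp = RegularGridInterpolator(axes, values, method="linear")
    sampled = interp(pts)
    z = pts[:, -1]
    kz = np.clip((z / h - 0.5).round().astype(int), 0, phantom.nz - 1)
    labels = phantom.tissue_names(phantom.axis_labels()[kz])
    return CutlineProfile(depths=z, values=sampled, domain_labels=labels)
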