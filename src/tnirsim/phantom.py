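"""Synthetic layered head phantoms.

Stand-in for a tetrahedral anatomical head mesh: a structured grid whose
cells are labeled by tissue layer, outermost first —
``scalp_skull -> csf -> gray_matter -> white_matter`` — with depth ``z``
increasing into the head from the surface at ``z = 0``.

Three grid kinds are supported:

- ``slab_1d``      — a 1-D stack of layers (unit cross-section, planar source);
- ``axisymmetric_2d`` — cylindrical (r, z) grid, the natural geometry for a
  source on the axis of a layered half-space (default for the pipeline);
- ``voxel_3d``     — Cartesian voxels, the geometry the Monte Carlo transport
  runs on.

Default layer thicknesses (scalp+skull 13 mm, CSF 7 mm, gray matter 4 mm,
white matter remainder) put the gray-matter interface at 20 mm depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import bioheat_params
from .chromophores import diffusion_coefficient
from .errors import ConfigurationError, DomainError, GeometryError, ResolutionError
from .tables import ANISOTROPY_G, TISSUES, load_reference_tables

__all__ = [
    "LayerSpec",
    "Phantom",
    "CellProperties",
    "default_layers",
    "build_phantom",
    "assign_properties",
]

TISSUE_CODES = {name: i for i, name in enumerate(TISSUES)}

GRID_KINDS = ("slab_1d", "axisymmetric_2d", "voxel_3d")

#: Depth axis position within the label array for each grid kind.
Z_AXIS = {"slab_1d": 0, "axisymmetric_2d": 1, "voxel_3d": 2}


@dataclass(frozen=True)
class LayerSpec:
    """One phantom layer: tissue label and thickness in meters.

    ``thickness=None`` marks the innermost layer as "remainder" (it fills the
    grid down to the bottom of the domain).
    """

    tissue_id: str
    thickness: float | None

    def __post_init__(self) -> None:
        if self.tissue_id not in TISSUE_CODES:
            raise ConfigurationError(f"unknown tissue {self.tissue_id!r}")
        if self.thickness is not None and self.thickness <= 0:
            raise DomainError(
                f"layer {self.tissue_id}: thickness must be positive "
                f"(got {self.thickness})"
            )


def default_layers() -> list[LayerSpec]:
    """Default stack: scalp+skull 13 mm, CSF 7 mm, gray 4 mm, white remainder."""
    return [
        LayerSpec("scalp_skull", 13e-3),
        LayerSpec("csf", 7e-3),
        LayerSpec("gray_matter", 4e-3),
        LayerSpec("white_matter", None),
    ]


@dataclass(frozen=True)
class Phantom:
    """Discretized layered phantom with per-cell tissue labels."""

    grid_kind: str
    spacing: float
    shape: tuple
    labels: np.ndarray  # int8 tissue codes, shape == self.shape
    layer_interfaces: tuple  # depths (m) of internal layer boundaries
    lateral_extent: float
    total_depth: float
    layers: tuple = ()

    @property
    def z_axis(self) -> int:
        return Z_AXIS[self.grid_kind]

    @property
    def nz(self) -> int:
        return self.shape[self.z_axis]

    def z_centers(self) -> np.ndarray:
        """Depth of cell centers below the surface, m."""
        return (np.arange(self.nz) + 0.5) * self.spacing

    def r_faces(self) -> np.ndarray:
        """Radial face positions (axisymmetric grids only)."""
        if self.grid_kind != "axisymmetric_2d":
            raise GeometryError("r_faces is defined for axisymmetric grids only")
        return np.arange(self.shape[0] + 1) * self.spacing

    def cell_volumes(self) -> np.ndarray:
        """Per-cell volume, m³ (per m² of cross-section for slab_1d)."""
        h = self.spacing
        if self.grid_kind == "slab_1d":
            return np.full(self.shape, h)
        if self.grid_kind == "axisymmetric_2d":
            rf = self.r_faces()
            ring = np.pi * (rf[1:] ** 2 - rf[:-1] ** 2)
            return np.broadcast_to(ring[:, None] * h, self.shape).copy()
        return np.full(self.shape, h**3)

    def axis_index(self) -> tuple:
        """Lateral index of the source axis (center column)."""
        if self.grid_kind == "slab_1d":
            return ()
        if self.grid_kind == "axisymmetric_2d":
            return (0,)
        return (self.shape[0] // 2, self.shape[1] // 2)

    def axis_labels(self) -> np.ndarray:
        """Tissue codes along the source axis (one per z cell)."""
        return self.labels[self.axis_index()]

    def tissue_names(self, codes: np.ndarray) -> np.ndarray:
        return np.asarray(TISSUES)[np.asarray(codes, dtype=int)]

    def gray_matter_interface_depth(self) -> float:
        """Depth of the CSF / gray-matter boundary, m."""
        order = [TISSUE_CODES[l.tissue_id] for l in self.layers]
        gm_pos = order.index(TISSUE_CODES["gray_matter"])
        return self.layer_interfaces[gm_pos - 1]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            grid_kind=self.grid_kind,
            spacing=self.spacing,
            labels=self.labels,
            layer_interfaces=np.asarray(self.layer_interfaces),
            lateral_extent=self.lateral_extent,
            total_depth=self.total_depth,
            layer_tissues=np.asarray([l.tissue_id for l in self.layers]),
            layer_thicknesses=np.asarray(
                [np.nan if l.thickness is None else l.thickness for l in self.layers]
            ),
        )

    @classmethod
    def load(cls, path) -> "Phantom":
        with np.load(path, allow_pickle=False) as f:
            layers = tuple(
                LayerSpec(str(t), None if np.isnan(th) else float(th))
                for t, th in zip(f["layer_tissues"], f["layer_thicknesses"])
            )
            labels = f["labels"]
            return cls(
                grid_kind=str(f["grid_kind"]),
                spacing=float(f["spacing"]),
                shape=labels.shape,
                labels=labels,
                layer_interfaces=tuple(f["layer_interfaces"]),
                lateral_extent=float(f["lateral_extent"]),
                total_depth=float(f["total_depth"]),
                layers=layers,
            )


def build_phantom(
    layers: Sequence[LayerSpec] | None = None,
    grid_kind: str = "axisymmetric_2d",
    spacing: float = 0.5e-3,
    lateral_extent: float = 50e-3,
    total_depth: float = 60e-3,
) -> Phantom:
    """Build a layered phantom on a structured grid.

    Parameters
    ----------
    layers
        Ordered layer stack (outermost first). Defaults to
        :func:`default_layers`. Only the innermost layer may omit its
        thickness; cells beyond the last finite layer are white matter.
    grid_kind
        ``slab_1d``, ``axisymmetric_2d`` or ``voxel_3d``.
    spacing
        Cell edge, m. Must resolve every finite layer with >= 2 cells.
    lateral_extent
        Radius (axisymmetric) or half-width (voxel) of the grid, m.
    total_depth
        Depth of the grid, m.
    """
    layers = list(default_layers() if layers is None else layers)
    if grid_kind not in GRID_KINDS:
        raise ConfigurationError(f"unknown grid kind {grid_kind!r}")
    if spacing <= 0:
        raise DomainError("spacing must be positive")
    if total_depth <= 0 or lateral_extent <= 0:
        raise DomainError("domain extents must be positive")

    codes = [TISSUE_CODES[l.tissue_id] for l in layers]
    if codes != sorted(codes) or len(set(codes)) != len(codes):
        raise ConfigurationError(
            "layers must follow the order scalp_skull -> csf -> gray_matter -> "
            "white_matter without repetition"
        )
    for l in layers[:-1]:
        if l.thickness is None:
            raise ConfigurationError(
                f"only the innermost layer may omit its thickness ({l.tissue_id})"
            )
    for l in layers:
        if l.thickness is not None and spacing > l.thickness / 2:
            raise ResolutionError(
                f"spacing {spacing} m too coarse for layer {l.tissue_id!r} "
                f"of thickness {l.thickness} m (needs spacing <= thickness/2)"
            )

    interfaces = tuple(
        float(c) for c in np.cumsum([l.thickness for l in layers if l.thickness])
    )
    if interfaces and interfaces[-1] > total_depth:
        raise GeometryError(
            f"finite layers ({interfaces[-1]} m) exceed total depth {total_depth} m"
        )

    nz = int(round(total_depth / spacing))
    z = (np.arange(nz) + 0.5) * spacing
    col = np.full(nz, TISSUE_CODES["white_matter"], dtype=np.int8)
    bounds = (0.0,) + interfaces
    for layer, lo in zip(layers, bounds):
        hi = lo + layer.thickness if layer.thickness is not None else total_depth
        col[(z >= lo) & (z < hi)] = TISSUE_CODES[layer.tissue_id]
    # innermost finite layer extends to the bottom when no remainder layer given
    if layers[-1].thickness is not None:
        col[z >= interfaces[-1]] = TISSUE_CODES["white_matter"]

    if grid_kind == "slab_1d":
        shape: tuple = (nz,)
        labels = col.copy()
    elif grid_kind == "axisymmetric_2d":
        nr = int(round(lateral_extent / spacing))
        shape = (nr, nz)
        labels = np.broadcast_to(col, shape).copy()
    else:
        nxy = 2 * int(round(lateral_extent / spacing)) + 1
        shape = (nxy, nxy, nz)
        labels = np.broadcast_to(col, shape).copy()

    return Phantom(
        grid_kind=grid_kind,
        spacing=spacing,
        shape=shape,
        labels=labels,
        layer_interfaces=interfaces,
        lateral_extent=lateral_extent,
        total_depth=total_depth,
        layers=tuple(layers),
    )


@dataclass(frozen=True)
class CellProperties:
    """Per-cell optical, thermal and perfusion parameter fields on a phantom.

    Optical: ``mu_a``, ``mu_s_prime``, ``D`` (m) per cell plus the shared
    anisotropy ``g``. Thermal: conductivity ``K``, density ``rho``, specific
    heat ``c``, metabolic heat ``q_met`` per cell. Perfusion: rate ``omega_b``
    per cell plus blood scalars (``rho_b``, ``c_b``, arterial ``T_a``).
    """

    wavelength: float
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    D: np.ndarray
    g: float
    K: np.ndarray
    rho: np.ndarray
    c: np.ndarray
    q_met: np.ndarray
    omega_b: np.ndarray
    rho_b: float
    c_b: float
    T_a: float

    @property
    def mu_s(self) -> np.ndarray:
        return self.mu_s_prime / (1.0 - self.g)


def assign_properties(
    phantom: Phantom,
    wavelength: float,
    overrides: Mapping[str, Mapping[str, float]] | None = None,
    strict_thermal: bool = False,
) -> CellProperties:
    """Map per-tissue parameters onto every phantom cell.

    ``overrides`` is an optional ``{tissue: {"mu_a": ..., "mu_s_prime": ...}}``
    map; with overrides for all four tissues, arbitrary wavelengths can be run.
    A pure function of its arguments (idempotent).
    """
    overrides = {k: dict(v) for k, v in (overrides or {}).items()}
    tab = load_reference_tables()
    known = wavelength in set(tab.optical.wavelength_nm)

    mu_a_t = np.empty(len(TISSUES))
    mu_s_t = np.empty(len(TISSUES))
    for name, code in TISSUE_CODES.items():
        ov = overrides.get(name, {})
        if known:
            mu_a_t[code] = ov.get("mu_a", tab.lookup(name, wavelength, "mu_a"))
            mu_s_t[code] = ov.get(
                "mu_s_prime", tab.lookup(name, wavelength, "mu_s_prime")
            )
        else:
            if "mu_a" not in ov or "mu_s_prime" not in ov:
                raise ConfigurationError(
                    f"wavelength {wavelength} nm is not tabulated and overrides "
                    f"do not supply mu_a and mu_s_prime for {name!r}"
                )
            mu_a_t[code] = ov["mu_a"]
            mu_s_t[code] = ov["mu_s_prime"]

    lab = phantom.labels.astype(int)
    mu_a = mu_a_t[lab]
    mu_s_prime = mu_s_t[lab]
    thermal = bioheat_params.tissue_thermal_parameters(strict=strict_thermal)
    return CellProperties(
        wavelength=float(wavelength),
        mu_a=mu_a,
        mu_s_prime=mu_s_prime,
        D=diffusion_coefficient(mu_a, mu_s_prime),
        g=ANISOTROPY_G,
        K=thermal.K[lab],
        rho=thermal.rho[lab],
        c=thermal.c[lab],
        q_met=thermal.q_met[lab],
        omega_b=thermal.omega_b[lab],
        rho_b=thermal.rho_b,
        c_b=thermal.c_b,
        T_a=thermal.T_a,
    )
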