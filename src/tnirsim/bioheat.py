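"""Pennes bioheat transfer with an optical heat source.

Steady and transient solutions of::

    rho c dT/dt = div(K grad T) + rho_b omega_b c_b (T_a - T) + Q_met + Q_r

where blood perfusion acts as a distributed sink pulling tissue toward the
arterial temperature ``T_a`` and the optical source is ``Q_r = mu_a * phi``
(absorbed light power per volume). The scalp surface loses heat by convection,
``-K dT/dn = h (T - T_ambient)``; all other boundaries are insulated
(symmetry / far field).  "Temperature rise" is always reported against the
no-source steady state (the baseline solve), not against a flat 37 °C, since
convective cooling depresses the superficial layers even without light.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fv
from .diffusion import FluenceField
from .errors import DomainError, GeometryError, SolverError
from .phantom import CellProperties, Phantom
from .tables import TISSUES

__all__ = [
    "SurfaceBoundary",
    "TemperatureField",
    "TransientSolution",
    "heat_source",
    "solve_steady_bioheat",
    "solve_transient_bioheat",
    "temperature_rise_summary",
]


@dataclass(frozen=True)
class SurfaceBoundary:
    """Convective scalp-surface boundary: coefficient h (W/m²·°C) and ambient °C."""

    h: float = 4.0
    T_ambient: float = 25.0

    def __post_init__(self) -> None:
        if self.h < 0:
            raise DomainError("convective coefficient h must be >= 0")


@dataclass(frozen=True)
class TemperatureField:
    """Steady temperature (°C) and its no-optical-source baseline."""

    values: np.ndarray
    baseline: np.ndarray
    phantom: Phantom

    @property
    def rise(self) -> np.ndarray:
        """Temperature rise attributable to the optical source, °C."""
        return self.values - self.baseline


@dataclass(frozen=True)
class TransientSolution:
    """Implicit time march: times (s) and temperature snapshots."""

    times: np.ndarray
    values: np.ndarray  # shape (n_times, *grid shape)
    phantom: Phantom

    @property
    def final(self) -> np.ndarray:
        return self.values[-1]


def heat_source(mu_a_map: np.ndarray, fluence: FluenceField | np.ndarray) -> np.ndarray:
    """Optical heat deposition Q_r = mu_a * phi, W/m³ (pointwise product)."""
    phi = fluence.values if isinstance(fluence, FluenceField) else np.asarray(fluence)
    mu_a_map = np.asarray(mu_a_map)
    if mu_a_map.shape != phi.shape:
        raise GeometryError(
            f"mu_a map shape {mu_a_map.shape} != fluence shape {phi.shape}"
        )
    return mu_a_map * phi


def _thermal_system(phantom: Phantom, props: CellProperties,
                    boundary: SurfaceBoundary) -> _fv.FVSystem:
    removal = props.rho_b * props.c_b * props.omega_b
    boundaries = {(phantom.z_axis, 0): ("convective", boundary.h, boundary.T_ambient)}
    if boundary.h == 0 and float(np.max(removal)) <= 0.0:
        raise SolverError(
            "no perfusion and no surface convection: the steady bioheat "
            "problem is singular"
        )
    return _fv.assemble(phantom, props.K, removal, boundaries)


def _thermal_rhs(phantom: Phantom, props: CellProperties,
                 Qr: np.ndarray | None) -> np.ndarray:
    vol = phantom.cell_volumes()
    q = props.q_met + props.rho_b * props.c_b * props.omega_b * props.T_a
    if Qr is not None:
        if Qr.shape != phantom.shape:
            raise GeometryError("Qr shape does not match the phantom grid")
        q = q + Qr
    return q * vol


def solve_steady_bioheat(
    phantom: Phantom,
    props: CellProperties,
    Qr: np.ndarray | None,
    boundary: SurfaceBoundary | None = None,
) -> TemperatureField:
    """Steady Pennes solution with and without the optical source.

    Solves twice — once with ``Qr`` and once with ``Qr = 0`` — so the returned
    field carries both the heated state and the baseline that defines the
    temperature rise.
    """
    boundary = boundary or SurfaceBoundary()
    system = _thermal_system(phantom, props, boundary)
    baseline = system.solve(_thermal_rhs(phantom, props, None))
    if Qr is None or not np.any(Qr):
        values = baseline
    else:
        values = system.solve(_thermal_rhs(phantom, props, Qr))
    return TemperatureField(values=values, baseline=baseline, phantom=phantom)


def solve_transient_bioheat(
    phantom: Phantom,
    props: CellProperties,
    Qr: np.ndarray | None,
    boundary: SurfaceBoundary | None = None,
    t_end: float = 600.0,
    dt: float = 5.0,
    T0: np.ndarray | None = None,
    store_every: int = 1,
) -> TransientSolution:
    """Implicit-Euler march of the Pennes equation (unconditionally stable).

    Starts from ``T0`` (default: the no-source steady baseline) and integrates
    to ``t_end``; with a non-zero ``Qr`` the trajectory relaxes toward the
    heated steady state.
    """
    if dt <= 0 or t_end <= 0:
        raise DomainError("dt and t_end must be positive")
    boundary = boundary or SurfaceBoundary()
    if np.any(props.rho <= 0) or np.any(props.c <= 0):
        raise SolverError(
            "transient bioheat needs positive rho and c in every cell "
            "(as-printed densities are not usable here)"
        )
    system = _thermal_system(phantom, props, boundary)
    rhs = _thermal_rhs(phantom, props, Qr)
    if T0 is None:
        T0 = system.solve(_thermal_rhs(phantom, props, None))

    vol = phantom.cell_volumes()
    mass = (props.rho * props.c * vol).ravel() / dt
    A_step = (system.matrix + sp.diags(mass)).tocsc()
    lu = spla.splu(A_step)

    n_steps = int(np.ceil(t_end / dt))
    T = T0.ravel().astype(float).copy()
    b_const = rhs.ravel() + system.rhs_boundary
    times = [0.0]
    snaps = [T0.copy()]
    for n in range(1, n_steps + 1):
        T = lu.solve(b_const + mass * T)
        if n % store_every == 0 or n == n_steps:
            times.append(n * dt)
            snaps.append(T.reshape(phantom.shape).copy())
    return TransientSolution(times=np.asarray(times), values=np.asarray(snaps),
                             phantom=phantom)


def temperature_rise_summary(field: TemperatureField, phantom: Phantom | None = None) -> dict:
    """Per-tissue temperature-rise statistics and volume averages.

    Returns ``{"per_tissue": {tissue: {max_dT, mean_dT, volume_avg_T}},
    "surface_max_dT": ..., "max_dT": ..., "axis_profile": CutlineProfile-like
    dict}`` with dT = values - baseline.
    """
    phantom = phantom or field.phantom
    dT = field.rise
    vol = phantom.cell_volumes()
    per_tissue = {}
    for code, name in enumerate(TISSUES):
        mask = phantom.labels == code
        if not mask.any():
            continue
        w = vol[mask]
        per_tissue[name] = {
            "max_dT": float(dT[mask].max()),
            "mean_dT": float(np.average(dT[mask], weights=w)),
            "volume_avg_T": float(np.average(field.values[mask], weights=w)),
        }
    surf = (slice(None),) * phantom.z_axis + (0,)
    axis = phantom.axis_index()
    return {
        "per_tissue": per_tissue,
        "surface_max_dT": float(dT[surf].max()),
        "max_dT": float(dT.max()),
        "axis_profile": {
            "depth_m": phantom.z_centers().tolist(),
            "T_C": field.values[axis].tolist(),
            "dT_C": dT[axis].tolist(),
            "tissue": phantom.tissue_names(phantom.axis_labels()).tolist(),
        },
    }
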