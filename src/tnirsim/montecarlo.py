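"""Voxel Monte Carlo photon transport — the independent oracle for the
diffusion solver.

Weighted (implicit-capture) photons on a Cartesian voxel phantom: free paths
are sampled from the local total interaction coefficient ``mu_t = mu_a + mu_s``
(with ``mu_s = mu_s' / (1 - g)``), a fraction ``mu_a/mu_t`` of the weight is
deposited at each collision, directions are drawn from the Henyey–Greenstein
phase function, and low-weight photons play Russian roulette.  Fluence is
estimated with the track-length estimator (sum of weight × path length per
voxel divided by voxel volume), which converges to ``phi`` in W/m² when scaled
by source power per photon.

Boundaries are absorbing (escaping photons are tallied as reflected through
the ``z = 0`` face or transmitted elsewhere); internal refractive-index
mismatch is not modeled, matching the diffusion solver's index-matched Robin
closure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .diffusion import SourceSpec
from .errors import ConfigurationError, GeometryError
from .phantom import CellProperties, Phantom

__all__ = ["MCConfig", "MCResult", "run_mc", "sample_henyey_greenstein",
           "radial_mean_profile"]


def radial_mean_profile(values: np.ndarray, phantom: Phantom,
                        radius: float) -> np.ndarray:
    """Mean of a voxel field over the lateral disc ``r <= radius``, per depth.

    Averaging over the column around the source axis suppresses tally noise
    in Monte Carlo fields while preserving the depth profile, which makes
    diffusion-vs-MC comparisons meaningful at moderate photon counts.
    """
    if phantom.grid_kind != "voxel_3d":
        raise GeometryError("radial_mean_profile expects a voxel_3d phantom")
    if values.shape != phantom.shape:
        raise GeometryError("field shape does not match the phantom")
    cx, cy = phantom.axis_index()
    x = (np.arange(phantom.shape[0]) - cx) * phantom.spacing
    y = (np.arange(phantom.shape[1]) - cy) * phantom.spacing
    mask = (x[:, None] ** 2 + y[None, :] ** 2) <= radius**2
    if not mask.any():
        raise GeometryError("averaging radius smaller than one voxel")
    return values[mask].reshape(-1, phantom.nz).mean(axis=0)


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo run parameters."""

    n_photons: int = 100_000
    seed: int = 0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    g: float = 0.89

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ConfigurationError("n_photons must be >= 1 (empty result otherwise)")
        if not 0.0 < self.roulette_survival < 1.0:
            raise ConfigurationError("roulette survival must lie in (0, 1)")
        if not 0.0 <= self.g < 1.0:
            raise ConfigurationError("anisotropy g must lie in [0, 1)")


@dataclass(frozen=True)
class MCResult:
    """Per-voxel fluence estimate (W/m²) and launched-weight bookkeeping."""

    fluence: np.ndarray
    absorbed_fraction: float
    reflected_fraction: float
    transmitted_fraction: float
    config: MCConfig
    phantom: Phantom

    def axis_profile(self) -> np.ndarray:
        return self.fluence[self.phantom.axis_index()]


def sample_henyey_greenstein(g: float, n: int, seed: int = 0) -> np.ndarray:
    """Sample ``n`` scattering-angle cosines from the HG phase function."""
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    if g == 0.0:
        return 2.0 * u - 1.0
    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - s * s) / (2.0 * g)


@njit(cache=True)
def _transport(mua, mus, nx, ny, nz, h, launch_kind, x0, y0, z0,
               n_photons, seed, w_thresh, p_survive, g):
    np.random.seed(seed)
    tally = np.zeros(mua.size)
    absorbed = 0.0
    reflected = 0.0
    transmitted = 0.0
    eps = 1e-12

    for _ in range(n_photons):
        x, y, z = x0, y0, z0
        if launch_kind == 0:  # collimated at the surface
            ux, uy, uz = 0.0, 0.0, 1.0
            z = eps
        else:  # isotropic at an interior point
            cost = 2.0 * np.random.random() - 1.0
            sint = np.sqrt(max(0.0, 1.0 - cost * cost))
            phi_a = 2.0 * np.pi * np.random.random()
            ux = sint * np.cos(phi_a)
            uy = sint * np.sin(phi_a)
            uz = cost
        ix = int(x / h)
        iy = int(y / h)
        iz = int(z / h)
        w = 1.0
        tau = -np.log(np.random.random())
        alive = True
        while alive:
            if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
                if uz < 0.0 and iz < 0:
                    reflected += w
                else:
                    transmitted += w
                break
            v = (ix * ny + iy) * nz + iz
            mut = mua[v] + mus[v]

            # distances to the voxel faces along the direction of flight
            if ux > 0.0:
                tx = ((ix + 1) * h - x) / ux
            elif ux < 0.0:
                tx = (ix * h - x) / ux
            else:
                tx = 1e30
            if uy > 0.0:
                ty = ((iy + 1) * h - y) / uy
            elif uy < 0.0:
                ty = (iy * h - y) / uy
            else:
                ty = 1e30
            if uz > 0.0:
                tz = ((iz + 1) * h - z) / uz
            elif uz < 0.0:
                tz = (iz * h - z) / uz
            else:
                tz = 1e30
            tb = min(tx, ty, tz)
            if tb < 0.0:
                tb = 0.0

            d_event = tau / mut if mut > 0.0 else 1e30
            if d_event < tb:
                # collision inside this voxel
                x += ux * d_event
                y += uy * d_event
                z += uz * d_event
                tally[v] += w * d_event
                absorbed += w * mua[v] / mut
                w *= mus[v] / mut
                if w < w_thresh:
                    if np.random.random() < p_survive:
                        w /= p_survive
                    else:
                        alive = False
                        continue
                if w <= 0.0:
                    alive = False
                    continue
                # Henyey-Greenstein deflection
                u = np.random.random()
                if g == 0.0:
                    cost = 2.0 * u - 1.0
                else:
                    s = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                    cost = (1.0 + g * g - s * s) / (2.0 * g)
                if cost > 1.0:
                    cost = 1.0
                elif cost < -1.0:
                    cost = -1.0
                sint = np.sqrt(1.0 - cost * cost)
                phi_a = 2.0 * np.pi * np.random.random()
                cosp = np.cos(phi_a)
                sinp = np.sin(phi_a)
                if abs(uz) > 0.99999:
                    ux_n = sint * cosp
                    uy_n = sint * sinp
                    uz_n = cost * (1.0 if uz > 0.0 else -1.0)
                else:
                    den = np.sqrt(1.0 - uz * uz)
                    ux_n = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
                    uy_n = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
                    uz_n = -sint * cosp * den + uz * cost
                nrm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux, uy, uz = ux_n / nrm, uy_n / nrm, uz_n / nrm
                tau = -np.log(np.random.random())
            else:
                # cross into the neighbouring voxel
                x += ux * tb
                y += uy * tb
                z += uz * tb
                tally[v] += w * tb
                tau -= tb * mut
                if tb == tx:
                    ix += 1 if ux > 0.0 else -1
                elif tb == ty:
                    iy += 1 if uy > 0.0 else -1
                else:
                    iz += 1 if uz > 0.0 else -1
    return tally, absorbed, reflected, transmitted


def run_mc(
    phantom: Phantom,
    props: CellProperties,
    source: SourceSpec | None = None,
    config: MCConfig | None = None,
    launch: str = "pencil",
    launch_position: tuple | None = None,
) -> MCResult:
    """Run the voxel Monte Carlo transport.

    ``launch='pencil'`` starts photons collimated at the surface under the
    source position (the physical analogue of the regularized diffusion point
    source); ``launch='isotropic'`` emits isotropically from
    ``launch_position = (x, y, z)`` in meters, which is the configuration used
    to validate against the infinite-medium Green's function.
    """
    if phantom.grid_kind != "voxel_3d":
        raise GeometryError("Monte Carlo transport runs on voxel_3d phantoms")
    source = source or SourceSpec()
    config = config or MCConfig()
    if launch not in ("pencil", "isotropic"):
        raise ConfigurationError(f"unknown launch mode {launch!r}")

    nx, ny, nz = phantom.shape
    h = phantom.spacing
    mus = props.mu_s_prime / (1.0 - config.g)
    if launch_position is None:
        cx, cy = phantom.axis_index()
        launch_position = ((cx + 0.5) * h, (cy + 0.5) * h, 0.0)
    x0, y0, z0 = (float(c) for c in launch_position)
    if not (0 <= x0 <= nx * h and 0 <= y0 <= ny * h and 0 <= z0 <= nz * h):
        raise GeometryError("launch position outside the voxel grid")

    tally, absorbed, reflected, transmitted = _transport(
        np.ascontiguousarray(props.mu_a, dtype=np.float64).ravel(),
        np.ascontiguousarray(mus, dtype=np.float64).ravel(),
        nx, ny, nz, h,
        0 if launch == "pencil" else 1,
        x0, y0, z0,
        int(config.n_photons), int(config.seed),
        float(config.roulette_threshold), float(config.roulette_survival),
        float(config.g),
    )
    n = float(config.n_photons)
    scale = source.total_power / (n * h**3)
    return MCResult(
        fluence=(tally * scale).reshape(phantom.shape),
        absorbed_fraction=absorbed / n,
        reflected_fraction=reflected / n,
        transmitted_fraction=transmitted / n,
        config=config,
        phantom=phantom,
    )
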