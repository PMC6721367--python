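"""Finite-volume assembly shared by the photon-diffusion and bioheat solvers.

Both equations have the form ``-div(C grad u) + a u = q`` on a structured
grid (1-D slab, cylindrical axisymmetric, or Cartesian voxels).  Cell-centered
finite volumes with harmonic-mean face conductances give a symmetric positive
definite M-matrix, so solutions inherit a discrete maximum principle
(non-negative sources yield non-negative fields).

Boundary faces support three closures:

- ``("insulated",)``                    zero flux;
- ``("photon",)``                       partial-current Robin closure
  ``u + 2 A_n C du/dn = 0`` with A_n = 1 (index matched), discretized as an
  escape conductance ``A_face * 2C / (h + 4C)``;
- ``("convective", h_conv, u_amb)``     Newton cooling ``-C du/dn = h (u - u_amb)``,
  series conductance ``A_face / (1/h_conv + h/(2C))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import ConvergenceError, SolverError

#: Above this many unknowns the direct factorization is replaced by CG.
DIRECT_SOLVE_MAX_UNKNOWNS = 400_000

#: Relative residual tolerance for solves.
RESIDUAL_RTOL = 1e-8


def _internal_face_area(phantom, axis: int):
    h = phantom.spacing
    kind = phantom.grid_kind
    if kind == "slab_1d":
        return 1.0
    if kind == "voxel_3d":
        return h * h
    rf = phantom.r_faces()
    if axis == 0:  # radial faces at rf[1..nr-1]
        return (2.0 * np.pi * rf[1:-1] * h)[:, None]
    ring = np.pi * (rf[1:] ** 2 - rf[:-1] ** 2)
    return ring[:, None]


def _boundary_face_area(phantom, axis: int, side: int):
    h = phantom.spacing
    kind = phantom.grid_kind
    if kind == "slab_1d":
        return 1.0
    if kind == "voxel_3d":
        return h * h
    rf = phantom.r_faces()
    if axis == 0:
        return 0.0 if side == 0 else 2.0 * np.pi * rf[-1] * h
    return np.pi * (rf[1:] ** 2 - rf[:-1] ** 2)


@dataclass
class FVSystem:
    """Assembled sparse system with boundary bookkeeping."""

    matrix: sp.csr_matrix
    rhs_boundary: np.ndarray
    flux_terms: list  # (flat cell indices, conductance, reference value)
    volumes: np.ndarray
    shape: tuple

    def solve(self, source: np.ndarray) -> np.ndarray:
        """Solve for the field given a volumetric source vector (integrated, W)."""
        b = source.ravel() + self.rhs_boundary
        n = self.matrix.shape[0]
        if not np.any(b):
            return np.zeros(self.shape)
        try:
            if n <= DIRECT_SOLVE_MAX_UNKNOWNS:
                lu = spla.splu(self.matrix.tocsc())
                x = lu.solve(b)
            else:
                d = self.matrix.diagonal()
                M = sp.diags(1.0 / d)
                x, info = spla.cg(
                    self.matrix, b, rtol=RESIDUAL_RTOL * 1e-2, maxiter=20_000, M=M
                )
                if info != 0:
                    res = np.linalg.norm(self.matrix @ x - b) / np.linalg.norm(b)
                    raise ConvergenceError(
                        f"CG did not converge (info={info})", residual=res
                    )
        except RuntimeError as exc:  # singular factorization
            raise SolverError(f"linear solve failed: {exc}") from exc
        res = np.linalg.norm(self.matrix @ x - b) / np.linalg.norm(b)
        if not np.isfinite(res) or res > RESIDUAL_RTOL:
            raise ConvergenceError(
                f"relative residual {res:.2e} above {RESIDUAL_RTOL}", residual=res
            )
        return x.reshape(self.shape)

    def boundary_outflow(self, field: np.ndarray) -> float:
        """Total flux leaving through non-insulated boundaries, W."""
        u = field.ravel()
        total = 0.0
        for cells, G, uref in self.flux_terms:
            total += float(np.sum(G * (u[cells] - uref)))
        return total


def assemble(phantom, coeff: np.ndarray, removal: np.ndarray, boundaries: dict) -> FVSystem:
    """Assemble ``-div(C grad u) + a u`` over the phantom grid.

    Parameters
    ----------
    coeff
        Per-cell transport coefficient C (diffusion coefficient D, m, or
        thermal conductivity K, W/m·°C).
    removal
        Per-cell volumetric removal rate a (mu_a in 1/m, or rho_b*omega_b*c_b
        in W/m³·°C).
    boundaries
        ``{(axis, side): spec}`` with specs as in the module docstring;
        missing faces are insulated.
    """
    shape = phantom.shape
    ndim = len(shape)
    h = phantom.spacing
    N = int(np.prod(shape))
    vol = phantom.cell_volumes()
    if coeff.shape != shape or removal.shape != shape:
        raise SolverError("coefficient arrays must match the phantom shape")

    diag = (removal * vol).ravel().astype(float)
    rhs = np.zeros(N)
    idx = np.arange(N).reshape(shape)
    rows, cols, vals = [], [], []
    flux_terms = []

    for ax in range(ndim):
        sl_l = [slice(None)] * ndim
        sl_r = [slice(None)] * ndim
        sl_l[ax] = slice(0, -1)
        sl_r[ax] = slice(1, None)
        c_l = coeff[tuple(sl_l)]
        c_r = coeff[tuple(sl_r)]
        area = _internal_face_area(phantom, ax)
        G = (area / (h / (2.0 * c_l) + h / (2.0 * c_r))).ravel()
        il = idx[tuple(sl_l)].ravel()
        ir = idx[tuple(sl_r)].ravel()
        rows += [il, ir]
        cols += [ir, il]
        vals += [-G, -G]
        np.add.at(diag, il, G)
        np.add.at(diag, ir, G)

        for side in (0, 1):
            spec = boundaries.get((ax, side), ("insulated",))
            if spec[0] == "insulated":
                continue
            sl_b = [slice(None)] * ndim
            sl_b[ax] = 0 if side == 0 else -1
            c_b = coeff[tuple(sl_b)]
            area_b = _boundary_face_area(phantom, ax, side)
            if np.all(np.asarray(area_b) == 0.0):
                continue
            if spec[0] == "photon":
                Gb = area_b * 2.0 * c_b / (h + 4.0 * c_b)
                uref = 0.0
            elif spec[0] == "convective":
                _, h_conv, uref = spec
                if h_conv == 0:
                    continue
                Gb = area_b / (1.0 / h_conv + h / (2.0 * c_b))
            else:
                raise SolverError(f"unknown boundary closure {spec[0]!r}")
            ib = idx[tuple(sl_b)].ravel()
            Gb = np.broadcast_to(Gb, idx[tuple(sl_b)].shape).ravel().astype(float)
            np.add.at(diag, ib, Gb)
            rhs[ib] += Gb * uref
            flux_terms.append((ib, Gb, uref))

    rows.append(np.arange(N))
    cols.append(np.arange(N))
    vals.append(diag)
    A = sp.csr_matrix(
        sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(N, N),
        )
    )
    if not flux_terms and float(np.max(removal)) <= 0.0:
        raise SolverError(
            "system has no removal and no boundary conductance (pure Neumann); "
            "the steady problem is singular"
        )
    return FVSystem(matrix=A, rhs_boundary=rhs, flux_terms=flux_terms,
                    volumes=vol, shape=shape)
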