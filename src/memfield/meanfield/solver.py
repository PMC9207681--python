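"""Linearized Poisson-Boltzmann field solver on a regular grid.

Geometry: the membrane is an impermeable plane at z = 0 carrying a surface
charge density; the electrolyte fills the upper half of a cubic box of edge
``box_edge_A``.  Potentials are in kT/e throughout.

Discretization: a 19-point Mehrstellen (compact fourth-order) stencil for
the screened operator ``laplacian(psi) - psi/lambda^2 = -4 pi l_B rho``,
with a Numerov-consistent screening mass and a sixth-order source expansion
``f + (h^2/12) L7 f + (h^4/360) L7^2 f``.  The membrane surface-charge flux
condition ``d(psi)/dz|_0+ = -4 pi l_B sigma`` enters through mirror ghost
nodes whose flux coefficient is chosen so the uniform charged plane
(Gouy-Chapman) mode is reproduced exactly; the lateral faces are periodic
(the membrane tiles the box; Dirichlet side walls would demix the charged
leaflet toward the walls and break the uniform reference state) and the
top face is Dirichlet (psi = 0).  This combination meets a <2% pointwise
tolerance against the Yukawa point-charge and exponential plane closed
forms at a grid spacing of half a Debye length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..constants import bjerrum_length, ion_number_density_per_A3
from ..core.config import SolverConfig
from ..core.membrane import LatticeMembrane
from ..core.structure import ChargedStructure
from ..errors import ConvergenceError, GeometryError

__all__ = ["SolverConfig", "FieldSolution", "GridSolver", "solve_potential"]

_SPLU_MAX_UNKNOWNS = 70_000


@dataclass
class FieldSolution:
    """Electrostatic potential on the solver grid, in kT/e.

    ``psi`` is indexed (iz, iy, ix): x, y periodic over ``0..n-1``, z in
    ``0..n-1`` (z = 0 is the membrane surface row; the z = L face is
    Dirichlet).  ``components`` may hold the protein-only and surface-only
    superposition parts.
    """

    psi: np.ndarray
    solver: "GridSolver"
    converged: bool = True
    iterations: int = 1
    unit: str = "kT/e"
    components: dict = dc_field(default_factory=dict)
    model: object | None = None   # PoseEnergyModel backref, set by the caller

    @property
    def c_plus(self) -> np.ndarray:
        """Counter-ion concentration field, mol/L (linearized)."""
        c0 = self.solver.cfg.ionic_strength_M
        return c0 * (1.0 - self.psi)

    @property
    def c_minus(self) -> np.ndarray:
        c0 = self.solver.cfg.ionic_strength_M
        return c0 * (1.0 + self.psi)

    def potential_at(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of psi at Cartesian points (angstrom)."""
        return self.solver.gather_volume(self.psi, points)

    def surface_potential_at(self, xy: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of psi on the membrane plane z = 0."""
        return self.solver.gather_surface(self.psi[0], xy)


class GridSolver:
    """Assembled discrete operator for one (box, grid, electrolyte) setup."""

    def __init__(self, cfg: SolverConfig):
        cfg.validate()
        self.cfg = cfg
        self.n = int(cfg.grid_points)
        self.L = float(cfg.box_edge_A)
        self.h = self.L / self.n
        self.lam = cfg.debye_length_A
        self.kappa = 1.0 / self.lam
        self.l_B = bjerrum_length(cfg.temperature_K, cfg.relative_permittivity)
        # node coordinates of the unknowns; x/y are periodic (n nodes),
        # z runs from the membrane surface row (k = 0) to below the
        # Dirichlet top face (k = n - 1)
        self.xs = -self.L / 2.0 + np.arange(self.n) * self.h
        self.ys = self.xs.copy()
        self.zs = np.arange(0, self.n) * self.h
        self.nx = self.n
        self.nz = self.n
        self._assemble()
        self._lu = None

    # -- assembly --------------------------------------------------------

    def _assemble(self) -> None:
        h, kap = self.h, self.kappa
        nx, nz = self.nx, self.nz
        one = np.ones
        Dlat = sp.diags([one(nx - 1), -2.0 * one(nx), one(nx - 1),
                         one(1), one(1)],
                        [-1, 0, 1, nx - 1, -(nx - 1)]) / h ** 2  # periodic
        Dz = sp.diags([one(nz - 1), -2.0 * one(nz), one(nz - 1)],
                      [-1, 0, 1]).tolil()
        Dz[0, 0] = -2.0
        Dz[0, 1] = 2.0            # even mirror ghost folded in
        Dz = (Dz / h ** 2).tocsr()
        Ix = sp.identity(nx, format="csr")
        Iz = sp.identity(nz, format="csr")
        Wz = sp.diags([0.5] + [1.0] * (nz - 1))   # half-weight surface rows

        def k3(a, b, c):
            return sp.kron(a, sp.kron(b, c))

        D7 = k3(Dz, Ix, Ix) + k3(Iz, Dlat, Ix) + k3(Iz, Ix, Dlat)
        C = (k3(Dz, Dlat, Ix) + k3(Dz, Ix, Dlat) + k3(Iz, Dlat, Dlat))
        L19 = D7 + (h ** 2 / 6.0) * C
        M = sp.identity(nz * nx * nx, format="csr") + (h ** 2 / 12.0) * D7
        W3 = k3(Wz, Ix, Ix)
        self._A = (W3 @ (-L19 + kap ** 2 * M)).tocsr()
        self._M = M.tocsr()
        self._W3 = W3.tocsr()
        # Numerov ghost flux coefficient: exact for the laterally uniform mode
        beta = (kap * h) ** 2 / 12.0
        a = 2.0 + 10.0 * beta
        mu = (a - math.sqrt(a * a - 4.0 * (1.0 - beta) ** 2)) / (
            2.0 * (1.0 - beta))
        self._ghost_c = (a - 2.0 * mu * (1.0 - beta)) / (
            2.0 * kap * (1.0 - beta))
        self._flux_rhs_coeff = 0.5 * (1.0 / h ** 2 - kap ** 2 / 12.0) \
            * 2.0 * self._ghost_c * 4.0 * math.pi * self.l_B

    @property
    def n_unknowns(self) -> int:
        return self.nz * self.nx * self.nx

    # -- charge assignment ----------------------------------------------

    def spread_protein(self, protein: ChargedStructure) -> np.ndarray:
        """Trilinear (cloud-in-cell) assignment of atom charges to nodes.

        Returns the source field ``4 pi l_B rho`` (rho in e/A^3) on the
        unknown-node array, mirror-extended virtually at z < 0 by the even
        reflection implied by the impermeable-plane boundary.
        """
        pos = np.asarray(protein.positions, dtype=float)
        q = np.asarray(protein.charges, dtype=float)
        if np.any(pos[:, 2] < 0.0):
            raise GeometryError("protein atoms must lie in the upper "
                                "half-space (z >= 0)")
        f = np.zeros((self.nz, self.nx, self.nx))
        if not np.any(q):
            return f
        h = self.h
        # fractional grid coordinates relative to the unknown-node origin
        gx = (pos[:, 0] - self.xs[0]) / h
        gy = (pos[:, 1] - self.ys[0]) / h
        gz = pos[:, 2] / h
        base = np.floor(np.stack([gz, gy, gx], axis=1)).astype(int)
        frac = np.stack([gz, gy, gx], axis=1) - base
        coeff = 4.0 * math.pi * self.l_B / h ** 3
        for a in range(len(q)):
            if q[a] == 0.0:
                continue
            for dz in (0, 1):
                wz = (1.0 - frac[a, 0]) if dz == 0 else frac[a, 0]
                for dy in (0, 1):
                    wy = (1.0 - frac[a, 1]) if dy == 0 else frac[a, 1]
                    for dx in (0, 1):
                        wx = (1.0 - frac[a, 2]) if dx == 0 else frac[a, 2]
                        k = base[a, 0] + dz
                        j = (base[a, 1] + dy) % self.nx   # periodic x/y
                        i = (base[a, 2] + dx) % self.nx
                        if k < 0:      # even mirror across z = 0
                            k = -k
                        if 0 <= k < self.nz:
                            f[k, j, i] += q[a] * wz * wy * wx * coeff
        return f

    def _source_rhs(self, f: np.ndarray) -> np.ndarray:
        """Apply the source operator I + (h^2/12) L7 + (h^4/360) L7^2.

        The z < 0 ghost layer uses even reflection (image charges of the
        impermeable plane); x/y wrap periodically; the top ghost is zero
        (Dirichlet face).
        """
        h = self.h

        def lap7(g: np.ndarray) -> np.ndarray:
            q = np.pad(g, ((0, 0), (1, 1), (1, 1)), mode="wrap")
            p = np.pad(q, ((1, 1), (0, 0), (0, 0)))
            p[0] = p[2]                      # even mirror below z = 0
            out = (p[:-2, 1:-1, 1:-1] + p[2:, 1:-1, 1:-1]
                   + p[1:-1, :-2, 1:-1] + p[1:-1, 2:, 1:-1]
                   + p[1:-1, 1:-1, :-2] + p[1:-1, 1:-1, 2:]
                   - 6.0 * g) / h ** 2
            return out

        l1 = lap7(f)
        return f + (h ** 2 / 12.0) * l1 + (h ** 4 / 360.0) * lap7(l1)

    # -- surface charge ---------------------------------------------------

    def surface_xy_index(self, xy: np.ndarray):
        """Bilinear weights of in-plane points on the surface-node lattice."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        gx = (xy[:, 0] - self.xs[0]) / self.h
        gy = (xy[:, 1] - self.ys[0]) / self.h
        bx = np.floor(gx).astype(int)
        by = np.floor(gy).astype(int)
        fx = gx - bx
        fy = gy - by
        return bx, by, fx, fy

    def _site_overlap(self, site_xy: np.ndarray, site_size: float):
        """Overlap-area weights between square site cells and node cells.

        Yields ``(s, j_idx, i_idx, w)`` per site where ``w`` is the fraction
        of the site area shared with each node cell (node cell = h x h
        square centered on the node).  A site fully inside the box has
        weights summing to 1.
        """
        h = self.h
        half = (site_size + h) / 2.0
        xy = np.atleast_2d(np.asarray(site_xy, dtype=float))
        for s in range(len(xy)):
            cx, cy = xy[s]
            i_lo = int(np.ceil((cx - half - self.xs[0]) / h))
            i_hi = int(np.floor((cx + half - self.xs[0]) / h))
            j_lo = int(np.ceil((cy - half - self.ys[0]) / h))
            j_hi = int(np.floor((cy + half - self.ys[0]) / h))
            ii_raw = np.arange(i_lo, i_hi + 1)
            jj_raw = np.arange(j_lo, j_hi + 1)
            # virtual (unwrapped) node centers; indices wrap periodically
            vx = self.xs[0] + ii_raw * h
            vy = self.ys[0] + jj_raw * h
            ox = (np.minimum(vx + h / 2, cx + site_size / 2)
                  - np.maximum(vx - h / 2, cx - site_size / 2))
            oy = (np.minimum(vy + h / 2, cy + site_size / 2)
                  - np.maximum(vy - h / 2, cy - site_size / 2))
            w = (np.clip(oy, 0.0, None)[:, None]
                 * np.clip(ox, 0.0, None)[None, :]) / site_size ** 2
            yield s, jj_raw % self.nx, ii_raw % self.nx, w

    def spread_surface_charge(self, site_xy: np.ndarray,
                              site_charge: np.ndarray,
                              site_size: float) -> np.ndarray:
        """Conservative overlap-area assignment of site charges (e) onto the
        z = 0 node plane.

        Each lattice site is treated as a uniformly charged square of side
        ``site_size``; the returned array is the node surface-charge density
        (e/A^2).  A uniform site field maps to an exactly uniform node
        field.  Charge overhanging the Dirichlet side faces is dropped (the
        membrane patch is expected to lie inside the box).
        """
        sigma = np.zeros((self.nx, self.nx))
        q = np.asarray(site_charge, dtype=float)
        for s, jj, ii, w in self._site_overlap(site_xy, site_size):
            sigma[np.ix_(jj, ii)] += q[s] * w / self.h ** 2
        return sigma

    def gather_surface_sites(self, plane: np.ndarray, site_xy: np.ndarray,
                             site_size: float) -> np.ndarray:
        """Adjoint of :meth:`spread_surface_charge`: per-site potential as
        the overlap-weighted average of the surface node plane."""
        out = np.zeros(len(np.atleast_2d(site_xy)))
        for s, jj, ii, w in self._site_overlap(site_xy, site_size):
            out[s] = float(np.sum(plane[np.ix_(jj, ii)] * w))
        return out

    def gather_surface(self, plane: np.ndarray, xy: np.ndarray) -> np.ndarray:
        """Bilinear gather from the z = 0 node plane (adjoint of the spread)."""
        bx, by, fx, fy = self.surface_xy_index(xy)
        out = np.zeros(len(bx))
        for dy in (0, 1):
            wy = np.where(dy == 0, 1.0 - fy, fy)
            for dx in (0, 1):
                wx = np.where(dx == 0, 1.0 - fx, fx)
                j = (by + dy) % self.nx
                i = (bx + dx) % self.nx
                out += wy * wx * plane[j, i]
        return out

    def gather_volume(self, psi: np.ndarray, points: np.ndarray) -> np.ndarray:
        """Trilinear gather of a grid field at Cartesian points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        gx = (pts[:, 0] - self.xs[0]) / self.h
        gy = (pts[:, 1] - self.ys[0]) / self.h
        gz = pts[:, 2] / self.h
        bx = np.floor(gx).astype(int)
        by = np.floor(gy).astype(int)
        bz = np.floor(gz).astype(int)
        fx, fy, fz = gx - bx, gy - by, gz - bz
        out = np.zeros(len(pts))
        for dz in (0, 1):
            wz = np.where(dz == 0, 1.0 - fz, fz)
            for dy in (0, 1):
                wy = np.where(dy == 0, 1.0 - fy, fy)
                for dx in (0, 1):
                    wx = np.where(dx == 0, 1.0 - fx, fx)
                    k = bz + dz
                    j = (by + dy) % self.nx
                    i = (bx + dx) % self.nx
                    ok = (k >= 0) & (k < self.nz)   # z=L face is psi = 0
                    vals = np.zeros(len(pts))
                    vals[ok] = psi[k[ok], j[ok], i[ok]]
                    out += wz * wy * wx * vals
        return out

    # -- linear solves ----------------------------------------------------

    def _solve_linear(self, b: np.ndarray) -> np.ndarray:
        if self.n_unknowns <= _SPLU_MAX_UNKNOWNS:
            if self._lu is None:
                self._lu = spla.splu(self._A.tocsc())
            return self._lu.solve(b)
        x, info = spla.cg(self._A, b, rtol=1e-10, atol=0.0,
                          maxiter=20 * self.n)
        if info != 0:
            res = np.linalg.norm(self._A @ x - b)
            raise ConvergenceError(
                f"CG failed to converge (info={info}, residual={res:.3e})")
        return x

    def solve_components(self, f_protein: np.ndarray | None,
                         sigma_nodes: np.ndarray | None) -> np.ndarray:
        """Solve for the potential of a volume source and/or surface charge.

        With ``cfg.nonlinear_ions`` the full Boltzmann ion response
        ``laplacian(psi) = sinh(psi)/lambda^2 - f`` is solved by Picard
        iteration around the cached linear operator.
        """
        b = np.zeros((self.nz, self.nx, self.nx))
        if f_protein is not None and np.any(f_protein):
            b += self._source_rhs(f_protein)
        b[0] *= 0.5        # surface rows carry half weight (symmetry)
        if sigma_nodes is not None and np.any(sigma_nodes):
            b[0] += self._flux_rhs_coeff * sigma_nodes
        b = b.ravel()
        psi = self._solve_linear(b)
        if self.cfg.nonlinear_ions:
            kap2 = self.kappa ** 2
            damping = 0.5
            prev_res = np.inf
            for it in range(2000):
                # move the nonlinear excess kappa^2 (psi - sinh psi) to the
                # right-hand side; the ion response saturates at |psi| = 10
                # kT/e (steric cap: this option targets moderate surface
                # potentials, not bare point-charge near fields)
                psi_c = np.clip(psi, -10.0, 10.0)
                correction = self._W3 @ (self._M @ (
                    kap2 * (psi_c - np.sinh(psi_c))))
                psi_new = self._solve_linear(b + correction)
                res = float(np.max(np.abs(psi_new - psi)))
                if res < 1e-9:
                    psi = psi_new
                    break
                if res > prev_res:
                    damping = max(0.5 * damping, 1e-3)
                prev_res = res
                psi = psi + damping * (psi_new - psi)
            else:
                raise ConvergenceError(
                    "nonlinear ion Picard iteration did not converge "
                    f"(residual {prev_res:.3e})")
        return psi.reshape(self.nz, self.nx, self.nx)

    def volume_weights(self) -> np.ndarray:
        """Per-node volume weights h^3 (half on the surface row) as (nz,1,1)."""
        w = np.full(self.nz, self.h ** 3)
        w[0] *= 0.5
        return w.reshape(self.nz, 1, 1)

    @property
    def ion_density_A3(self) -> float:
        return ion_number_density_per_A3(self.cfg.ionic_strength_M)


def membrane_site_charges(membrane: LatticeMembrane,
                          phi: np.ndarray | None = None) -> np.ndarray:
    """Per-site surface charge in e: z_l * phi * A_site / a."""
    sigma = membrane.surface_charge_density(phi)
    return sigma * membrane.site_area


def solve_potential(protein: ChargedStructure, membrane: LatticeMembrane,
                    cfg: SolverConfig,
                    solver: Optional[GridSolver] = None) -> FieldSolution:
    """Solve the linearized PB problem for a protein pose over a membrane.

    The returned solution is the superposition of the protein-driven and
    surface-charge-driven parts (stored in ``components``).
    """
    grid = solver if solver is not None else GridSolver(cfg)
    f_p = grid.spread_protein(protein)
    sigma = grid.spread_surface_charge(
        membrane.site_xy, membrane_site_charges(membrane),
        membrane.lattice_spacing)
    psi_p = grid.solve_components(f_p, None) if np.any(f_p) else np.zeros(
        (grid.nz, grid.nx, grid.nx))
    psi_s = grid.solve_components(None, sigma) if np.any(sigma) else np.zeros(
        (grid.nz, grid.nx, grid.nx))
    return FieldSolution(psi=psi_p + psi_s, solver=grid,
                         components={"protein": psi_p, "surface": psi_s})
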