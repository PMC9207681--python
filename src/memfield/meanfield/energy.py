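"""Mean-field free energy F = F_el + F_ion + F_lip and the self-consistent
relaxation of the mobile anionic lipid density.

All energies are in kT, measured relative to the reference state with the
protein uncharged/removed and the anionic density uniform at its mean.
The electrostatic + ion-entropy sum equals the Debye-Huckel charging energy
``1/2 sum(q_fixed * psi)``; it is split into a field-energy part (F_el) and
the quadratic ion-entropy part (F_ion) so that each component vanishes in
the reference state and the total is the thermodynamic functional whose
minimization drives the density updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from ..core.config import SolverConfig
from ..core.membrane import LatticeMembrane
from ..core.structure import ChargedStructure
from ..errors import ConvergenceError
from .solver import FieldSolution, GridSolver, solve_potential

__all__ = ["FreeEnergyBreakdown", "PoseEnergyModel", "free_energy",
           "update_lipid_densities"]


@dataclass(frozen=True)
class FreeEnergyBreakdown:
    F_total: float
    F_el: float
    F_ion: float
    F_lip: float

    def __post_init__(self) -> None:
        if abs(self.F_total - (self.F_el + self.F_ion + self.F_lip)) > 1e-9:
            raise ValueError("free-energy components do not sum to the total")


def _xlogx(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] * np.log(x[pos])
    return out


def _check_phi(phi: np.ndarray) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if np.any(phi <= 0.0) or np.any(phi >= 1.0):
        raise ValueError("phi must lie strictly inside (0, 1) at every site")
    return phi


def mixing_entropy(phi: np.ndarray, phi_ref: float, site_area: float,
                   area_per_lipid: float) -> float:
    """Lattice-gas mixing entropy sum relative to the uniform reference, kT."""
    phi = np.asarray(phi, dtype=float)
    per_site = _xlogx(phi) + _xlogx(1.0 - phi)
    ref = _xlogx(np.asarray([phi_ref]))[0] + _xlogx(
        np.asarray([1.0 - phi_ref]))[0]
    return float((site_area / area_per_lipid) * np.sum(per_site - ref))


def _conserving_langmuir(x: np.ndarray, target_sum: float) -> np.ndarray:
    """phi' = expit(mu - x) with mu chosen so sum(phi') = target_sum."""
    n = len(x)
    if not (0.0 < target_sum < n):
        raise ValueError("target amount must keep phi inside (0, 1)")

    def g(mu: float) -> float:
        return float(np.sum(expit(mu - x)) - target_sum)

    mu0 = float(logit(target_sum / n))
    lo = mu0 + float(np.min(-x)) - 1.0
    hi = mu0 + float(np.max(-x)) + 1.0
    for _ in range(200):
        if g(lo) < 0.0:
            break
        lo -= max(1.0, abs(lo))
    else:
        raise ConvergenceError("failed to bracket the chemical potential (lo)")
    for _ in range(200):
        if g(hi) > 0.0:
            break
        hi += max(1.0, abs(hi))
    else:
        raise ConvergenceError("failed to bracket the chemical potential (hi)")
    mu = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=300)
    return expit(mu - x)


class PoseEnergyModel:
    """Free-energy evaluations for one fixed protein pose over a membrane.

    Caches the protein-driven field and the uniform-density reference so the
    per-iteration cost of the self-consistent loop is a single surface solve.
    """

    def __init__(self, protein: ChargedStructure, membrane: LatticeMembrane,
                 cfg: SolverConfig, solver: Optional[GridSolver] = None):
        self.protein = protein
        self.membrane = membrane
        self.cfg = cfg
        self.solver = solver if solver is not None else GridSolver(cfg)
        self.site_xy = membrane.site_xy
        self.z_l = membrane.anionic_species.headgroup_charge
        self.site_area = membrane.site_area
        self.area_per_lipid = membrane.area_per_lipid
        self.phi_ref = float(np.mean(membrane.phi))
        self.site_size = membrane.lattice_spacing
        g = self.solver
        f_p = g.spread_protein(protein)
        zero = np.zeros((g.nz, g.nx, g.nx))
        self.psi_p = (g.solve_components(f_p, None) if np.any(f_p)
                      else zero.copy())
        self.psi_p_sites = g.gather_surface_sites(self.psi_p[0], self.site_xy,
                                                  self.site_size)
        # uniform-density reference
        q_ref = self._site_charges(np.full(membrane.n_sites, self.phi_ref))
        sig_ref = g.spread_surface_charge(self.site_xy, q_ref, self.site_size)
        self.psi_sref = (g.solve_components(None, sig_ref)
                         if np.any(sig_ref) else zero.copy())
        self._U_ref = 0.5 * float(
            q_ref @ g.gather_surface_sites(self.psi_sref[0], self.site_xy,
                                           self.site_size))
        self._vol_w = g.volume_weights()

    # -- pieces -----------------------------------------------------------

    def _site_charges(self, phi: np.ndarray) -> np.ndarray:
        return self.z_l * np.asarray(phi) * self.site_area \
            / self.area_per_lipid

    def solve_surface(self, phi: np.ndarray) -> np.ndarray:
        sigma = self.solver.spread_surface_charge(
            self.site_xy, self._site_charges(phi), self.site_size)
        if not np.any(sigma):
            return np.zeros_like(self.psi_p)
        return self.solver.solve_components(None, sigma)

    def field(self, phi: np.ndarray,
              psi_s: np.ndarray | None = None) -> FieldSolution:
        if psi_s is None:
            psi_s = self.solve_surface(phi)
        sol = FieldSolution(psi=self.psi_p + psi_s, solver=self.solver,
                            components={"protein": self.psi_p,
                                        "surface": psi_s})
        sol.model = self
        return sol

    def free_energy(self, phi: np.ndarray,
                    psi_s: np.ndarray | None = None) -> FreeEnergyBreakdown:
        phi = _check_phi(phi)
        if psi_s is None:
            psi_s = self.solve_surface(phi)
        g = self.solver
        q = self._site_charges(phi)
        psi_s_sites = g.gather_surface_sites(psi_s[0], self.site_xy,
                                             self.site_size)
        U_int = float(q @ self.psi_p_sites)
        U_ss = 0.5 * float(q @ psi_s_sites)
        F_elion = U_int + U_ss - self._U_ref
        psi_tot = self.psi_p + psi_s
        c0 = g.ion_density_A3
        F_ion = float(c0 * np.sum(
            (psi_tot ** 2 - self.psi_p ** 2 - self.psi_sref ** 2)
            * self._vol_w))
        F_lip = mixing_entropy(phi, self.phi_ref, self.site_area,
                               self.area_per_lipid)
        return FreeEnergyBreakdown(F_total=F_elion + F_lip,
                                   F_el=F_elion - F_ion,
                                   F_ion=F_ion, F_lip=F_lip)

    def langmuir_target(self, phi: np.ndarray,
                        psi_s: np.ndarray | None = None) -> np.ndarray:
        """Undamped conserving Langmuir update of phi for the current field."""
        if psi_s is None:
            psi_s = self.solve_surface(phi)
        psi_tot_sites = self.psi_p_sites + self.solver.gather_surface_sites(
            psi_s[0], self.site_xy, self.site_size)
        x = self.z_l * psi_tot_sites
        return _conserving_langmuir(x, float(np.sum(phi)))

    # -- self-consistent relaxation --------------------------------------

    def relax(self, phi0: np.ndarray | None = None,
              phi_tol: float = 1e-9, collect_history: bool = False):
        """Damped fixed-point iteration with monotone free-energy descent.

        Returns ``(phi, breakdown, info)`` where ``info`` carries iteration
        count, convergence flag, and optionally the F_total history.
        """
        cfg = self.cfg
        phi = (np.asarray(phi0, dtype=float) if phi0 is not None
               else self.membrane.phi.copy())
        phi = _check_phi(phi)
        psi_s = self.solve_surface(phi)
        fe = self.free_energy(phi, psi_s)
        history = [fe.F_total]
        converged = False
        iterations = 0
        eps = 1e-12
        m_adapt = cfg.mixing
        m_near = None
        prev_res = np.inf
        for iterations in range(1, cfg.max_iter + 1):
            target = self.langmuir_target(phi, psi_s)
            delta = target - phi
            res = float(np.max(np.abs(delta)))
            if res < phi_tol:
                converged = True
                break
            if res < 1e-5:
                # near the fixed point free-energy differences sit at the
                # rounding floor, so the descent check is uninformative:
                # switch to plain damped iteration with residual monitoring
                if m_near is None:
                    m_near = min(max(m_adapt, cfg.mixing), 1.0)
                if res > prev_res:
                    m_near = max(0.5 * m_near, 1e-3)
                prev_res = res
                phi = phi + m_near * delta
                psi_s = self.solve_surface(phi)
                fe = self.free_energy(phi, psi_s)
                history.append(fe.F_total)
                continue
            # largest step keeping phi strictly inside (0, 1)
            with np.errstate(divide="ignore"):
                up = np.where(delta > 0, (1.0 - eps - phi) / delta, np.inf)
                dn = np.where(delta < 0, (eps - phi) / delta, np.inf)
            m_feas = float(min(np.min(up), np.min(dn)))
            m = min(m_adapt, m_feas)
            accepted = False
            backtracked = False
            for _ in range(60):
                phi_try = phi + m * delta
                psi_try = self.solve_surface(phi_try)
                fe_try = self.free_energy(phi_try, psi_try)
                if fe_try.F_total <= fe.F_total \
                        + 1e-12 * max(1.0, abs(fe.F_total)):
                    phi, psi_s, fe = phi_try, psi_try, fe_try
                    accepted = True
                    break
                m *= 0.5
                backtracked = True
            # adapt the damping: grow after clean acceptances (over-relaxation
            # speeds up the linear contraction), remember reductions
            if accepted:
                m_adapt = (max(m, cfg.mixing * 1e-3) if backtracked
                           else min(m_adapt * 1.3, 4.0))
            history.append(fe.F_total)
            if not accepted:
                # descent stalled at numerical floor; treat as converged if
                # the remaining step is already small
                if float(np.max(np.abs(delta))) < 1e-6:
                    converged = True
                    break
                raise ConvergenceError(
                    "free-energy descent stalled with residual "
                    f"max|dphi| = {float(np.max(np.abs(delta))):.3e}")
        if not converged:
            raise ConvergenceError(
                f"density relaxation did not converge in {cfg.max_iter} "
                f"iterations (residual max|dphi| = "
                f"{float(np.max(np.abs(target - phi))):.3e})")
        info = {"iterations": iterations, "converged": converged}
        if collect_history:
            info["history"] = history
        return phi, fe, info


# -- module-level operations matching the pipeline surface ----------------

def update_lipid_densities(field: FieldSolution, membrane: LatticeMembrane,
                           cfg: SolverConfig,
                           mixing: float | None = None) -> np.ndarray:
    """One damped, amount-conserving Langmuir update of phi.

    ``phi'/(1-phi') = exp(-(z_l psi - mu))`` with mu set by bisection so the
    total anionic amount is conserved; the configured mixing damping is then
    applied: ``phi_next = (1 - m) phi + m phi'``.
    """
    phi = _check_phi(membrane.phi)
    z_l = membrane.anionic_species.headgroup_charge
    psi_sites = field.solver.gather_surface_sites(
        field.psi[0], membrane.site_xy, membrane.lattice_spacing)
    target = _conserving_langmuir(z_l * psi_sites, float(np.sum(phi)))
    m = cfg.mixing if mixing is None else mixing
    return (1.0 - m) * phi + m * target


def free_energy(field: FieldSolution, membrane: LatticeMembrane,
                cfg: SolverConfig,
                protein: ChargedStructure | None = None
                ) -> FreeEnergyBreakdown:
    """Free-energy breakdown for a solved field and the membrane's phi.

    Requires the superposition components of the field (as produced by
    :func:`solve_potential` or :class:`PoseEnergyModel.field`).
    """
    model = field.model
    if model is None:
        if protein is None:
            raise ValueError(
                "free_energy needs either a model-attached field or the "
                "protein structure")
        model = PoseEnergyModel(protein, membrane, cfg, solver=field.solver)
    psi_s = field.components.get("surface")
    return model.free_energy(membrane.phi, psi_s)
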