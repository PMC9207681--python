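"""Lattice membrane with laterally mobile anionic lipid density.

The membrane is a 2D lattice of lipid sites in the plane z = 0 (internal
frame; outward normal +z).  Each site carries a species assignment and the
smooth anionic area-fraction field phi(x, y) used by the mean-field stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class LipidSpecies:
    name: str
    headgroup_charge: float     # elementary charges
    mole_fraction: float


@dataclass
class LatticeMembrane:
    """Per-leaflet lipid lattice plus the mobile anionic density field.

    ``site_xy`` holds the in-plane site centers of the upper (protein-facing)
    leaflet in the membrane frame; ``phi`` is the anionic area fraction at
    those sites.  ``occupancy_upper``/``occupancy_lower`` are per-site species
    names for the two leaflets (equal length for symmetric bilayers).
    """

    plane_origin: np.ndarray                 # (3,)
    normal: np.ndarray                       # (3,), unit
    lattice_spacing: float                   # A
    area_per_lipid: float                    # A^2
    species: Sequence[LipidSpecies]
    site_xy: np.ndarray                      # (n_sites, 2)
    occupancy_upper: np.ndarray              # (n_sites,) str
    occupancy_lower: np.ndarray              # (n_sites,) str
    phi: np.ndarray                          # (n_sites,)

    def __post_init__(self) -> None:
        self.plane_origin = np.asarray(self.plane_origin, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        nrm = np.linalg.norm(self.normal)
        if not np.isclose(nrm, 1.0, atol=1e-8):
            raise ValueError("normal must be a unit vector")
        self.site_xy = np.asarray(self.site_xy, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        total = sum(s.mole_fraction for s in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mole fractions sum to {total}, expected 1")
        if np.any(self.phi < 0) or np.any(self.phi > 1):
            raise ValueError("phi must lie in [0, 1]")
        if len(self.phi) != len(self.site_xy):
            raise ValueError("phi and site_xy length mismatch")
        if len(self.occupancy_upper) != len(self.site_xy):
            raise ValueError("occupancy_upper length mismatch")
        if len(self.occupancy_lower) != len(self.occupancy_upper):
            raise ValueError("leaflets must have equal site counts")

    @property
    def n_sites(self) -> int:
        return len(self.site_xy)

    @property
    def site_area(self) -> float:
        return self.lattice_spacing ** 2

    @property
    def n_lipids(self) -> int:
        return len(self.occupancy_upper) + len(self.occupancy_lower)

    @property
    def anionic_species(self) -> LipidSpecies:
        """The (single) charged mobile species carried by phi."""
        charged = [s for s in self.species if s.headgroup_charge != 0.0]
        if len(charged) != 1:
            raise ValueError(
                f"expected exactly one charged species, found {len(charged)}")
        return charged[0]

    @property
    def total_anionic_amount(self) -> float:
        """Conserved quantity: sum of phi times site area."""
        return float(self.phi.sum() * self.site_area)

    def surface_charge_density(self, phi: np.ndarray | None = None
                               ) -> np.ndarray:
        """sigma(x, y) = z_l * phi / a, in e/A^2 at each site."""
        p = self.phi if phi is None else np.asarray(phi, dtype=float)
        return self.anionic_species.headgroup_charge * p / self.area_per_lipid

    def with_phi(self, phi: np.ndarray) -> "LatticeMembrane":
        return LatticeMembrane(
            plane_origin=self.plane_origin, normal=self.normal,
            lattice_spacing=self.lattice_spacing,
            area_per_lipid=self.area_per_lipid, species=self.species,
            site_xy=self.site_xy, occupancy_upper=self.occupancy_upper,
            occupancy_lower=self.occupancy_lower,
            phi=np.asarray(phi, dtype=float))


def uniform_membrane(extent: float, lattice_spacing: float,
                     species: Sequence[LipidSpecies],
                     area_per_lipid: float = 65.0) -> LatticeMembrane:
    """Square membrane patch centered on the origin with uniform phi.

    ``extent`` is the side length; phi is initialised to the anionic mole
    fraction everywhere.
    """
    n_side = max(int(round(extent / lattice_spacing)), 1)
    coords = (np.arange(n_side) - (n_side - 1) / 2.0) * lattice_spacing
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    site_xy = np.column_stack([xx.ravel(), yy.ravel()])
    charged = [s for s in species if s.headgroup_charge != 0.0]
    if len(charged) != 1:
        raise ValueError("uniform_membrane needs exactly one charged species")
    phi = np.full(len(site_xy), charged[0].mole_fraction)
    majority = max(species, key=lambda s: s.mole_fraction)
    occ = np.full(len(site_xy), majority.name)
    return LatticeMembrane(
        plane_origin=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]),
        lattice_spacing=lattice_spacing, area_per_lipid=area_per_lipid,
        species=list(species), site_xy=site_xy,
        occupancy_upper=occ, occupancy_lower=occ.copy(), phi=phi)
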