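"""Shared fixtures: probe structures, membranes, and cached grid solvers.

Grid solvers are session-scoped because operator assembly/factorization is
the dominant cost; all tests that can share a (box, grid) setup do so.
"""

from __future__ import annotations

import numpy as np
import pytest

from memfield.core.config import SolverConfig
from memfield.core.membrane import LipidSpecies, uniform_membrane
from memfield.core.structure import ChargedStructure
from memfield.meanfield.solver import GridSolver


def make_probe(positions, charges, names=None, residue_names=None,
               residue_ids=None, elements=None) -> ChargedStructure:
    """Bare point-charge structure for solver tests."""
    n = len(charges)
    return ChargedStructure(
        atom_id=np.arange(1, n + 1),
        name=np.array(names if names is not None else ["Q"] * n,
                      dtype=object),
        residue_name=np.array(
            residue_names if residue_names is not None else ["ION"] * n,
            dtype=object),
        residue_id=np.array(
            residue_ids if residue_ids is not None else np.arange(1, n + 1)),
        positions=np.array(positions, dtype=float),
        charges=np.array(charges, dtype=float),
        elements=np.array(elements if elements is not None else ["C"] * n,
                          dtype=object),
        segments=np.array(["other"] * n, dtype=str))


PS_SPECIES = [LipidSpecies("POPC", 0.0, 0.9), LipidSpecies("POPS", -1.0, 0.1)]
PIP2_SPECIES = [LipidSpecies("POPC", 0.0, 0.9),
                LipidSpecies("PIP2", -4.0, 0.1)]


@pytest.fixture(scope="session")
def cfg_small() -> SolverConfig:
    return SolverConfig(box_edge_A=64.0, grid_points=16, max_iter=800,
                        mixing=0.5)


@pytest.fixture(scope="session")
def solver_small(cfg_small) -> GridSolver:
    return GridSolver(cfg_small)


@pytest.fixture(scope="session")
def cfg_oracle() -> SolverConfig:
    # lambda/2 grid resolution: h = 4 A vs lambda = 8.09 A
    return SolverConfig(box_edge_A=128.0, grid_points=32)


@pytest.fixture(scope="session")
def solver_oracle(cfg_oracle) -> GridSolver:
    return GridSolver(cfg_oracle)


@pytest.fixture()
def ps_membrane_small():
    return uniform_membrane(extent=64.0, lattice_spacing=8.0,
                            species=PS_SPECIES)


@pytest.fixture()
def pip2_membrane_small():
    return uniform_membrane(extent=64.0, lattice_spacing=8.0,
                            species=PIP2_SPECIES)


@pytest.fixture()
def pip2_membrane_oracle():
    return uniform_membrane(extent=128.0, lattice_spacing=8.0,
                            species=PIP2_SPECIES)
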