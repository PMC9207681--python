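"""Export the steady-state anionic density map and draw lipid placements."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ..core.membrane import LatticeMembrane
from ..core.tables import TableArtifact

__all__ = ["density_map_table", "place_anionic_sites",
           "export_density_and_place"]


def density_map_table(membrane: LatticeMembrane, command: str = "",
                      seed: int | None = None,
                      config: dict | None = None) -> TableArtifact:
    """Long-format (x, y, phi) table of the anionic density map."""
    df = pd.DataFrame({
        "x_A": membrane.site_xy[:, 0],
        "y_A": membrane.site_xy[:, 1],
        "phi": membrane.phi,
    })
    return TableArtifact.create(df, command=command, seed=seed, config=config)


def place_anionic_sites(membrane: LatticeMembrane, n_anionic: int,
                        seed: int) -> np.ndarray:
    """Draw ``n_anionic`` distinct lattice sites with probability
    proportional to phi (without replacement); seeded and reproducible."""
    phi = np.asarray(membrane.phi, dtype=float)
    if n_anionic < 0:
        raise ValueError("n_anionic must be >= 0")
    if n_anionic > membrane.n_sites:
        raise ValueError(
            f"cannot place {n_anionic} lipids on {membrane.n_sites} sites")
    total = phi.sum()
    if total <= 0.0:
        raise ValueError("density map is identically zero")
    n_support = int(np.count_nonzero(phi))
    if n_anionic > n_support:
        raise ValueError(
            f"cannot place {n_anionic} lipids on {n_support} sites with "
            "nonzero density")
    rng = np.random.default_rng(seed)
    sites = rng.choice(membrane.n_sites, size=n_anionic, replace=False,
                       p=phi / total)
    return np.sort(sites)


def export_density_and_place(membrane: LatticeMembrane, n_anionic: int,
                             seed: int, out_dir: str | Path | None = None,
                             command: str = "", config: dict | None = None
                             ) -> tuple[TableArtifact, np.ndarray]:
    """Write the density map CSV and a seeded site assignment.

    Returns the map artifact and the chosen site indices; files
    ``density.csv`` and ``placement.csv`` are written when ``out_dir``
    is given.
    """
    table = density_map_table(membrane, command=command, seed=seed,
                              config=config)
    sites = place_anionic_sites(membrane, n_anionic, seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.write_csv(out / "density.csv")
        placement = TableArtifact.create(
            pd.DataFrame({
                "site_index": sites,
                "x_A": membrane.site_xy[sites, 0],
                "y_A": membrane.site_xy[sites, 1],
            }), command=command, seed=seed, config=config)
        placement.write_csv(out / "placement.csv")
    return table, sites
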