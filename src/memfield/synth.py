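"""Seeded synthetic-data generators.

Everything the analysis stages consume can be generated here with no
downloads: bead proteins with labeled segments and charged sites, lattice
bilayers at a 44:23:23:10-style composition, trajectories with planted
orientations and lipid-binding events, and single-exponential FRET traces.
All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .analysis.contacts import parse_residue_label
from .core.membrane import LatticeMembrane, LipidSpecies
from .core.structure import ChargedStructure, Segment
from .core.trajectory import Trajectory
from .errors import ConfigError
from .kinetics import FretTrace

__all__ = ["BeadProteinSpec", "ChargedSite", "BindingPlan", "BindingEvent",
           "make_bilayer", "make_bead_protein", "make_trajectory",
           "make_fret_trace", "plan_totals", "largest_remainder_allocation",
           "sample_orientation_schedule", "pose_rotation",
           "canonical_frame_rotation"]


# -- bilayer ---------------------------------------------------------------

def largest_remainder_allocation(percentages: Sequence[float],
                                 n_total: int) -> list[int]:
    """Hamilton apportionment of ``n_total`` among percentage shares."""
    if abs(sum(percentages) - 100.0) > 1e-9:
        raise ConfigError(
            f"composition percentages sum to {sum(percentages)}, "
            "expected 100")
    quotas = [p * n_total / 100.0 for p in percentages]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n_total - sum(counts)
    order = sorted(range(len(quotas)),
                   key=lambda i: (quotas[i] - counts[i], -i), reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _grid_shape(n: int) -> tuple[int, int]:
    """Most-square factor pair of n (falls back to 1 x n for primes)."""
    best = (1, n)
    for a in range(1, int(math.isqrt(n)) + 1):
        if n % a == 0:
            best = (a, n // a)
    return best


def make_bilayer(n_per_leaflet: int = 200,
                 composition_percent: Mapping[str, float] | None = None,
                 anionic_species: str = "PIP2",
                 anionic_charge_e: float = -4.0,
                 lattice_spacing_A: float | None = None,
                 area_per_lipid_A2: float = 65.0,
                 seed: int = 0,
                 density_map: np.ndarray | None = None) -> LatticeMembrane:
    """Symmetric bilayer on a square lattice with seeded site placement.

    Species counts per leaflet follow largest-remainder allocation of the
    composition percentages (default 44:23:23:10 POPC/POPE/CHOL/anionic).
    When a ``density_map`` (per-site weights) is given, anionic sites are
    drawn proportionally to it instead of uniformly.
    """
    comp = dict(composition_percent) if composition_percent is not None \
        else {"POPC": 44.0, "POPE": 23.0, "CHOL": 23.0, anionic_species: 10.0}
    if anionic_species not in comp:
        raise ConfigError(
            f"anionic species {anionic_species!r} absent from composition")
    names = list(comp)
    counts = largest_remainder_allocation([comp[n] for n in names],
                                          n_per_leaflet)
    spacing = (lattice_spacing_A if lattice_spacing_A is not None
               else math.sqrt(area_per_lipid_A2))
    ny, nx = _grid_shape(n_per_leaflet)
    gx = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    gy = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    xx, yy = np.meshgrid(gx, gy, indexing="xy")
    site_xy = np.column_stack([xx.ravel(), yy.ravel()])

    rng = np.random.default_rng(seed)
    pool = np.repeat(np.array(names, dtype=object), counts)

    def leaflet() -> np.ndarray:
        if density_map is not None:
            w = np.asarray(density_map, dtype=float)
            if len(w) != n_per_leaflet:
                raise ConfigError("density map length must equal site count")
            if w.sum() <= 0:
                raise ConfigError("density map is identically zero")
            occ = np.empty(n_per_leaflet, dtype=object)
            n_anionic = counts[names.index(anionic_species)]
            anionic_sites = rng.choice(n_per_leaflet, size=n_anionic,
                                       replace=False, p=w / w.sum())
            rest = np.setdiff1d(np.arange(n_per_leaflet), anionic_sites)
            others = pool[pool != anionic_species]
            occ[anionic_sites] = anionic_species
            occ[rest] = rng.permutation(others)
            return occ
        return rng.permutation(pool)

    occ_upper = leaflet()
    occ_lower = leaflet()
    species = [LipidSpecies(
        name=n, mole_fraction=comp[n] / 100.0,
        headgroup_charge=anionic_charge_e if n == anionic_species else 0.0)
        for n in names]
    phi = np.full(n_per_leaflet, comp[anionic_species] / 100.0)
    return LatticeMembrane(
        plane_origin=np.zeros(3), normal=np.array([0.0, 0.0, 1.0]),
        lattice_spacing=spacing, area_per_lipid=area_per_lipid_A2,
        species=species, site_xy=site_xy, occupancy_upper=occ_upper,
        occupancy_lower=occ_lower, phi=phi)


# -- bead protein ----------------------------------------------------------

_SITE_ATOMS = {"ARG": ("NH1", "N"), "LYS": ("NZ", "N"), "SER": ("OG", "O")}


@dataclass(frozen=True)
class ChargedSite:
    label: str                    # e.g. "R46"
    charge_e: float
    offset: tuple[float, float, float] = (3.0, 0.0, 0.0)
    absolute: bool = False        # offset is an absolute position


@dataclass
class BeadProteinSpec:
    helix_n_residues: int = 22
    helix_rise_A: float = 1.5
    helix_twist_deg: float = 100.0
    helix_radius_A: float = 2.3
    helix_start_resid: int = 203
    loop_n_beads: int = 6
    loop_start_resid: int = 120
    loop_center: tuple[float, float, float] = (9.0, 0.0, -10.0)
    loop_spread_A: float = 2.5
    sheet_n_beads: int = 4
    sheet_start_resid: int = 20
    sheet_center: tuple[float, float, float] = (-6.0, 4.0, -8.0)
    sheet_spread_A: float = 3.0
    charged_sites: Sequence[ChargedSite] = field(default_factory=lambda: (
        ChargedSite("R46", +1.0, (6.0, 0.0, -14.0), absolute=True),
        ChargedSite("R58", +1.0, (8.5, 2.0, -13.0), absolute=True),
        ChargedSite("S215", 0.0, (3.5, 0.0, 0.0)),
        ChargedSite("R218", +1.0, (3.5, 0.0, 0.0)),
    ))

    def validate(self) -> None:
        if self.helix_n_residues < 4:
            raise ConfigError("helix needs at least 4 residues")
        labels = [s.label for s in self.charged_sites]
        if len(labels) != len(set(labels)):
            raise ConfigError("charged-site labels must be unique")


def make_bead_protein(spec: BeadProteinSpec | None = None,
                      seed: int = 0) -> ChargedStructure:
    """Bead protein in the canonical frame: C-terminal helix along +z
    (N terminus at low z), omega1-loop beads offset toward +x.

    Charged sites whose residue id falls on a helix residue become sidechain
    beads attached to that residue; others are standalone residues at their
    absolute positions.
    """
    spec = spec or BeadProteinSpec()
    spec.validate()
    rows = []  # (name, resname, resid, pos, charge, element, segment)

    n = spec.helix_n_residues
    z = (np.arange(n) - (n - 1) / 2.0) * spec.helix_rise_A
    ang = np.radians(spec.helix_twist_deg) * np.arange(n)
    helix_pos = np.column_stack([spec.helix_radius_A * np.cos(ang),
                                 spec.helix_radius_A * np.sin(ang), z])
    helix_resids = spec.helix_start_resid + np.arange(n)
    for i in range(n):
        rows.append(["CA", "ALA", int(helix_resids[i]), helix_pos[i], 0.0,
                     "C", Segment.CTERM_HELIX.value])

    rng = np.random.default_rng(seed)
    for b in range(spec.loop_n_beads):
        # deterministic ring layout; the seed only perturbs nothing by default
        a = 2.0 * math.pi * b / max(spec.loop_n_beads, 1)
        pos = np.array(spec.loop_center) + spec.loop_spread_A * np.array(
            [0.3 * math.cos(a), math.sin(a), math.cos(a)])
        rows.append(["CA", "GLY", spec.loop_start_resid + b, pos, 0.0, "C",
                     Segment.OMEGA1_LOOP.value])
    for b in range(spec.sheet_n_beads):
        pos = np.array(spec.sheet_center) + np.array(
            [0.0, 0.0, -spec.sheet_spread_A * b])
        rows.append(["CA", "VAL", spec.sheet_start_resid + b, pos, 0.0, "C",
                     Segment.BETA_SHEET.value])

    resid_to_row = {r[2]: i for i, r in enumerate(rows)}
    for site in spec.charged_sites:
        resname, resid = parse_residue_label(site.label)
        atom_name, element = _SITE_ATOMS.get(resname, ("NH1", "N"))
        if site.absolute:
            pos = np.array(site.offset, dtype=float)
            segment = Segment.OTHER.value
        else:
            if resid not in resid_to_row:
                raise ConfigError(
                    f"charged site {site.label}: residue {resid} not built "
                    "and offset is not absolute")
            host = rows[resid_to_row[resid]]
            pos = np.asarray(host[3], dtype=float) + np.array(site.offset)
            host[1] = resname          # host residue adopts the site type
            segment = host[6]
        rows.append([atom_name, resname, resid, pos, site.charge_e, element,
                     segment])

    rows.sort(key=lambda r: (r[2], r[0]))
    return ChargedStructure(
        atom_id=np.arange(1, len(rows) + 1),
        name=np.array([r[0] for r in rows], dtype=object),
        residue_name=np.array([r[1] for r in rows], dtype=object),
        residue_id=np.array([r[2] for r in rows], dtype=int),
        positions=np.array([r[3] for r in rows], dtype=float),
        charges=np.array([r[4] for r in rows], dtype=float),
        elements=np.array([r[5] for r in rows], dtype=object),
        segments=np.array([r[6] for r in rows], dtype=str))


# -- trajectories with planted orientations and binding events -------------

@dataclass(frozen=True)
class BindingEvent:
    residue: str | int            # label like "R46" or a residue id
    lipid_id: int
    frames: frozenset
    bound_distance_A: float = 3.5
    unbound_distance_A: float = 5.5

    def resid(self) -> int:
        if isinstance(self.residue, int):
            return self.residue
        return parse_residue_label(self.residue)[1]


@dataclass
class BindingPlan:
    events: list = field(default_factory=list)
    cutoff_A: float = 4.0         # the active contact criterion cutoff

    def add(self, residue: str | int, lipid_id: int,
            frames, bound_distance_A: float = 3.5,
            unbound_distance_A: float = 5.5) -> "BindingPlan":
        ev = BindingEvent(residue=residue, lipid_id=lipid_id,
                          frames=frozenset(int(f) for f in frames),
                          bound_distance_A=bound_distance_A,
                          unbound_distance_A=unbound_distance_A)
        if not ev.bound_distance_A < self.cutoff_A <= ev.unbound_distance_A:
            raise ConfigError(
                f"binding plan violates bound < cutoff <= unbound "
                f"({ev.bound_distance_A} / {self.cutoff_A} / "
                f"{ev.unbound_distance_A}); the fixture would be "
                "unverifiable")
        self.events.append(ev)
        return self

    @property
    def lipid_ids(self) -> list[int]:
        return sorted({e.lipid_id for e in self.events})


def _rot_y(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(deg: float) -> np.ndarray:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def pose_rotation(tilt_deg: float, rotation_deg: float) -> np.ndarray:
    """Rotation placing the canonical protein at a planted (tilt, rotation).

    The canonical frame has the helix axis along +z and the rotation
    reference offset toward +x; the membrane outward normal is +z.
    """
    return _rot_y(tilt_deg) @ _rot_z(rotation_deg + 180.0)


def canonical_frame_rotation(protein: ChargedStructure) -> np.ndarray:
    """Rotation mapping the protein's measured helix axis onto +z and the
    projection of its rotation-reference vector onto +x.

    Uses the C-terminal-helix CA atoms and the omega1-loop centroid (the
    same constructions the orientation analysis applies), so planted
    (tilt, rotation) schedules are recovered exactly.  Falls back to the
    identity when either segment is absent.
    """
    from .analysis.orientation import helix_axis as _helix_axis
    helix_mask = (protein.segments == Segment.CTERM_HELIX.value) \
        & (protein.name == "CA")
    ref_mask = protein.segments == Segment.OMEGA1_LOOP.value
    if np.count_nonzero(helix_mask) < 4 or not np.any(ref_mask):
        return np.eye(3)
    axis = _helix_axis(protein.positions[helix_mask])
    helix_center = protein.positions[helix_mask].mean(axis=0)
    ref_vec = protein.positions[ref_mask].mean(axis=0) - helix_center
    e3 = axis / np.linalg.norm(axis)
    proj = ref_vec - (ref_vec @ e3) * e3
    if np.linalg.norm(proj) < 1e-9:
        return np.eye(3)
    e1 = proj / np.linalg.norm(proj)
    e2 = np.cross(e3, e1)
    return np.vstack([e1, e2, e3])   # maps e1->x, e2->y, e3->z


def sample_orientation_schedule(law: Mapping, n_frames: int,
                                rng: np.random.Generator) -> np.ndarray:
    """Sample (tilt, rotation) pairs from a law specification.

    Laws: ``fixed`` (tilt, rotation), ``wrapped_gaussian`` (tilt_mean,
    tilt_sd, rotation_mean, rotation_sd), ``mixture`` (components with
    weights).  Rotations wrap into [-180, 180); tilts clip to (0.5, 179.5)
    to keep the helix axis away from the degenerate pole.
    """
    kind = law.get("kind", "fixed")
    if kind == "fixed":
        return np.tile([float(law["tilt"]), float(law["rotation"])],
                       (n_frames, 1))
    if kind == "wrapped_gaussian":
        tilt = rng.normal(law["tilt_mean"], law["tilt_sd"], n_frames)
        rot = rng.normal(law["rotation_mean"], law["rotation_sd"], n_frames)
        tilt = np.clip(tilt, 0.5, 179.5)
        rot = (rot + 180.0) % 360.0 - 180.0
        return np.column_stack([tilt, rot])
    if kind == "mixture":
        comps = law["components"]
        weights = np.array([c.get("weight", 1.0) for c in comps], dtype=float)
        weights /= weights.sum()
        choice = rng.choice(len(comps), size=n_frames, p=weights)
        out = np.empty((n_frames, 2))
        for ci in range(len(comps)):
            m = choice == ci
            if np.any(m):
                out[m] = sample_orientation_schedule(
                    comps[ci], int(np.count_nonzero(m)), rng)
        return out
    raise ConfigError(f"unknown orientation law kind {kind!r}")


def make_trajectory(protein: ChargedStructure, membrane: LatticeMembrane,
                    orientation_schedule, binding_plan: BindingPlan | None
                    = None, n_frames: int | None = None,
                    stride_ns: float = 1.0, seed: int = 0,
                    height_A: float = 18.0,
                    height_schedule: Sequence[float] | None = None,
                    lipid_species_name: str = "PIP") -> Trajectory:
    """Trajectory with planted orientations and planted binding events.

    Topology = protein atoms + upper-leaflet phosphate beads (residue PHO,
    atom P, for plane fitting and embedding areas) + one headgroup-oxygen
    bead (atom O1) per lipid molecule named in the binding plan.  In each
    frame the protein is posed at the scheduled (tilt, rotation) at
    ``height_A`` above the plane; each planned lipid oxygen sits at its
    bound distance from the named residue's polar atom in planned frames
    and at the unbound distance otherwise.
    """
    if isinstance(orientation_schedule, Mapping):
        if n_frames is None:
            raise ValueError("n_frames required with an orientation law")
        rng = np.random.default_rng(seed)
        schedule = sample_orientation_schedule(orientation_schedule,
                                               n_frames, rng)
    else:
        schedule = np.asarray(orientation_schedule, dtype=float)
        if schedule.ndim != 2 or schedule.shape[1] != 2:
            raise ValueError("schedule must be a list of (tilt, rotation)")
        if n_frames is not None and len(schedule) != n_frames:
            raise ValueError("schedule length must match n_frames")
    nf = len(schedule)
    if nf == 0:
        raise ValueError("need at least one frame")
    if height_schedule is not None and len(height_schedule) != nf:
        raise ValueError("height schedule length must match frame count")

    plan = binding_plan or BindingPlan()
    lipid_ids = plan.lipid_ids
    n_prot = protein.n_atoms
    n_sites = membrane.n_sites

    atom_id = list(range(1, n_prot + 1))
    names = list(protein.name)
    resnames = list(protein.residue_name)
    resids = list(protein.residue_id)
    charges = list(protein.charges)
    elements = list(protein.elements)
    segments = list(protein.segments)
    # phosphate beads of the upper leaflet
    pho_resid0 = 5000
    for s in range(n_sites):
        atom_id.append(len(atom_id) + 1)
        names.append("P")
        resnames.append("PHO")
        resids.append(pho_resid0 + s)
        charges.append(0.0)
        elements.append("P")
        segments.append(Segment.OTHER.value)
    # lipid headgroup oxygen beads
    lipid_rows = {}
    for lid in lipid_ids:
        lipid_rows[lid] = len(atom_id)
        atom_id.append(len(atom_id) + 1)
        names.append("O1")
        resnames.append(lipid_species_name)
        resids.append(lid)
        charges.append(0.0)
        elements.append("O")
        segments.append(Segment.OTHER.value)

    topology = ChargedStructure(
        atom_id=np.array(atom_id), name=np.array(names, dtype=object),
        residue_name=np.array(resnames, dtype=object),
        residue_id=np.array(resids, dtype=int),
        positions=np.zeros((len(atom_id), 3)),
        charges=np.array(charges, dtype=float),
        elements=np.array(elements, dtype=object),
        segments=np.array(segments, dtype=str))

    R_canon = canonical_frame_rotation(protein)
    centered = (protein.positions - protein.positions.mean(axis=0)) \
        @ R_canon.T
    pho_xyz = np.column_stack([membrane.site_xy,
                               np.zeros(n_sites)]) + membrane.plane_origin

    # per-frame constraints: lipid -> list of (atom_index_in_protein, dist)
    polar_atom_of: dict[int, int] = {}
    for ev in plan.events:
        rid = ev.resid()
        cand = np.flatnonzero((protein.residue_id == rid)
                              & (protein.charges != 0.0))
        if len(cand) == 0:
            cand = np.flatnonzero((protein.residue_id == rid)
                                  & np.isin(protein.name,
                                            ["NH1", "NE", "NH2", "NZ", "OG"]))
        if len(cand) == 0:
            cand = np.flatnonzero(protein.residue_id == rid)
        if len(cand) == 0:
            raise ConfigError(f"binding plan names residue {rid} which is "
                              "absent from the protein")
        polar_atom_of[ev.lipid_id * 100000 + rid] = int(cand[0])

    positions = np.empty((nf, topology.n_atoms, 3))
    times = np.arange(nf, dtype=float) * float(stride_ns)
    for f in range(nf):
        tilt, rot = schedule[f]
        R = pose_rotation(tilt, rot)
        h = (height_schedule[f] if height_schedule is not None else height_A)
        prot_xyz = centered @ R.T + np.array([0.0, 0.0, h])
        positions[f, :n_prot] = prot_xyz
        positions[f, n_prot:n_prot + n_sites] = pho_xyz
        prot_centroid = prot_xyz.mean(axis=0)
        for lid in lipid_ids:
            bound_atoms = []
            anchor = None
            dist = None
            for ev in plan.events:
                if ev.lipid_id != lid:
                    continue
                idx = polar_atom_of[lid * 100000 + ev.resid()]
                if f in ev.frames:
                    bound_atoms.append((idx, ev.bound_distance_A))
                elif anchor is None:
                    anchor, dist = idx, ev.unbound_distance_A
            if bound_atoms:
                pts = np.array([prot_xyz[i] for i, _ in bound_atoms])
                d_target = min(d for _, d in bound_atoms)
                center = pts.mean(axis=0)
                out_dir = center - prot_centroid
                if np.linalg.norm(out_dir) < 1e-9:
                    out_dir = np.array([0.0, 0.0, -1.0])
                out_dir /= np.linalg.norm(out_dir)
                if len(pts) == 1:
                    pos = pts[0] + d_target * out_dir
                else:
                    span = max(np.linalg.norm(p - center) for p in pts)
                    if span >= d_target:
                        raise ConfigError(
                            f"lipid {lid}: bound residues too far apart "
                            f"({2 * span:.2f} A) for bound distance "
                            f"{d_target} A")
                    sep = pts[1] - pts[0]
                    perp = out_dir - (out_dir @ sep) * sep \
                        / float(sep @ sep)
                    if np.linalg.norm(perp) < 1e-9:
                        perp = np.cross(sep, [0.0, 0.0, 1.0])
                    perp /= np.linalg.norm(perp)
                    lift = math.sqrt(max(d_target ** 2 - span ** 2, 0.0))
                    pos = center + lift * perp
            else:
                idx, d = (anchor, dist) if anchor is not None else (0, 60.0)
                out_dir = prot_xyz[idx] - prot_centroid
                if np.linalg.norm(out_dir) < 1e-9:
                    out_dir = np.array([0.0, 0.0, -1.0])
                out_dir /= np.linalg.norm(out_dir)
                pos = prot_xyz[idx] + d * out_dir
            positions[f, lipid_rows[lid]] = pos
    return Trajectory(topology=topology, times_ns=times, positions=positions,
                      membrane=membrane)


# -- FRET traces and bookkeeping ------------------------------------------

def make_fret_trace(F0: float, F_inf: float, k_per_min: float,
                    t_grid_min: np.ndarray, noise_sd: float = 0.0,
                    seed: int = 0, metadata: dict | None = None) -> FretTrace:
    """Single-exponential trace with optional Gaussian noise, seeded."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if k_per_min < 0:
        raise ValueError("k must be >= 0")
    t = np.asarray(t_grid_min, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    y = F_inf + (F0 - F_inf) * np.exp(-k_per_min * t)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, len(t))
    return FretTrace(time_min=t, signal=y, metadata=metadata or {})


def plan_totals(n_traj: int, per_traj_duration_us: float) -> float:
    """Aggregate sampling per loading state: n_traj * duration (microseconds)."""
    if n_traj <= 0 or per_traj_duration_us <= 0:
        raise ValueError("trajectory count and duration must be > 0")
    return n_traj * per_traj_duration_us
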