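"""Contact criterion boundaries, brute-force equivalence, planted
probabilities, shared-site occlusion, and pooling equivalence."""

import numpy as np
import pytest

from memfield.analysis.contacts import (ContactCriterion, ContactTable,
                                        binding_probability_table,
                                        parse_residue_label,
                                        residue_lipid_contacts)
from memfield.core.structure import ChargedStructure
from memfield.core.trajectory import Trajectory, concatenate
from memfield.errors import SelectionError
from memfield.synth import (BeadProteinSpec, BindingPlan, make_bead_protein,
                            make_bilayer, make_trajectory)


def build_frame(res_atoms, lipid_atoms):
    """res_atoms: (resname, resid, atomname, xyz); lipids: (lipid_id, xyz)."""
    rows = []
    for resname, rid, aname, xyz in res_atoms:
        rows.append((aname, resname, rid, xyz, "N"))
    for lid, xyz in lipid_atoms:
        rows.append(("O1", "PIP", lid, xyz, "O"))
    n = len(rows)
    return ChargedStructure(
        atom_id=np.arange(1, n + 1),
        name=np.array([r[0] for r in rows], dtype=object),
        residue_name=np.array([r[1] for r in rows], dtype=object),
        residue_id=np.array([r[2] for r in rows], dtype=int),
        positions=np.array([r[3] for r in rows], dtype=float),
        charges=np.zeros(n),
        elements=np.array([r[4] for r in rows], dtype=object),
        segments=np.array(["other"] * n, dtype=str))


CRIT = ContactCriterion()


def test_parse_residue_label():
    assert parse_residue_label("R46") == ("ARG", 46)
    assert parse_residue_label("K52") == ("LYS", 52)
    assert parse_residue_label("S215") == ("SER", 215)
    with pytest.raises(ValueError):
        parse_residue_label("X9")


@pytest.mark.parametrize("distance,expected", [(3.99, True), (4.0, True),
                                               (4.01, False)])
def test_cutoff_boundary_inclusive(distance, expected):
    frame = build_frame([("LYS", 7, "NZ", [0.0, 0.0, 0.0])],
                        [(100, [distance, 0.0, 0.0])])
    bound = residue_lipid_contacts(frame, CRIT, [7], ["PIP"])
    assert (100 in bound[7]) is expected


def test_bruteforce_equivalence_on_random_frames():
    rng = np.random.default_rng(12)
    for _ in range(100):
        n_res = int(rng.integers(1, 5))
        res_atoms = []
        for k in range(n_res):
            rid = 10 + k
            res_atoms.append(("ARG", rid, "NH1",
                              rng.uniform(-10, 10, 3)))
            res_atoms.append(("ARG", rid, "NE", rng.uniform(-10, 10, 3)))
        n_lip = int(rng.integers(1, 8))
        lipids = [(100 + j, rng.uniform(-10, 10, 3)) for j in range(n_lip)]
        frame = build_frame(res_atoms, lipids)
        got = residue_lipid_contacts(frame, CRIT, [10 + k for k in
                                                   range(n_res)], ["PIP"])
        # brute force all-pairs oracle
        for k in range(n_res):
            rid = 10 + k
            atoms = [np.asarray(a[3]) for a in res_atoms if a[1] == rid]
            expect = set()
            for lid, lxyz in lipids:
                for axyz in atoms:
                    if np.linalg.norm(np.asarray(lxyz) - axyz) <= 4.0:
                        expect.add(lid)
                        break
            assert got[rid] == expect


def test_unresolvable_atom_names_error():
    frame = build_frame([("HIS", 3, "ND1", [0, 0, 0])], [(100, [1, 0, 0])])
    with pytest.raises(SelectionError, match="HIS"):
        residue_lipid_contacts(frame, CRIT, [3], ["PIP"])
    with pytest.raises(SelectionError, match="species"):
        residue_lipid_contacts(frame, CRIT, [3], ["XXX"])


@pytest.fixture()
def protein_and_membrane():
    return (make_bead_protein(BeadProteinSpec()),
            make_bilayer(n_per_leaflet=36, lattice_spacing_A=8.0))


def test_planted_bound_probability(protein_and_membrane):
    protein, mem = protein_and_membrane
    plan = BindingPlan().add("R46", 7, range(30))
    traj = make_trajectory(protein, mem, {"kind": "fixed", "tilt": 45.0,
                                          "rotation": 30.0},
                          binding_plan=plan, n_frames=100)
    table = binding_probability_table(traj, CRIT, [46], ["PIP"])
    row = table.per_residue.set_index("residue_id").loc[46]
    assert row["p_bound"] == pytest.approx(0.30)
    assert row["p_two_or_more"] == 0.0


def test_planted_multiplicity(protein_and_membrane):
    protein, mem = protein_and_membrane
    plan = (BindingPlan()
            .add("R46", 7, range(70))
            .add("R46", 8, range(70)))
    traj = make_trajectory(protein, mem, {"kind": "fixed", "tilt": 45.0,
                                          "rotation": 30.0},
                          binding_plan=plan, n_frames=100)
    table = binding_probability_table(traj, CRIT, [46], ["PIP"])
    row = table.per_residue.set_index("residue_id").loc[46]
    assert row["p_bound"] == pytest.approx(0.70)
    assert row["p_two_or_more"] == pytest.approx(0.70)
    assert row["mean_multiplicity"] == pytest.approx(1.40)


def test_shared_site_occlusion_construction(protein_and_membrane):
    # every lipid binding R58 is simultaneously bound to R46
    protein, mem = protein_and_membrane
    plan = BindingPlan()
    for f in range(40):
        plan.add("R58", 7, [f])
        plan.add("R46", 7, [f])
    plan.add("R46", 8, range(40, 60))     # R46-only extra binding
    traj = make_trajectory(protein, mem, {"kind": "fixed", "tilt": 45.0,
                                          "rotation": 30.0},
                          binding_plan=plan, n_frames=100)
    table = binding_probability_table(traj, CRIT, [46, 58], ["PIP"],
                                      shared_pairs=[(46, 58)])
    pr = table.per_residue.set_index("residue_id")
    p_shared = table.per_pair.iloc[0]["p_shared"]
    assert pr.loc[58, "p_bound"] == pytest.approx(0.40)
    assert p_shared == pytest.approx(pr.loc[58, "p_bound"])
    assert pr.loc[46, "p_bound"] >= pr.loc[58, "p_bound"]
    # no frame with R58-only binding
    for i in range(traj.n_frames):
        bound = residue_lipid_contacts(traj.frame(i), CRIT, [46, 58],
                                       ["PIP"])
        assert bound[58] <= bound[46]


def test_contact_table_invariants_enforced():
    import pandas as pd
    with pytest.raises(ValueError):
        ContactTable(per_residue=pd.DataFrame(
            [{"residue_id": 1, "p_bound": 0.2, "p_two_or_more": 0.3,
              "mean_multiplicity": 0.4}]),
            per_pair=pd.DataFrame(columns=["residue_a", "residue_b",
                                           "p_shared"]),
            n_frames=10)


def test_empty_trajectory_rejected(protein_and_membrane):
    protein, mem = protein_and_membrane
    with pytest.raises(ValueError):
        make_trajectory(protein, mem, [], binding_plan=None)


def test_pooling_equals_concatenation(protein_and_membrane):
    protein, mem = protein_and_membrane
    plan_a = BindingPlan().add("R46", 7, range(10))
    plan_b = BindingPlan().add("R46", 7, range(25))
    kw = dict(n_frames=50, stride_ns=1.0)
    ta = make_trajectory(protein, mem, {"kind": "fixed", "tilt": 45.0,
                                        "rotation": 30.0},
                         binding_plan=plan_a, **kw)
    tb = make_trajectory(protein, mem, {"kind": "fixed", "tilt": 45.0,
                                        "rotation": 30.0},
                         binding_plan=plan_b, **kw)
    pooled = binding_probability_table(concatenate([ta, tb]), CRIT, [46],
                                       ["PIP"])
    pa = binding_probability_table(ta, CRIT, [46], ["PIP"])
    pb = binding_probability_table(tb, CRIT, [46], ["PIP"])
    got = pooled.per_residue.iloc[0]["p_bound"]
    want = (pa.per_residue.iloc[0]["p_bound"] * 50
            + pb.per_residue.iloc[0]["p_bound"] * 50) / 100
    assert got == pytest.approx(want)
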