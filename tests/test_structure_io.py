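import numpy as np
import pytest

from memfield.core.pdbio import (read_charge_table, read_structure,
                                 read_trajectory, write_structure,
                                 write_trajectory)
from memfield.core.structure import (Segment, apply_charge_table,
                                     apply_default_charge_rule,
                                     assign_segments)
from memfield.core.trajectory import Trajectory, concatenate
from memfield.errors import ConfigError, ParseError, SelectionError
from memfield.synth import BeadProteinSpec, make_bead_protein

TOY_PDB = """\
ATOM      1  NH1 ARG A  46       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  NH2 ARG A  46       2.000   2.000   3.000  1.00  0.00           N
ATOM      3  NE  ARG A  46       1.500   3.000   3.000  1.00  0.00           N
END
"""


@pytest.fixture()
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


def test_read_toy_pdb_with_charge_table(toy_pdb):
    table = {("ARG", "NH1"): 0.33, ("ARG", "NH2"): 0.33, ("ARG", "NE"): 0.33}
    s = read_structure(toy_pdb, charges=table)
    assert s.n_atoms == 3
    assert s.net_charge == pytest.approx(0.99)
    assert np.allclose(s.positions[0], [1.0, 2.0, 3.0])


def test_charge_table_csv_roundtrip(toy_pdb, tmp_path):
    csv = tmp_path / "charges.csv"
    csv.write_text("residue_name,atom_name,charge\nARG,NH1,0.5\n")
    s = read_structure(toy_pdb, charges=csv)
    assert s.charges[list(s.name).index("NH1")] == 0.5
    assert read_charge_table(csv) == {("ARG", "NH1"): 0.5}


def test_strict_charge_table_rejects_unmatched(toy_pdb):
    s = read_structure(toy_pdb)
    with pytest.raises(SelectionError):
        apply_charge_table(s, {("LYS", "NZ"): 1.0}, strict=True)


def test_default_charge_rule():
    prot = make_bead_protein(BeadProteinSpec())
    ruled = apply_default_charge_rule(prot)
    # rule puts +1 on LYS NZ / ARG CZ only; bead ARGs carry NH1 atoms
    assert ruled.net_charge == 0.0


def test_segment_label_propagation(tmp_path):
    lines = []
    for i, rid in enumerate(range(200, 230)):
        lines.append(
            f"ATOM  {i + 1:5d}  CA  ALA A{rid:4d}    "
            f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
    path = tmp_path / "helix.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    s = read_structure(path)
    in_range = (s.residue_id >= 203) & (s.residue_id <= 224)
    assert np.all(s.segments[in_range] == Segment.CTERM_HELIX.value)
    assert np.all(s.segments[~in_range] == Segment.OTHER.value)


def test_assign_segments_rejects_overlap():
    with pytest.raises(ConfigError):
        assign_segments(np.array([10]), {"omega1_loop": [(5, 15)],
                                         "beta_sheet": [(12, 20)]})


def test_malformed_pdb_reports_line_number(tmp_path):
    path = tmp_path / "bad.pdb"
    path.write_text("ATOM      1  CA  ALA A   1       1.0\n")
    with pytest.raises(ParseError, match=":1:"):
        read_structure(path)


def test_structure_roundtrip_coordinates(tmp_path):
    # write -> read preserves coordinates to PDB precision (1e-3 A)
    rng = np.random.default_rng(7)
    for rep in range(100):
        n = int(rng.integers(3, 20))
        from conftest import make_probe
        s = make_probe(rng.uniform(-99, 99, (n, 3)).round(3),
                       np.zeros(n), names=["CA"] * n,
                       residue_names=["ALA"] * n,
                       residue_ids=np.arange(1, n + 1))
        path = tmp_path / f"s{rep}.pdb"
        write_structure(s, path)
        back = read_structure(path, use_default_charge_rule=False)
        assert np.allclose(back.positions, s.positions, atol=1.001e-3)


def test_trajectory_roundtrip(tmp_path):
    rng = np.random.default_rng(11)
    from conftest import make_probe
    for rep in range(10):
        n = int(rng.integers(4, 12))
        top = make_probe(rng.uniform(-50, 50, (n, 3)).round(3), np.zeros(n),
                         names=["CA"] * n, residue_names=["GLY"] * n,
                         residue_ids=np.arange(1, n + 1))
        nf = int(rng.integers(2, 6))
        coords = rng.uniform(-50, 50, (nf, n, 3)).round(3)
        traj = Trajectory(topology=top, times_ns=np.arange(nf) * 0.5,
                          positions=coords)
        top_path = tmp_path / f"top{rep}.pdb"
        trj_path = tmp_path / f"trj{rep}.pdb"
        write_structure(top, top_path)
        write_trajectory(traj, trj_path)
        back = read_trajectory(top_path, trj_path, stride_ns=0.5)
        assert back.n_frames == nf
        assert np.allclose(back.positions, coords, atol=1.001e-3)


def test_trajectory_stride_times(tmp_path):
    from conftest import make_probe
    top = make_probe([[0, 0, 0]], [0.0])
    traj = Trajectory(topology=top, times_ns=np.arange(5.0),
                      positions=np.zeros((5, 1, 3)))
    write_structure(top, tmp_path / "t.pdb")
    write_trajectory(traj, tmp_path / "m.pdb")
    back = read_trajectory(tmp_path / "t.pdb", tmp_path / "m.pdb",
                           stride_ns=0.1)
    assert np.allclose(back.times_ns, [0.0, 0.1, 0.2, 0.3, 0.4])


def test_trajectory_atom_count_mismatch(tmp_path):
    from conftest import make_probe
    top2 = make_probe([[0, 0, 0], [1, 0, 0]], [0.0, 0.0])
    top1 = make_probe([[0, 0, 0]], [0.0])
    traj = Trajectory(topology=top1, times_ns=[0.0],
                      positions=np.zeros((1, 1, 3)))
    write_structure(top2, tmp_path / "top2.pdb")
    write_trajectory(traj, tmp_path / "one.pdb")
    with pytest.raises(ParseError, match="frame 0"):
        read_trajectory(tmp_path / "top2.pdb", tmp_path / "one.pdb")


def test_zero_frame_trajectory_errors(tmp_path):
    from conftest import make_probe
    top = make_probe([[0, 0, 0]], [0.0])
    write_structure(top, tmp_path / "top.pdb")
    (tmp_path / "empty.pdb").write_text("END\n")
    with pytest.raises(ParseError):
        read_trajectory(tmp_path / "top.pdb", tmp_path / "empty.pdb")


def test_trajectory_invariants():
    from conftest import make_probe
    top = make_probe([[0, 0, 0]], [0.0])
    with pytest.raises(ValueError, match="increasing"):
        Trajectory(topology=top, times_ns=[0.0, 0.0],
                   positions=np.zeros((2, 1, 3)))
    with pytest.raises(ValueError, match="atom count"):
        Trajectory(topology=top, times_ns=[0.0],
                   positions=np.zeros((1, 2, 3)))


def test_concatenate_preserves_frames():
    from conftest import make_probe
    top = make_probe([[0, 0, 0]], [0.0])
    a = Trajectory(topology=top, times_ns=[0.0, 1.0],
                   positions=np.arange(6.0).reshape(2, 1, 3))
    b = Trajectory(topology=top, times_ns=[0.0, 1.0],
                   positions=10 + np.arange(6.0).reshape(2, 1, 3))
    pooled = concatenate([a, b])
    assert pooled.n_frames == 4
    assert np.all(np.diff(pooled.times_ns) > 0)
    assert np.allclose(pooled.positions[:2], a.positions)
    assert np.allclose(pooled.positions[2:], b.positions)
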