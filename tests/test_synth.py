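"""Synthetic generators: bilayer bookkeeping, bead protein geometry,
planted trajectories, FRET traces, plan totals."""

import numpy as np
import pytest

from memfield.analysis.membrane_frame import fit_membrane_plane
from memfield.analysis.orientation import frame_orientation, helix_axis
from memfield.core.structure import Segment
from memfield.errors import ConfigError
from memfield.synth import (BeadProteinSpec, BindingPlan, ChargedSite,
                            largest_remainder_allocation, make_bead_protein,
                            make_bilayer, make_fret_trace, make_trajectory,
                            plan_totals, sample_orientation_schedule)


class TestBilayer:
    def test_default_composition_counts(self):
        mem = make_bilayer(n_per_leaflet=200)
        assert mem.n_lipids == 400
        for occ in (mem.occupancy_upper, mem.occupancy_lower):
            counts = {s: int(np.sum(occ == s)) for s in
                      ("POPC", "POPE", "CHOL", "PIP2")}
            assert counts == {"POPC": 88, "POPE": 46, "CHOL": 46, "PIP2": 20}

    def test_half_half_allocation(self):
        counts = largest_remainder_allocation([50.0, 50.0, 0.0, 0.0], 10)
        assert counts == [5, 5, 0, 0]

    def test_allocation_sums_and_errors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            raw = rng.uniform(0.1, 1.0, 4)
            pct = 100.0 * raw / raw.sum()
            n = int(rng.integers(5, 400))
            counts = largest_remainder_allocation(pct, n)
            assert sum(counts) == n
            quotas = pct * n / 100.0
            assert all(abs(c - q) < 1.0 for c, q in zip(counts, quotas))
        with pytest.raises(ConfigError, match="100"):
            largest_remainder_allocation([60.0, 60.0], 10)

    def test_seed_determinism(self):
        a = make_bilayer(seed=7)
        b = make_bilayer(seed=7)
        c = make_bilayer(seed=8)
        assert np.array_equal(a.occupancy_upper, b.occupancy_upper)
        assert np.array_equal(a.occupancy_lower, b.occupancy_lower)
        assert not np.array_equal(a.occupancy_upper, c.occupancy_upper)

    def test_density_map_placement(self):
        w = np.zeros(100)
        w[:25] = 1.0
        mem = make_bilayer(n_per_leaflet=100, density_map=w, seed=1)
        anionic_sites = np.flatnonzero(mem.occupancy_upper == "PIP2")
        assert np.all(anionic_sites < 25)

    def test_phi_uniform_at_fraction(self):
        mem = make_bilayer(n_per_leaflet=200)
        assert np.allclose(mem.phi, 0.10)
        assert mem.total_anionic_amount == pytest.approx(
            0.10 * 200 * mem.site_area)


class TestBeadProtein:
    def test_helix_geometry(self):
        prot = make_bead_protein(BeadProteinSpec(helix_n_residues=22))
        ca = prot.positions[(prot.segments == Segment.CTERM_HELIX.value)
                            & (prot.name == "CA")]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.allclose(d, d[0], atol=1e-9)      # constant CA-CA spacing
        assert np.allclose(helix_axis(ca), [0, 0, 1], atol=1e-6)

    def test_zero_charged_sites_neutral(self):
        spec = BeadProteinSpec(charged_sites=())
        assert make_bead_protein(spec).net_charge == 0.0

    def test_duplicate_labels_rejected(self):
        spec = BeadProteinSpec(charged_sites=(
            ChargedSite("R46", 1.0, (0, 0, 0), absolute=True),
            ChargedSite("R46", 1.0, (1, 0, 0), absolute=True)))
        with pytest.raises(ConfigError, match="unique"):
            make_bead_protein(spec)

    def test_determinism(self):
        a = make_bead_protein(seed=3)
        b = make_bead_protein(seed=3)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.name, b.name)

    def test_site_attached_to_helix_residue(self):
        prot = make_bead_protein(BeadProteinSpec())
        r218 = prot.select(prot.residue_id == 218)
        assert set(r218.name) == {"CA", "NH1"}
        assert np.all(r218.residue_name == "ARG")
        assert r218.charges.sum() == 1.0


class TestTrajectory:
    def test_planted_orientation_roundtrip(self):
        prot = make_bead_protein(BeadProteinSpec())
        mem = make_bilayer(n_per_leaflet=36, lattice_spacing_A=8.0)
        traj = make_trajectory(prot, mem, [(45.0, 30.0)] * 20,
                               stride_ns=0.5)
        mask = traj.topology.residue_name == "PHO"
        for i in range(traj.n_frames):
            frame = traj.frame(i)
            origin, normal = fit_membrane_plane(
                frame.positions[mask],
                frame.positions[~mask].mean(axis=0))
            s = frame_orientation(frame, origin, normal)
            assert s.tilt_deg == pytest.approx(45.0, abs=1e-6)
            assert s.rotation_deg == pytest.approx(30.0, abs=1e-6)
        assert np.allclose(traj.times_ns, np.arange(20) * 0.5)

    def test_orientation_law_sampling(self):
        rng = np.random.default_rng(0)
        sched = sample_orientation_schedule(
            {"kind": "wrapped_gaussian", "tilt_mean": 60.0, "tilt_sd": 5.0,
             "rotation_mean": 0.0, "rotation_sd": 30.0}, 500, rng)
        assert sched.shape == (500, 2)
        assert 55 < sched[:, 0].mean() < 65
        assert np.all(sched[:, 1] >= -180) and np.all(sched[:, 1] < 180)
        mix = sample_orientation_schedule(
            {"kind": "mixture", "components": [
                {"kind": "fixed", "tilt": 30.0, "rotation": 0.0,
                 "weight": 0.5},
                {"kind": "fixed", "tilt": 120.0, "rotation": 0.0,
                 "weight": 0.5}]}, 400, rng)
        assert set(np.round(mix[:, 0]).astype(int)) == {30, 120}

    def test_empty_plan_all_probabilities_zero(self):
        from memfield.analysis.contacts import (ContactCriterion,
                                                binding_probability_table)
        prot = make_bead_protein(BeadProteinSpec())
        mem = make_bilayer(n_per_leaflet=36, lattice_spacing_A=8.0)
        traj = make_trajectory(prot, mem, [(45.0, 30.0)] * 10,
                               binding_plan=BindingPlan().add(
                                   "R46", 7, []))
        table = binding_probability_table(traj, ContactCriterion(), [46],
                                          ["PIP"])
        assert table.per_residue.iloc[0]["p_bound"] == 0.0

    def test_unverifiable_plan_rejected(self):
        with pytest.raises(ConfigError, match="unverifiable"):
            BindingPlan().add("R46", 7, [0], bound_distance_A=4.5)
        with pytest.raises(ConfigError, match="unverifiable"):
            BindingPlan().add("R46", 7, [0], unbound_distance_A=3.9)

    def test_seed_determinism(self):
        prot = make_bead_protein(BeadProteinSpec())
        mem = make_bilayer(n_per_leaflet=36, lattice_spacing_A=8.0)
        law = {"kind": "wrapped_gaussian", "tilt_mean": 60.0, "tilt_sd": 5.0,
               "rotation_mean": 0.0, "rotation_sd": 30.0}
        a = make_trajectory(prot, mem, law, n_frames=10, seed=4)
        b = make_trajectory(prot, mem, law, n_frames=10, seed=4)
        assert np.array_equal(a.positions, b.positions)


class TestFretTrace:
    def test_noiseless_exact(self):
        t = np.linspace(0, 5, 20)
        tr = make_fret_trace(1.0, 3.0, 0.7, t, noise_sd=0.0)
        assert np.allclose(tr.signal, 3.0 - 2.0 * np.exp(-0.7 * t))

    def test_zero_rate_constant_signal(self):
        t = np.linspace(0, 5, 20)
        tr = make_fret_trace(1.5, 9.0, 0.0, t, noise_sd=0.0)
        assert np.allclose(tr.signal, 1.5)

    def test_noise_sd_recovered(self):
        t = np.linspace(0, 10, 10_000)
        tr = make_fret_trace(1.0, 1.0, 0.0, t, noise_sd=0.05, seed=2)
        sd = np.std(tr.signal - 1.0)
        assert sd == pytest.approx(0.05, rel=0.05)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            make_fret_trace(1.0, 2.0, 0.5, np.linspace(0, 1, 5),
                            noise_sd=-0.1)


class TestPlanTotals:
    def test_study_bookkeeping(self):
        assert plan_totals(12, 2.2) == pytest.approx(26.4)

    def test_identity(self):
        assert plan_totals(1, 3.7) == pytest.approx(3.7)

    def test_embedding_phase(self):
        assert plan_totals(9, 5.5) == pytest.approx(49.5)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            plan_totals(0, 2.2)
        with pytest.raises(ValueError):
            plan_totals(12, -1.0)
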