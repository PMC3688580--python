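"""Coordinate I/O, Kabsch superposition, closure metrics and interactions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_

import glkit as g
from glkit.errors import InputError, PartitionError
from glkit.structure import (
    DomainPartition,
    default_tlgk_partition,
    interactions_to_tsv,
    rotation_angle,
)

from conftest import make_model


def rot_z(deg):
    t = np.radians(deg)
    return np.array([[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1.0]])


@pytest.fixture()
def cation_pi_fixture():
    """Arg202 guanidinium stacked 3.4 Å above the Tyr354 ring (the closed-
    state contact geometry), plus partition placing them in different domains."""
    ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    ring = np.column_stack([1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)])
    guan_names = ("CZ", "NH1", "NH2", "NE")
    local = np.array([[0.0, 0, 0], [-0.67, 1.15, 0], [-0.67, -1.15, 0], [1.33, 0, 0]])
    guan = local - local.mean(axis=0) + np.array([0.0, 0, 3.4])
    model = make_model(["A"] * 10, [202] * 4 + [354] * 6,
                       ["ARG"] * 4 + ["TYR"] * 6,
                       list(guan_names) + list(ring_names),
                       np.vstack([guan, ring]))
    part = DomainPartition({"small": [("A", 190, 210)], "large": [("A", 350, 360)]})
    return model, part


class TestLoadStructure:
    def test_minimal_fixture_atoms_and_elements(self, tmp_path):
        pdb = tmp_path / "three.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C\n"
            "ATOM      3  O   ALA A   1      12.050   8.209  -4.212  1.00  0.00           O\n"
            "END\n")
        model = g.load_structure(pdb)
        assert len(model) == 3
        assert model.element == ["N", "C", "O"]
        assert model.xyz[1, 0] == pytest.approx(11.639)

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "END\n")
        model = g.load_structure(pdb)
        assert len(model) == 1
        assert model.xyz[0, 0] == pytest.approx(9.0)
        assert model.occupancy[0] == pytest.approx(0.6)

    def test_missing_chain_lists_available(self, tmp_path):
        pdb = tmp_path / "x.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "END\n")
        with pytest.raises(InputError, match="available: A"):
            g.load_structure(pdb, chain="B")

    def test_round_trip_to_pdb_precision(self, tmp_path, two_domain):
        _, open_m, _, _ = two_domain
        path = tmp_path / "m.pdb"
        g.write_pdb(open_m, path)
        back = g.load_structure(path)
        assert len(back) == len(open_m)
        assert np.max(np.abs(back.xyz - open_m.xyz)) < 1e-3

    def test_unreadable_file_rejected(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a coordinate file\n")
        with pytest.raises(InputError):
            g.load_structure(bad)


class TestDomainPartition:
    def test_requires_large_and_small(self):
        with pytest.raises(PartitionError):
            DomainPartition({"big": [("A", 1, 10)], "small": [("A", 20, 30)]})

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(PartitionError):
            DomainPartition({"large": [("A", 1, 10)], "small": [("A", 5, 15)]})

    def test_cfg_round_trip(self, tmp_path):
        part = default_tlgk_partition()
        path = tmp_path / "p.cfg"
        path.write_text(part.to_cfg())
        back = DomainPartition.from_cfg(path.read_text())
        assert back.ranges == part.ranges

    def test_shipped_partition_covers_cluster_residues(self):
        """All small-domain cluster residues fall in 'small', all
        large-domain partners in 'large'."""
        part = default_tlgk_partition()
        for res in (46, 74, 115, 117, 188, 191, 202):
            assert part.domain_of("A", res) == "small"
        for res in (246, 354, 382, 386, 445, 446, 447):
            assert part.domain_of("A", res) == "large"


class TestDomainDistance:
    def test_two_single_atoms(self):
        model = make_model(["A", "A"], [1, 50], ["GLY", "GLY"], ["CA", "CA"],
                           [[0.0, 0, 0], [3.0, 4.0, 0]])
        part = DomainPartition({"large": [("A", 1, 10)], "small": [("A", 40, 60)]})
        assert g.domain_distance(model, part) == pytest.approx(5.0)

    def test_generator_separation_recovered(self, two_domain):
        _, open_m, closed_m, truth = two_domain
        part = truth["partition"]
        assert g.domain_distance(open_m, part) == pytest.approx(
            truth["separation_open"], abs=1e-9)
        assert g.domain_distance(closed_m, part) == pytest.approx(
            truth["separation_closed"], abs=1e-9)

    def test_empty_domain_rejected(self, two_domain):
        _, open_m, _, _ = two_domain
        part = DomainPartition({"large": [("A", 1, 10)], "small": [("A", 5000, 5010)]})
        with pytest.raises(PartitionError):
            g.domain_distance(open_m, part)


class TestKabsch:
    def test_identity_on_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(20, 3))
        rot, t, rmsd = g.superpose_kabsch(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-12)

    def test_recovers_constructed_rotation(self):
        pts = np.random.default_rng(1).normal(size=(40, 3)) * 7.0
        moved = pts @ rot_z(25.0).T + np.array([2.0, -1.0, 4.0])
        rot, t, rmsd = g.superpose_kabsch(moved, pts)
        assert rotation_angle(rot) == pytest.approx(25.0, abs=1e-6)
        assert rmsd < 1e-9

    def test_mirror_image_gets_proper_rotation(self):
        pts = np.random.default_rng(2).normal(size=(25, 3))
        mirror = pts * np.array([-1.0, 1.0, 1.0])
        rot, t, rmsd = g.superpose_kabsch(pts, mirror)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(InputError):
            g.superpose_kabsch(line, line + 1.0)
        with pytest.raises(InputError):
            g.superpose_kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_kabsch_beats_random_placements(self):
        """Optimality oracle: no random rigid placement does better."""
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(30, 3)) * 5
        mov = ref @ rot_z(40.0).T + 2.0 + rng.normal(scale=0.3, size=(30, 3))
        _, _, rmsd_opt = g.superpose_kabsch(ref, mov)
        for _ in range(100):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(0, np.pi)
            kx, ky, kz = axis
            k = np.array([[0, -kz, ky], [kz, 0, -kx], [-ky, kx, 0]])
            rr = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
            placed = mov @ rr.T + rng.normal(scale=2.0, size=3)
            rmsd_rand = np.sqrt(np.mean(np.sum((placed - ref) ** 2, axis=1)))
            assert rmsd_opt <= rmsd_rand + 1e-12


class TestInterdomainRotation:
    def test_self_rotation_is_zero(self, two_domain):
        _, open_m, _, truth = two_domain
        rot = g.interdomain_rotation(open_m, open_m, truth["partition"])
        # arccos loses half the precision near +1, so "zero" is ~1e-6 deg
        assert rot.angle_deg == pytest.approx(0.0, abs=1e-5)

    def test_recovers_12_degree_hinge(self, two_domain):
        _, open_m, closed_m, truth = two_domain
        rot = g.interdomain_rotation(open_m, closed_m, truth["partition"])
        assert rot.angle_deg == pytest.approx(12.0, abs=0.01)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(angle=st_.floats(min_value=1.0, max_value=60.0))
    def test_recovers_arbitrary_hinge_angles(self, angle):
        spec = g.TwoDomainSpec(hinge_angle_deg=angle, seed=5)
        open_m, closed_m, truth = g.gen_two_domain_model(spec)
        rot = g.interdomain_rotation(open_m, closed_m, truth["partition"])
        assert rot.angle_deg == pytest.approx(angle, abs=0.05)

    def test_jitter_degrades_gracefully(self):
        spec = g.TwoDomainSpec(hinge_angle_deg=12.0, jitter=0.2, seed=6)
        open_m, closed_m, truth = g.gen_two_domain_model(spec)
        rot = g.interdomain_rotation(open_m, closed_m, truth["partition"])
        assert rot.angle_deg == pytest.approx(12.0, abs=1.0)

    def test_too_few_common_atoms_rejected(self, two_domain):
        _, open_m, closed_m, truth = two_domain
        small = truth["partition"].ranges["small"][0]
        tiny = DomainPartition({
            "large": truth["partition"].ranges["large"],
            "small": [(small[0], small[1], small[1] + 4)]})
        with pytest.raises(InputError):
            g.interdomain_rotation(open_m, closed_m, tiny)


class TestClosureTrajectory:
    def test_monotone_distance_rg_and_contacts(self):
        """Closing trajectory: distance decreases, Rg decreases, attractive
        inter-domain contacts do not decrease."""
        spec = g.TwoDomainSpec(seed=11)
        frames, truth = g.gen_closing_trajectory(spec, n_frames=5)
        part = truth["partition"]
        dists = [g.domain_distance(f, part) for f in frames]
        rgs = [g.coords_rg(f).rg for f in frames]
        assert all(d1 > d2 for d1, d2 in zip(dists, dists[1:]))
        assert all(r1 > r2 for r1, r2 in zip(rgs, rgs[1:]))
        contacts = [len(g.detect_interactions(f, part)) for f in frames]
        assert all(c2 >= c1 for c1, c2 in zip(contacts, contacts[1:]))


class TestGroupDistance:
    def test_single_atom_groups(self):
        model = make_model(["A", "A"], [117, 382], ["ARG", "LYS"], ["NE", "NZ"],
                           [[0.0, 0, 0], [2.9, 0, 0]], elements=["N", "N"])
        d = g.group_distance(model, ("A", 117), ("NE",), ("A", 382), ("NZ",))
        assert d == pytest.approx(2.9)

    def test_group_vs_itself_zero(self, cation_pi_fixture):
        model, _ = cation_pi_fixture
        assert g.group_distance(model, ("A", 202), "guanidinium",
                                ("A", 202), "guanidinium") == 0.0

    def test_triangle_centroid_to_vertex(self):
        side = 3.0
        h = side * np.sqrt(3) / 2
        tri = np.array([[0.0, 0, 0], [side, 0, 0], [side / 2, h, 0]])
        model = make_model(["A"] * 4, [1] * 3 + [2], ["GLY"] * 3 + ["GLY"],
                           ["C1", "C2", "C3", "CA"],
                           np.vstack([tri, tri[0]]))
        d = g.group_distance(model, ("A", 1), ("C1", "C2", "C3"), ("A", 2), ("CA",))
        assert d == pytest.approx(side / np.sqrt(3), rel=1e-9)

    def test_missing_atoms_listed(self, cation_pi_fixture):
        model, _ = cation_pi_fixture
        with pytest.raises(InputError, match="NH1"):
            model_no = model.subset(np.array([a != "NH1" for a in model.atomname]))
            g.group_distance(model_no, ("A", 202), "guanidinium",
                             ("A", 354), "phenol_ring")


class TestDetectInteractions:
    def test_cation_pi_fixture_detected(self, cation_pi_fixture):
        model, part = cation_pi_fixture
        recs = g.detect_interactions(model, part, kinds=("cation_pi",))
        assert len(recs) == 1
        rec = recs[0]
        assert rec.kind == "cation_pi"
        assert (rec.resnum_a, rec.resnum_b) == (202, 354)
        assert rec.distance == pytest.approx(3.4, abs=1e-6)

    def test_lysine_pair_repulsive_at_4A(self):
        model = make_model(["A", "A"], [74, 246], ["LYS", "LYS"], ["NZ", "NZ"],
                           [[0.0, 0, 0], [4.0, 0, 0]], elements=["N", "N"])
        part = DomainPartition({"small": [("A", 70, 80)], "large": [("A", 240, 250)]})
        recs = g.detect_interactions(model, part, kinds=("repulsive_pair",))
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(4.0)

    def test_same_domain_pair_ignored(self):
        model = make_model(["A", "A"], [74, 78], ["LYS", "LYS"], ["NZ", "NZ"],
                           [[0.0, 0, 0], [4.0, 0, 0]], elements=["N", "N"])
        part = DomainPartition({"small": [("A", 70, 80)], "large": [("A", 240, 250)]})
        assert g.detect_interactions(model, part) == []

    def test_hbond_geometry_criteria(self):
        """Ser OG donor to backbone O at 2.8 Å with a trans antecedent is a
        bond; the same pair squeezed past 3.5 Å is not."""
        def build(d):
            return make_model(
                ["A"] * 3, [10, 10, 300], ["SER", "SER", "GLY"],
                ["CB", "OG", "O"],
                [[-1.4, 0, 0], [0.0, 0, 0], [d, 0, 0]],
                elements=["C", "O", "O"])
        part = DomainPartition({"small": [("A", 5, 15)], "large": [("A", 295, 305)]})
        assert len(g.detect_interactions(build(2.8), part, kinds=("hbond",))) == 1
        assert g.detect_interactions(build(3.8), part, kinds=("hbond",)) == []

    def test_rigid_motion_invariance(self, cation_pi_fixture):
        model, part = cation_pi_fixture
        before = g.detect_interactions(model, part)
        moved = model.transformed(rot_z(33.0), np.array([5.0, -2.0, 7.0]))
        after = g.detect_interactions(moved, part)
        assert len(before) == len(after)
        for b, a in zip(before, after):
            assert a.distance == pytest.approx(b.distance, abs=1e-9)

    def test_tsv_report(self, cation_pi_fixture, tmp_path):
        model, part = cation_pi_fixture
        recs = g.detect_interactions(model, part)
        path = tmp_path / "contacts.tsv"
        interactions_to_tsv(recs, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("kind\t")
        assert len(lines) == len(recs) + 1
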