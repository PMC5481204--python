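"""DNA geometry: pairing, helical axes, bend angle, flipping, contacts.

All structures are generated synthetic B-DNA fixtures; no downloads.
"""

import numpy as np
import pytest

from baseflip.bdna import (
    add_probe_atom,
    displace_residue,
    flip_base_out,
    make_bent_duplex,
    make_duplex,
    transform_structure,
    write_pdb,
)
from baseflip.geometry import (
    ContactCutoffs,
    NucleotideRef,
    bend_angle,
    detect_flipped_bases,
    find_base_pairs,
    fit_helical_axis,
    load_structure,
    pair_center,
    pair_distance,
    protein_dna_contacts,
)

SEQ12 = "ATGCATGCATGC"
SEQ24 = SEQ12 * 2


@pytest.fixture
def duplex12():
    return make_duplex(SEQ12)


class TestLoadStructure:
    def test_fixture_round_trip(self, duplex12, tmp_path):
        path = tmp_path / "duplex.pdb"
        write_pdb(duplex12, path)
        model = load_structure(path)
        chains = [c.name for c in model.model]
        assert chains == ["A", "B"]
        assert len(model.nucleotides()) == 24
        assert len(find_base_pairs(model)) == 12

    def test_missing_glycosidic_nitrogen_flagged_not_fatal(self, duplex12, tmp_path):
        path = tmp_path / "broken.pdb"
        write_pdb(duplex12, path)
        # drop the N9 line of residue A/1 (DA)
        lines = [
            ln
            for ln in path.read_text().splitlines()
            if not (ln.startswith("ATOM") and " N9 " in ln and " DA A   1" in ln)
        ]
        path.write_text("\n".join(lines) + "\n")
        model = load_structure(path)
        incomplete = model.incomplete_nucleotides()
        assert NucleotideRef("A", 1, "DA") in incomplete

    def test_unparseable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.cif"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            model = load_structure(bad)
            if not model.nucleotides() and len(model.model) == 0:
                raise ValueError("empty structure")


class TestFindBasePairs:
    def test_ideal_duplex_fully_paired(self, duplex12):
        pairs = find_base_pairs(duplex12)
        assert len(pairs) == 12
        for p in pairs:
            assert p.purine.seqid + p.pyrimidine.seqid == 13
            assert p.distance <= 3.5

    def test_displaced_terminal_base_unpaired(self, duplex12):
        displace_residue(duplex12, "A", 12, np.array([10.0, 0.0, 0.0]))
        pairs = find_base_pairs(duplex12)
        assert len(pairs) == 11
        assert not any(p.involves(NucleotideRef("A", 12, "DC")) for p in pairs)

    def test_no_nucleotide_in_two_pairs(self, duplex12):
        pairs = find_base_pairs(duplex12)
        seen = [r for p in pairs for r in (p.purine, p.pyrimidine)]
        assert len(seen) == len(set(seen))


class TestHelicalAxis:
    def test_collinear_points_exact(self):
        pts = np.outer(np.arange(5), [0.0, 0.0, 1.0]) + np.array([1.0, 2.0, 3.0])
        axis = fit_helical_axis(pts)
        assert axis.rms_residual == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.abs(axis.direction), [0, 0, 1], atol=1e-12)
        # oriented along input order
        assert axis.direction[2] > 0

    def test_straight_duplex_axis_parallel_to_construction_axis(self, duplex12):
        pairs = find_base_pairs(duplex12)
        centers = np.array([pair_center(duplex12, p) for p in pairs])
        axis = fit_helical_axis(centers)
        cos = abs(np.dot(axis.direction, [0.0, 0.0, 1.0]))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_two_points_rejected(self):
        with pytest.raises(ValueError):
            fit_helical_axis(np.zeros((2, 3)))


class TestBendAngle:
    def test_straight_duplex_is_unbent(self):
        dup = make_duplex(SEQ24)
        angle = bend_angle(dup, ("A", (1, 12)), ("A", (13, 24)))
        assert angle < 5.0

    def test_constructed_right_angle_recovered(self):
        bent = make_bent_duplex(SEQ24, 90.0)
        angle = bend_angle(bent, ("A", (1, 12)), ("A", (13, 24)))
        assert angle == pytest.approx(90.0, abs=2.0)

    @pytest.mark.parametrize("target", [30.0, 147.0])
    def test_other_bends_recovered(self, target):
        bent = make_bent_duplex(SEQ24, target)
        angle = bend_angle(bent, ("A", (1, 12)), ("A", (13, 24)))
        assert angle == pytest.approx(target, abs=2.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_motion_invariance(self, seed):
        bent = make_bent_duplex(SEQ24, 90.0)
        ref = bend_angle(bent, ("A", (1, 12)), ("A", (13, 24)))
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        transform_structure(bent, q, rng.normal(scale=20.0, size=3))
        moved = bend_angle(bent, ("A", (1, 12)), ("A", (13, 24)))
        assert moved == pytest.approx(ref, abs=1e-6)

    def test_short_arm_rejected(self, duplex12):
        with pytest.raises(ValueError):
            bend_angle(duplex12, ("A", (1, 2)), ("A", (3, 12)))


class TestDetectFlippedBases:
    def test_ideal_duplex_has_none(self, duplex12):
        assert detect_flipped_bases(duplex12) == []

    def test_flipped_base_flagged(self, duplex12):
        flip_base_out(duplex12, "A", 6, radius=12.0)
        pairs = find_base_pairs(duplex12)
        flipped = detect_flipped_bases(duplex12, pairs)
        assert flipped == [NucleotideRef("A", 6, "DT")]

    def test_unpaired_but_intra_helical_not_flagged(self, duplex12):
        # small displacement breaks the pair but stays near the axis
        displace_residue(duplex12, "A", 6, np.array([2.5, 0.0, 0.0]))
        pairs = find_base_pairs(duplex12)
        assert not any(p.involves(NucleotideRef("A", 6, "DT")) for p in pairs)
        assert detect_flipped_bases(duplex12, pairs) == []


class TestContacts:
    def probe_position(self, duplex, chain, seqid, distance):
        """Position at ``distance`` from one OP1 and > 4.05 A from every

        other polar atom, found by scanning candidate directions."""
        target = duplex.atom_position(chain, seqid, "OP1")
        others = []
        for ch in duplex.model:
            for res in ch:
                for a in res:
                    if a.element.name in ("N", "O"):
                        p = np.array(a.pos.tolist())
                        if np.linalg.norm(p - target) > 1e-9:
                            others.append(p)
        others = np.array(others)
        rng = np.random.default_rng(0)
        for _ in range(500):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            pos = target + distance * d
            if np.min(np.linalg.norm(others - pos, axis=1)) > 4.05:
                return pos
        raise AssertionError("no isolated probe direction found")

    def test_single_salt_bridge_detected(self, duplex12):
        add_probe_atom(duplex12, self.probe_position(duplex12, "A", 3, 2.9))
        contacts = protein_dna_contacts(duplex12)
        assert len(contacts) == 1
        assert contacts[0].kind == "salt-bridge"
        assert contacts[0].distance == pytest.approx(2.9, abs=1e-6)
        assert "OP1" in contacts[0].dna_atom

    def test_neutral_nitrogen_is_hydrogen_bond(self, duplex12):
        add_probe_atom(
            duplex12, self.probe_position(duplex12, "A", 3, 2.9),
            resname="TRP", atom_name="NE1",
        )
        contacts = protein_dna_contacts(duplex12)
        assert len(contacts) == 1
        assert contacts[0].kind == "h-bond"

    def test_out_of_range_probe_gives_no_contact(self, duplex12):
        add_probe_atom(duplex12, self.probe_position(duplex12, "A", 3, 4.2))
        assert protein_dna_contacts(duplex12) == []

    def test_salt_bridge_range_beyond_hbond(self, duplex12):
        # 3.8 A: beyond h-bond cutoff but within the salt-bridge cutoff
        add_probe_atom(duplex12, self.probe_position(duplex12, "A", 3, 3.8))
        contacts = protein_dna_contacts(duplex12)
        assert [c.kind for c in contacts] == ["salt-bridge"]
        assert protein_dna_contacts(
            duplex12, ContactCutoffs(hbond=3.5, salt_bridge=3.5)
        ) == []


class TestPairDistance:
    def test_identical_atom_zero(self, duplex12):
        assert pair_distance(duplex12, "A/3/P", "A/3/P") == 0.0

    def test_three_four_five_triangle(self, duplex12):
        add_probe_atom(duplex12, np.array([0.0, 0.0, 0.0]), chain="X", seqid=1)
        add_probe_atom(duplex12, np.array([3.0, 4.0, 0.0]), chain="Y", seqid=1)
        assert pair_distance(duplex12, "X/1/NZ", "Y/1/NZ") == pytest.approx(5.0)

    def test_unresolvable_selector_names_it(self, duplex12):
        with pytest.raises(ValueError, match="Z/9/QQ"):
            pair_distance(duplex12, "A/3/P", "Z/9/QQ")
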