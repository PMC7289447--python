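import numpy as np
import pytest

from cochap.simulate import generate_toy_complex
from cochap.structure import (
    Structure,
    charged_fraction,
    detect_hbonds,
    detect_ion_pairs,
    interface_contacts,
    pair_probability,
)


def make_structure(atoms):
    """atoms: list of (chain, res_id, res_name, atom_name, element, xyz)."""
    return Structure(
        chain_ids=np.array([a[0] for a in atoms]),
        res_ids=np.array([a[1] for a in atoms]),
        res_names=np.array([a[2] for a in atoms]),
        atom_names=np.array([a[3] for a in atoms]),
        elements=np.array([a[4] for a in atoms]),
        coords=np.array([a[5] for a in atoms], dtype=float),
    )


def two_carbons(distance):
    return make_structure([
        ("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0)),
        ("B", 1, "GLY", "CA", "C", (distance, 0.0, 0.0)),
    ])


def brute_force_contacts(s, cutoff=0.5):
    """Independent O(n^2) oracle over heavy-atom pairs across chains."""
    count = 0
    pairs = {}
    for i in range(s.n_atoms):
        if s.chain_ids[i] != "A" or s.elements[i] == "H":
            continue
        for j in range(s.n_atoms):
            if s.chain_ids[j] != "B" or s.elements[j] == "H":
                continue
            if np.linalg.norm(s.coords[i] - s.coords[j]) < cutoff:
                count += 1
                key = (
                    (str(s.chain_ids[i]), int(s.res_ids[i]), str(s.res_names[i])),
                    (str(s.chain_ids[j]), int(s.res_ids[j]), str(s.res_names[j])),
                )
                pairs[key] = pairs.get(key, 0) + 1
    return count, pairs


class TestContacts:
    def test_pair_below_cutoff_counts(self):
        rep = interface_contacts(two_carbons(0.49), "A", "B")
        assert rep.atom_contact_count == 1

    def test_boundary_is_strict(self):
        rep = interface_contacts(two_carbons(0.50), "A", "B")
        assert rep.atom_contact_count == 0

    def test_overlapping_selections_rejected(self):
        s = two_carbons(0.4)
        with pytest.raises(ValueError, match="overlap"):
            interface_contacts(s, "A", "A")

    def test_symmetric_up_to_label_swap(self):
        s, _ = generate_toy_complex(6, 11)
        ab = interface_contacts(s, "A", "B")
        ba = interface_contacts(s, "B", "A")
        assert ab.atom_contact_count == ba.atom_contact_count
        assert ab.interface_residues_a == ba.interface_residues_b

    def test_report_internally_consistent(self):
        s, _ = generate_toy_complex(8, 2)
        rep = interface_contacts(s, "A", "B")
        assert rep.atom_contact_count == sum(n for _, _, n in rep.residue_pairs)
        assert all(n >= 1 for _, _, n in rep.residue_pairs)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_ground_truth_and_brute_force(self, seed):
        s, truth = generate_toy_complex(4 + seed % 5, seed)
        rep = interface_contacts(s, "A", "B")
        count, pairs = brute_force_contacts(s)
        assert rep.atom_contact_count == count
        assert {(ra, rb): n for ra, rb, n in rep.residue_pairs} == pairs
        assert rep.residue_pairs == truth.planted_contacts

    def test_separated_chains_have_no_contacts(self):
        s, truth = generate_toy_complex(5, 1, separation=10.0)
        assert interface_contacts(s, "A", "B").atom_contact_count == 0
        assert truth.planted_contacts == []
        assert truth.planted_ion_pairs == []


class TestIonPairs:
    def test_planted_pair_reported_at_exact_distance(self):
        s, truth = generate_toy_complex(5, 4)
        pairs = detect_ion_pairs(s)
        assert len(pairs) == 1
        (pos, neg, dist), = truth.planted_ion_pairs
        assert pairs[0].positive == pos and pairs[0].negative == neg
        assert pairs[0].distance == pytest.approx(dist, abs=1e-12)

    def test_like_charges_not_reported(self):
        s = make_structure([
            ("A", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
            ("B", 1, "ARG", "NE", "N", (0.3, 0.0, 0.0)),
            ("B", 1, "ARG", "CZ", "C", (0.45, 0.0, 0.0)),
            ("B", 1, "ARG", "NH1", "N", (0.52, 0.0, 0.104)),
            ("B", 1, "ARG", "NH2", "N", (0.52, 0.0, -0.104)),
        ])
        assert detect_ion_pairs(s) == []

    def test_boundary_is_strict(self):
        s = make_structure([
            ("A", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
            ("B", 1, "ASP", "CG", "C", (0.51, 0.0, 0.0)),
            ("B", 1, "ASP", "OD1", "O", (0.51, 0.0, 0.09)),
            ("B", 1, "ASP", "OD2", "O", (0.51, 0.0, -0.09)),
        ])
        assert detect_ion_pairs(s, cutoff=0.5) == []
        assert len(detect_ion_pairs(s, cutoff=0.52)) == 1

    def test_incomplete_group_skipped_with_warning(self):
        s = make_structure([
            ("A", 1, "LYS", "NZ", "N", (0.0, 0.0, 0.0)),
            ("B", 1, "ASP", "CG", "C", (0.4, 0.0, 0.0)),
            ("B", 1, "ASP", "OD1", "O", (0.4, 0.0, 0.09)),
        ])
        with pytest.warns(UserWarning, match="missing"):
            assert detect_ion_pairs(s) == []


class TestHydrogenBonds:
    def test_planted_bond_reported(self):
        s, truth = generate_toy_complex(5, 6)
        bonds = detect_hbonds(s)
        assert len(bonds) == 1
        (donor, acceptor, dist, angle), = truth.planted_hbonds
        assert bonds[0].donor == donor and bonds[0].acceptor == acceptor
        assert bonds[0].distance == pytest.approx(dist, abs=1e-12)
        assert bonds[0].angle == pytest.approx(angle, abs=1e-9)

    def collinear(self, d, angle_deg):
        a = np.radians(angle_deg)
        return make_structure([
            ("A", 1, "GLY", "N", "N", (0.0, 0.0, 0.0)),
            ("A", 1, "GLY", "H", "H", (0.1 * np.sin(a), 0.1 * np.cos(a), 0.0)),
            ("B", 1, "GLY", "O", "O", (0.0, d, 0.0)),
        ])

    def test_collinear_bond_detected(self):
        bonds = detect_hbonds(self.collinear(0.30, 0.0))
        assert len(bonds) == 1
        assert bonds[0].angle == pytest.approx(0.0, abs=1e-9)

    def test_distance_cutoff(self):
        assert detect_hbonds(self.collinear(0.36, 0.0)) == []

    def test_angle_cutoff(self):
        assert detect_hbonds(self.collinear(0.30, 31.0)) == []
        assert len(detect_hbonds(self.collinear(0.30, 29.0))) == 1

    def test_no_hydrogens_downgrades_to_distance_only(self):
        s = make_structure([
            ("A", 1, "GLY", "N", "N", (0.0, 0.0, 0.0)),
            ("B", 1, "GLY", "O", "O", (0.0, 0.30, 0.0)),
        ])
        with pytest.warns(UserWarning, match="distance criterion only"):
            bonds = detect_hbonds(s)
        assert len(bonds) == 1
        assert bonds[0].angle is None


class TestPairProbability:
    def test_fraction_of_frames(self):
        frames = []
        for seed in range(10):
            sep = 0.0 if seed < 3 else 10.0
            frames.append(generate_toy_complex(4, seed, separation=sep)[0])
        p = pair_probability(frames, [("A", 1), ("B", 1)], detect_ion_pairs)
        assert p == pytest.approx(0.3)
        # brute-force frame-by-frame recount
        manual = np.mean([
            any(ip.key == frozenset({("A", 1), ("B", 1)}) for ip in detect_ion_pairs(f))
            for f in frames
        ])
        assert p == pytest.approx(manual)

    def test_always_present(self):
        frames = [generate_toy_complex(4, s)[0] for s in range(4)]
        assert pair_probability(frames, [("A", 1), ("B", 1)], detect_ion_pairs) == 1.0

    def test_empty_frames_rejected(self):
        with pytest.raises(ValueError):
            pair_probability([], [("A", 1), ("B", 1)], detect_ion_pairs)


class TestChargedFraction:
    @pytest.mark.parametrize(
        "names,expected",
        [
            (["ARG", "LYS", "ASP"], (2 / 3, 1 / 3)),
            (["GLY"] * 5, (0.0, 0.0)),
            (["ARG", "LYS", "ARG"], (1.0, 0.0)),  # helix-II basic triplet
        ],
    )
    def test_examples(self, names, expected):
        assert charged_fraction(names) == pytest.approx(expected)

    def test_histidine_uncharged_by_default(self):
        assert charged_fraction(["HIS", "ASP"]) == pytest.approx((0.0, 0.5))
        assert charged_fraction(["HIS", "ASP"], histidine_positive=True) == pytest.approx(
            (0.5, 0.5)
        )

    def test_unknown_residue_warns_uncharged(self):
        with pytest.warns(UserWarning):
            assert charged_fraction(["XYZ", "ARG"]) == pytest.approx((0.5, 0.0))
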