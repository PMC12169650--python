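"""Contact counting against a brute-force oracle, and the bound-state rule."""

import numpy as np
import pytest

from dnaadapt.contacts import (AtomSelection, ContactSpec, ContactSeries,
                               contact_density_2d, contact_series,
                               count_contacts, is_bound, qgr_minor_contacts,
                               select_atoms, trp_sugar_contacts, SUGAR_ATOMS)
from dnaadapt.structure import Atom, Ensemble, Residue, Structure
from dnaadapt.synthetic import (ProbeAtomSpec, build_probe_complex)


def brute_force_contacts(coords_a, coords_b, cutoff=4.5):
    """O(n^2) reference count of strictly-within-cutoff pairs."""
    n = 0
    for a in coords_a:
        for b in coords_b:
            if np.linalg.norm(a - b) < cutoff:
                n += 1
    return n


def _two_atom_structure(distance):
    prot = Residue("TRP", "P", 109, [])
    prot.add_atom(Atom("NE1", "N", np.zeros(3), 109, "P"))
    dna = Residue("DA", "A", 1, [])
    dna.add_atom(Atom("C1'", "C", np.array([distance, 0.0, 0.0]), 1, "A"))
    return Structure({"P": [prot], "A": [dna]})


ACCEPTOR_NAMES = ("N3", "O2", "O4'")


class TestCountContacts:
    spec = ContactSpec(AtomSelection(chain_ids=("P",)),
                       AtomSelection(chain_ids=("A",)), cutoff=4.5)

    @pytest.mark.parametrize("distance,expected", [(4.4, 1), (4.6, 0),
                                                   (4.5, 0)])
    def test_strict_cutoff(self, distance, expected):
        assert count_contacts(_two_atom_structure(distance), self.spec) == expected

    def test_symmetry(self, bform_duplex):
        cx = build_probe_complex(bform_duplex, [
            ProbeAtomSpec("NE1", "TRP", 109, ("A", 6, "C1'"), 4.0)])
        ab = ContactSpec(AtomSelection(chain_ids=("P",)),
                         AtomSelection(dna=True))
        ba = ContactSpec(AtomSelection(dna=True),
                         AtomSelection(chain_ids=("P",)))
        assert count_contacts(cx, ab) == count_contacts(cx, ba)

    def test_matches_brute_force_on_random_clouds(self):
        rng = np.random.default_rng(21)
        for trial in range(5):
            prot = Residue("GLY", "P", 1, [])
            dna = Residue("DA", "A", 1, [])
            pa = rng.uniform(-6, 6, size=(12, 3))
            pb = rng.uniform(-6, 6, size=(15, 3))
            for i, p in enumerate(pa):
                prot.add_atom(Atom(f"A{i + 1}", "C", p, 1, "P"))
            for i, p in enumerate(pb):
                dna.add_atom(Atom(f"B{i + 1}", "C", p, 1, "A"))
            s = Structure({"P": [prot], "A": [dna]})
            assert count_contacts(s, self.spec) == brute_force_contacts(pa, pb)

    def test_empty_selection_named_in_error(self, bform_duplex):
        spec = ContactSpec(AtomSelection(chain_ids=("Z",)),
                           AtomSelection(dna=True))
        with pytest.raises(ValueError, match="group_a"):
            count_contacts(bform_duplex, spec)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError, match="cutoff"):
            ContactSpec(AtomSelection(), AtomSelection(), cutoff=0.0)


class TestPaperCoordinates:
    def _bound_complex(self, bform_duplex, n_qgr=26):
        """A fixture with exactly n_qgr QGR-acceptor contacts and 2
        Trp-sugar contacts, verified by construction."""
        # sugar O4' acceptors are accessible enough for exact-count
        # placement; two of the 24 are reused (total pair count still adds)
        acceptors = [(res.chain_id, res.index, "O4'")
                     for res in bform_duplex if res.is_nucleotide]
        specs = []
        for k in range(n_qgr):
            specs.append(ProbeAtomSpec(f"C{k + 1}", "QGR", 112 + k % 3,
                                       acceptors[k % len(acceptors)], 4.0))
        # NE1 between two sugar atoms: 4.0 A from C1' toward C2'
        c1 = bform_duplex.strand_watson[5].atom("C1'").position
        c2 = bform_duplex.strand_watson[5].atom("C2'").position
        centroid = np.mean([a.position for a in bform_duplex.iter_atoms()],
                           axis=0)
        out = c1 - centroid
        out[2] = 0.0
        d = out / np.linalg.norm(out) + 0.35 * (c2 - c1) / np.linalg.norm(c2 - c1)
        specs.append(ProbeAtomSpec("NE1", "TRP", 109, ("A", 6, "C1'"), 4.0,
                                   direction=tuple(d)))
        return build_probe_complex(bform_duplex, specs,
                                   avoid_names=ACCEPTOR_NAMES)

    def test_qgr_count_equals_brute_force(self, bform_duplex):
        cx = self._bound_complex(bform_duplex)
        qgr_atoms = select_atoms(cx, AtomSelection(
            residue_numbers=(112, 113, 114), dna=False))
        acceptor_atoms = []
        for res in cx:
            if res.is_nucleotide:
                for n in ("O4'", "N3" if res.is_purine else "O2"):
                    if res.has_atom(n):
                        acceptor_atoms.append(res.atom(n).position)
        assert qgr_minor_contacts(cx) == brute_force_contacts(
            qgr_atoms, np.array(acceptor_atoms))
        assert qgr_minor_contacts(cx) == 26

    def test_trp_count_equals_brute_force(self, bform_duplex):
        cx = self._bound_complex(bform_duplex)
        ne1 = select_atoms(cx, AtomSelection(residue_numbers=(109,),
                                             atom_names=("NE1",), dna=False))
        sugars = select_atoms(cx, AtomSelection(dna=True,
                                                atom_names=SUGAR_ATOMS))
        assert trp_sugar_contacts(cx) == brute_force_contacts(ne1, sugars)
        assert trp_sugar_contacts(cx) >= 2

    def test_bound_rule_classifies_fixtures(self, bform_duplex):
        """C_minor-QGR > 25 with >= 2 Trp-sugar contacts means bound; a
        probe planted far away means unbound."""
        assert is_bound(self._bound_complex(bform_duplex, n_qgr=26))
        assert not is_bound(self._bound_complex(bform_duplex, n_qgr=25))

        far = []
        for k in range(27):
            far.append(ProbeAtomSpec(f"C{k + 1}", "QGR", 112 + k % 3,
                                     ("A", 6, "O4'"), 30.0 + k))
        far.append(ProbeAtomSpec("NE1", "TRP", 109, ("A", 6, "C1'"), 30.0))
        cx_far = build_probe_complex(bform_duplex, far)
        assert qgr_minor_contacts(cx_far) == 0
        assert trp_sugar_contacts(cx_far) == 0
        assert not is_bound(cx_far)

    def test_missing_residues_reported(self, bform_duplex):
        with pytest.raises(ValueError, match="QGR"):
            qgr_minor_contacts(bform_duplex)
        with pytest.raises(ValueError, match="NE1"):
            trp_sugar_contacts(bform_duplex)


class TestDensity:
    def test_single_frame_single_bin(self):
        H, qe, te = contact_density_2d(ContactSeries(np.array([26]),
                                                     np.array([2])))
        assert H.shape == (1, 1)
        assert H[0, 0] == 1.0

    def test_two_distinct_frames(self):
        H, _, _ = contact_density_2d(ContactSeries(np.array([26, 10]),
                                                   np.array([2, 0])))
        assert H.sum() == 1.0
        assert sorted(H.ravel()[H.ravel() > 0]) == [0.5, 0.5]

    def test_matches_multinomial_frequencies(self):
        rng = np.random.default_rng(31)
        q = rng.integers(0, 5, size=200)
        t = rng.integers(0, 3, size=200)
        H, qe, te = contact_density_2d(ContactSeries(q, t))
        assert H.sum() == pytest.approx(1.0, abs=1e-12)
        for qi in range(int(q.min()), int(q.max()) + 1):
            for ti in range(int(t.min()), int(t.max()) + 1):
                expected = np.mean((q == qi) & (t == ti))
                assert H[qi - q.min(), ti - t.min()] == pytest.approx(expected)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            contact_density_2d(ContactSeries(np.array([]), np.array([])))
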