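"""Domain model for DNA duplexes and protein-DNA complexes, with PDB I/O.

The model is deliberately small: atoms grouped into residues, residues into
chains, chains into a :class:`Structure`.  A :class:`DuplexStructure` is a
structure whose first two chains form an antiparallel Watson-Crick paired
DNA duplex; any further chains (e.g. a protein probe) ride along.  An
:class:`Ensemble` is a list of coordinate snapshots sharing one topology,
standing in for an MD trajectory.

PDB reading and writing is delegated to biotite; a light pre-scan provides
line-numbered errors for malformed records.  Only the PDB v3.3 dialect is
supported: alternate locations keep altLoc 'A' or blank, insertion codes
are rejected, hydrogens are optional and ignored by all geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .refbases import COMPLEMENT, PURINES

__all__ = [
    "Atom", "Residue", "NucleotideResidue", "Structure", "DuplexStructure",
    "Ensemble", "PDBParseError", "read_pdb", "write_pdb", "pair_strands",
]

_NUC_NAMES = {"DA": "A", "DT": "T", "DG": "G", "DC": "C",
              "A": "A", "T": "T", "G": "G", "C": "C"}
_SUGAR_RING = ("C1'", "C2'", "C3'", "C4'", "O4'")


class PDBParseError(ValueError):
    """Malformed PDB content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


def infer_element(atom_name: str) -> str:
    """Chemical element from a PDB v3.3 atom label (heavy atoms + H)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    return stripped[0].upper()


@dataclass
class Atom:
    """A single atom: PDB-convention name, element, position in Angstrom."""

    name: str
    element: str
    position: np.ndarray
    residue_index: int
    chain_id: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be nonempty")


@dataclass
class Residue:
    """A residue: ordered atoms addressed by name."""

    name: str
    chain_id: str
    index: int
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_name = {a.name: a for a in self.atoms}

    def add_atom(self, atom: Atom) -> None:
        self.atoms.append(atom)
        self._by_name[atom.name] = atom

    def has_atom(self, name: str) -> bool:
        return name in self._by_name

    def atom(self, name: str) -> Atom:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"residue {self.chain_id}:{self.index} ({self.name}) has no "
                f"atom {name!r}") from None

    @property
    def is_nucleotide(self) -> bool:
        return self.name.strip() in _NUC_NAMES

    @property
    def base_type(self) -> str:
        try:
            return _NUC_NAMES[self.name.strip()]
        except KeyError:
            raise ValueError(f"residue {self.name!r} is not a nucleotide") from None

    @property
    def is_purine(self) -> bool:
        return self.base_type in PURINES

    def missing_core_atoms(self) -> list[str]:
        """Sugar-ring / base-frame atoms a nucleotide must carry."""
        required = list(_SUGAR_RING)
        required += ["N9", "C4"] if self.is_purine else ["N1", "C2"]
        return [n for n in required if not self.has_atom(n)]


# alias kept for clarity at call sites dealing specifically with DNA
NucleotideResidue = Residue


class Structure:
    """Ordered chains of residues; the shared topology for ensembles."""

    def __init__(self, chains: dict[str, list[Residue]]):
        self.chains: dict[str, list[Residue]] = dict(chains)
        self.incomplete_residues: list[tuple[str, int, list[str]]] = []
        for chain in self.chains.values():
            for res in chain:
                if res.is_nucleotide:
                    missing = res.missing_core_atoms()
                    if missing:
                        self.incomplete_residues.append(
                            (res.chain_id, res.index, missing))

    def __iter__(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def iter_atoms(self) -> Iterator[Atom]:
        for res in self:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.iter_atoms()])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """A deep copy of this structure carrying new coordinates."""
        coords = np.asarray(coords, float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape ({self.n_atoms}, 3)")
        new_chains: dict[str, list[Residue]] = {}
        k = 0
        for cid, chain in self.chains.items():
            new_chain = []
            for res in chain:
                new_res = Residue(res.name, res.chain_id, res.index, [])
                for a in res.atoms:
                    new_res.add_atom(Atom(a.name, a.element, coords[k],
                                          a.residue_index, a.chain_id))
                    k += 1
                new_chain.append(new_res)
            new_chains[cid] = new_chain
        out = type(self).__new__(type(self))
        Structure.__init__(out, new_chains)
        if isinstance(self, DuplexStructure):
            out._finish_duplex(self.watson_chain_id, self.crick_chain_id,
                               list(self.pairs))
        return out

    def dna_chain_ids(self) -> list[str]:
        return [cid for cid, chain in self.chains.items()
                if chain and all(r.is_nucleotide for r in chain)]

    def protein_chain_ids(self) -> list[str]:
        return [cid for cid, chain in self.chains.items()
                if chain and not all(r.is_nucleotide for r in chain)]


class DuplexStructure(Structure):
    """Two antiparallel Watson-Crick paired strands, plus optional extras.

    Residues are indexed 1-based 5'->3' per strand; pair i couples Watson
    residue i with Crick residue L+1-i under the default rule.
    """

    def __init__(self, chains: dict[str, list[Residue]],
                 watson_chain_id: str | None = None,
                 crick_chain_id: str | None = None,
                 pairs: list[tuple[int, int]] | None = None):
        super().__init__(chains)
        dna = self.dna_chain_ids()
        if watson_chain_id is None or crick_chain_id is None:
            if len(dna) != 2:
                raise ValueError(
                    f"need exactly two DNA chains to form a duplex, found {dna}")
            watson_chain_id, crick_chain_id = dna[0], dna[1]
        self._finish_duplex(watson_chain_id, crick_chain_id, pairs)

    def _finish_duplex(self, watson_chain_id, crick_chain_id, pairs):
        self.watson_chain_id = watson_chain_id
        self.crick_chain_id = crick_chain_id
        if pairs is None:
            pairs = pair_strands(self, rule="index")
        self.pairs = pairs

    @property
    def strand_watson(self) -> list[Residue]:
        return self.chains[self.watson_chain_id]

    @property
    def strand_crick(self) -> list[Residue]:
        return self.chains[self.crick_chain_id]

    @property
    def length(self) -> int:
        return len(self.pairs)

    @property
    def sequence(self) -> str:
        return "".join(r.base_type for r in self.strand_watson)


class Ensemble:
    """Coordinate snapshots over one topology; times in ns, increasing."""

    def __init__(self, topology: Structure, coordinates: np.ndarray,
                 times: np.ndarray | None = None):
        coordinates = np.asarray(coordinates, float)
        if coordinates.ndim != 3 or coordinates.shape[1:] != (topology.n_atoms, 3):
            raise ValueError(
                f"coordinates must have shape (n_frames, {topology.n_atoms}, 3)")
        if coordinates.shape[0] == 0:
            raise ValueError("an ensemble needs at least one frame")
        if times is None:
            times = np.arange(coordinates.shape[0], dtype=float)
        times = np.asarray(times, float)
        if times.shape != (coordinates.shape[0],):
            raise ValueError("one time per frame required")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.topology = topology
        self.coordinates = coordinates
        self.times = times

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coordinates[i])

    def __iter__(self) -> Iterator[Structure]:
        for i in range(self.n_frames):
            yield self.frame(i)


def pair_strands(duplex: DuplexStructure | Structure,
                 rule: str = "index") -> list[tuple[int, int]]:
    """Watson-Crick pairing of the two strands of a duplex.

    ``rule="index"`` pairs Watson residue i with Crick residue L+1-i and
    verifies complementarity; ``rule="geometric"`` pairs by minimal
    C1'-C1' distance (greedy bijection) and then checks complementarity.
    """
    if isinstance(duplex, DuplexStructure):
        watson, crick = duplex.strand_watson, duplex.strand_crick
    else:
        dna = duplex.dna_chain_ids()
        if len(dna) < 2:
            raise ValueError(
                f"duplex pairing requires two DNA strands, found {len(dna)}")
        watson, crick = duplex.chains[dna[0]], duplex.chains[dna[1]]
    if not watson or not crick:
        raise ValueError("duplex pairing requires two non-empty strands")
    L = len(watson)
    if len(crick) != L:
        raise ValueError(
            f"strand lengths differ ({L} vs {len(crick)}); cannot pair")

    if rule == "index":
        pairs = [(i, L + 1 - i) for i in range(1, L + 1)]
    elif rule == "geometric":
        from scipy.optimize import linear_sum_assignment

        wc1 = np.array([r.atom("C1'").position for r in watson])
        cc1 = np.array([r.atom("C1'").position for r in crick])
        dist = np.linalg.norm(wc1[:, None, :] - cc1[None, :, :], axis=-1)
        # minimum total C1'-C1' distance bijection over complementary pairs
        allowed = np.array([[COMPLEMENT[w.base_type] == c.base_type
                             for c in crick] for w in watson])
        cost = np.where(allowed, dist, 1e9)
        rows, cols = linear_sum_assignment(cost)
        if not allowed[rows, cols].all():
            bad = int(rows[~allowed[rows, cols]][0]) + 1
            raise ValueError(
                f"no complementary geometric pairing exists (first "
                f"unmatched Watson index {bad})")
        pairs = sorted((int(w) + 1, int(c) + 1) for w, c in zip(rows, cols))
    else:
        raise ValueError(f"unknown pairing rule {rule!r}")

    for wi, ci in pairs:
        bw = watson[wi - 1].base_type
        bc = crick[ci - 1].base_type
        if COMPLEMENT[bw] != bc:
            raise ValueError(
                f"non-complementary pair at Watson index {wi}: {bw} vs {bc}")
    return pairs


# ---------------------------------------------------------------------------
# PDB I/O (biotite backend)
# ---------------------------------------------------------------------------

def _validate_pdb_lines(path: Path) -> None:
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError("truncated ATOM/HETATM record", ln)
            if line[26] != " ":
                raise PDBParseError(
                    f"insertion code {line[26]!r} not supported", ln)
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise PDBParseError(
                        f"unparseable {what} coordinate {line[lo:hi]!r}",
                        ln) from None


def _array_to_structure(arr) -> Structure:
    chains: dict[str, list[Residue]] = {}
    residues: dict[tuple[str, int], Residue] = {}
    for i in range(arr.array_length()):
        altloc = getattr(arr, "altloc_id", None)
        if altloc is not None and altloc[i] not in (".", "", " ", "A"):
            continue
        element = str(arr.element[i]).strip() or infer_element(arr.atom_name[i])
        if element == "H":
            continue
        cid = str(arr.chain_id[i])
        rid = int(arr.res_id[i])
        key = (cid, rid)
        if key not in residues:
            res = Residue(str(arr.res_name[i]).strip(), cid, rid, [])
            residues[key] = res
            chains.setdefault(cid, []).append(res)
        residues[key].add_atom(Atom(str(arr.atom_name[i]).strip(), element,
                                    np.array(arr.coord[i], float), rid, cid))
    # renumber nucleotides 1-based 5'->3' per chain, preserving file order
    for chain in chains.values():
        if chain and all(r.is_nucleotide for r in chain):
            for k, res in enumerate(chain, start=1):
                res.index = k
                for a in res.atoms:
                    a.residue_index = k
    return Structure(chains)


def read_pdb(path: str | Path) -> Structure | DuplexStructure | Ensemble:
    """Read a (multi-model) PDB file into the domain model.

    Single-model files yield a :class:`DuplexStructure` when the DNA chains
    form a complementary duplex, otherwise a plain :class:`Structure`;
    multi-model files yield an :class:`Ensemble`.  Residues missing required
    sugar/base atoms are listed in ``structure.incomplete_residues``.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_pdb_lines(path)
    pdb = PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(model=None, altloc="first")
    except Exception as exc:  # pragma: no cover - biotite internal failures
        raise PDBParseError(f"PDB parsing failed: {exc}") from exc

    topology = _array_to_structure(stack[0])
    if len(topology.dna_chain_ids()) == 2:
        try:
            topology = DuplexStructure(topology.chains)
        except ValueError:
            pass
    if stack.stack_depth() == 1:
        return topology
    return Ensemble(topology, np.stack([
        _array_to_structure(stack[m]).coords()
        for m in range(stack.stack_depth())]))


def write_pdb(structure: Structure | Ensemble, path: str | Path) -> Path:
    """Write a structure (single model) or ensemble (MODEL-delimited) PDB."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(structure, Ensemble):
        models = [structure.topology.with_coords(structure.coordinates[i])
                  for i in range(structure.n_frames)]
    else:
        models = [structure]
    if not models or models[0].n_atoms == 0:
        raise ValueError("cannot write an empty structure")

    def to_array(s: Structure):
        atoms = list(s.iter_atoms())
        residues = {id(a): r for r in s for a in r.atoms}
        arr = struc.AtomArray(len(atoms))
        arr.coord = np.array([a.position for a in atoms])
        arr.chain_id = np.array([a.chain_id for a in atoms])
        arr.res_id = np.array([a.residue_index for a in atoms])
        arr.res_name = np.array([residues[id(a)].name for a in atoms])
        arr.atom_name = np.array([a.name for a in atoms])
        arr.element = np.array([a.element for a in atoms])
        arr.hetero = np.zeros(len(atoms), bool)
        return arr

    pdb = PDBFile()
    if len(models) == 1:
        pdb.set_structure(to_array(models[0]))
    else:
        pdb.set_structure(struc.stack([to_array(m) for m in models]))
    path = Path(path)
    pdb.write(str(path))
    return path
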