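"""Protein-DNA contact counting and bound-state classification.

Two contact coordinates characterise minor-groove binding by the H-NS DNA
binding domain: the number of heavy-atom contacts between the QGR motif
(residues 112-114) and the DNA minor-groove acceptors (purine N3,
pyrimidine O2, sugar O4'), and the number of contacts between the Trp-109
NE1 atom and the deoxyribose atoms of the backbone.  A frame is classified
bound when the QGR count exceeds 25 while the Trp-sugar count is at least
2.  Contacts use a strict 4.5 Angstrom heavy-atom cutoff by default; both
the cutoff and the acceptor set are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .refbases import PURINES, PYRIMIDINES

__all__ = [
    "AtomSelection", "ContactSpec", "ContactSeries", "select_atoms",
    "count_contacts", "qgr_minor_contacts", "trp_sugar_contacts",
    "is_bound", "contact_series", "contact_density_2d",
    "DEFAULT_CUTOFF", "QGR_RESIDUES", "TRP_RESIDUE",
]

DEFAULT_CUTOFF = 4.5
QGR_RESIDUES = (112, 113, 114)
TRP_RESIDUE = 109
SUGAR_ATOMS = ("C1'", "C2'", "C3'", "C4'", "C5'", "O4'")


@dataclass(frozen=True)
class AtomSelection:
    """Declarative atom selection: all criteria given must match."""

    chain_ids: tuple[str, ...] | None = None
    residue_numbers: tuple[int, ...] | None = None
    residue_names: tuple[str, ...] | None = None
    atom_names: tuple[str, ...] | None = None
    dna: bool | None = None   # True: nucleotides only; False: non-nucleotides

    def describe(self) -> str:
        parts = [f"{k}={v}" for k, v in self.__dict__.items() if v is not None]
        return ", ".join(parts) or "all atoms"


@dataclass(frozen=True)
class ContactSpec:
    group_a: AtomSelection
    group_b: AtomSelection
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


def select_atoms(structure, sel: AtomSelection) -> np.ndarray:
    """Heavy-atom coordinates matching a selection; hydrogens excluded."""
    coords = []
    for res in structure:
        if sel.dna is not None and res.is_nucleotide is not sel.dna:
            continue
        if sel.chain_ids is not None and res.chain_id not in sel.chain_ids:
            continue
        if sel.residue_numbers is not None and res.index not in sel.residue_numbers:
            continue
        if sel.residue_names is not None and res.name not in sel.residue_names:
            continue
        for a in res.atoms:
            if a.element == "H":
                continue
            if sel.atom_names is not None and a.name not in sel.atom_names:
                continue
            coords.append(a.position)
    return np.array(coords).reshape(-1, 3)


def count_contacts(structure, spec: ContactSpec) -> int:
    """Number of (a, b) heavy-atom pairs closer than the cutoff (strict)."""
    a = select_atoms(structure, spec.group_a)
    b = select_atoms(structure, spec.group_b)
    if a.shape[0] == 0:
        raise ValueError(f"empty selection: group_a ({spec.group_a.describe()})")
    if b.shape[0] == 0:
        raise ValueError(f"empty selection: group_b ({spec.group_b.describe()})")
    return int(np.count_nonzero(cdist(a, b) < spec.cutoff))


def _minor_groove_acceptor_coords(structure) -> np.ndarray:
    coords = []
    for res in structure:
        if not res.is_nucleotide:
            continue
        names = ["O4'"]
        names.append("N3" if res.base_type in PURINES else "O2")
        for n in names:
            if res.has_atom(n):
                coords.append(res.atom(n).position)
    return np.array(coords).reshape(-1, 3)


def qgr_minor_contacts(structure, cutoff: float = DEFAULT_CUTOFF) -> int:
    """Contacts between all QGR heavy atoms and minor-groove acceptors."""
    qgr = select_atoms(structure, AtomSelection(
        residue_numbers=QGR_RESIDUES, dna=False))
    if qgr.shape[0] == 0:
        raise ValueError(
            f"no protein atoms found for QGR residues {QGR_RESIDUES}")
    acceptors = _minor_groove_acceptor_coords(structure)
    if acceptors.shape[0] == 0:
        raise ValueError("no minor-groove acceptor atoms found")
    return int(np.count_nonzero(cdist(qgr, acceptors) < cutoff))


def trp_sugar_contacts(structure, cutoff: float = DEFAULT_CUTOFF) -> int:
    """Contacts between the Trp NE1 atom and deoxyribose sugar atoms."""
    ne1 = select_atoms(structure, AtomSelection(
        residue_numbers=(TRP_RESIDUE,), atom_names=("NE1",), dna=False))
    if ne1.shape[0] == 0:
        raise ValueError(f"NE1 atom of residue {TRP_RESIDUE} not found")
    sugars = select_atoms(structure, AtomSelection(
        dna=True, atom_names=SUGAR_ATOMS))
    if sugars.shape[0] == 0:
        raise ValueError("no sugar atoms found")
    return int(np.count_nonzero(cdist(ne1, sugars) < cutoff))


def is_bound(structure, cutoff: float = DEFAULT_CUTOFF,
             qgr_threshold: int = 25, trp_threshold: int = 2) -> bool:
    """Bound iff C_minor-QGR > 25 co-occurs with >= 2 Trp-sugar contacts."""
    return (qgr_minor_contacts(structure, cutoff) > qgr_threshold
            and trp_sugar_contacts(structure, cutoff) >= trp_threshold)


@dataclass
class ContactSeries:
    """Per-frame contact coordinates of an ensemble."""

    c_minor_qgr: np.ndarray
    c_sugar_trp: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(len(self.c_minor_qgr)),
            "C_minor_QGR": self.c_minor_qgr,
            "C_sugar_Trp": self.c_sugar_trp,
        })


def contact_series(ensemble, cutoff: float = DEFAULT_CUTOFF) -> ContactSeries:
    """Both contact coordinates for every frame of an ensemble."""
    qgr, trp = [], []
    for snap in ensemble:
        qgr.append(qgr_minor_contacts(snap, cutoff))
        trp.append(trp_sugar_contacts(snap, cutoff))
    return ContactSeries(np.array(qgr), np.array(trp))


def contact_density_2d(series: "ContactSeries | object",
                       cutoff: float = DEFAULT_CUTOFF,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised joint histogram over (C_minor_QGR, C_sugar_Trp).

    Accepts a :class:`ContactSeries` or an ensemble (counted on the fly).
    Bin edges are integers covering the observed ranges; the density sums
    to exactly 1.
    """
    if not isinstance(series, ContactSeries):
        series = contact_series(series, cutoff)
    q, t = series.c_minor_qgr, series.c_sugar_trp
    if len(q) == 0:
        raise ValueError("empty contact series")
    qe = np.arange(q.min(), q.max() + 2) - 0.5
    te = np.arange(t.min(), t.max() + 2) - 0.5
    H, _, _ = np.histogram2d(q, t, bins=(qe, te))
    return H / H.sum(), qe, te
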