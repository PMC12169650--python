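"""Sugar pucker, glycosidic torsion and A/B-form classification.

The deoxyribose ring conformation is summarised by the pseudorotation
phase P and amplitude nu_max (Altona-Sundaralingam): the five endocyclic
torsions obey ``nu_j = nu_max * cos(P + 144 deg * (j - 2))``, so

    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 * nu2 * (sin 36 + sin 72))

with nu_max = nu2 / cos P.  C2'-endo (South, P ~ 162 deg) typifies B-DNA,
C3'-endo (North, P ~ 18 deg) typifies A-DNA.  The glycosidic torsion chi
(O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for pyrimidines) separates the
anti region characteristic of A-DNA (~ -160 deg) from the high-anti region
characteristic of B-DNA (~ -100 deg).

Class boundaries are declared, configurable decisions: North is
P in [0, 90) u [270, 360), South is [90, 270); anti is chi in [-180, -120),
high-anti [-120, -60), syn [0, 90), everything else "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refbases import chi_reference_atoms

__all__ = [
    "dihedral", "pseudorotation", "classify_pucker", "chi_angle",
    "classify_chi", "fraction_profiles", "SugarConformation",
    "ConformationProfile", "ChiBoundaries", "sugar_conformation",
]

_SIN36_SIN72 = np.sin(np.radians(36.0)) + np.sin(np.radians(72.0))

# endocyclic torsion atom quadruples nu0..nu4 of the deoxyribose ring
_NU_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    IUPAC convention: looking along p2->p3, the angle is positive when the
    far bond is rotated clockwise from the near bond.  Raises ``ValueError``
    on collinear or zero-length bond vectors.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("collinear or coincident points: torsion undefined")
    ang = np.degrees(np.arctan2((np.cross(n1, n2) @ b2) / b2n, n1 @ n2))
    return 180.0 if ang <= -180.0 else float(ang)


def _ring_torsions(residue) -> np.ndarray:
    missing = [n for quad in _NU_ATOMS for n in quad if not residue.has_atom(n)]
    if missing:
        raise ValueError(
            f"residue {residue.chain_id}:{residue.index} is missing sugar "
            f"ring atoms: {sorted(set(missing))}")
    return np.array([
        dihedral(*(residue.atom(n).position for n in quad))
        for quad in _NU_ATOMS])


def pseudorotation_from_torsions(nu: np.ndarray) -> tuple[float, float]:
    """(P deg in [0,360), nu_max deg) from the five endocyclic torsions."""
    nu = np.asarray(nu, float)
    P = np.degrees(np.arctan2((nu[4] + nu[1]) - (nu[3] + nu[0]),
                              2.0 * nu[2] * _SIN36_SIN72))
    if P < 0:
        P += 360.0
    cosP = np.cos(np.radians(P))
    if abs(cosP) > 1e-6:
        nu_max = nu[2] / cosP
    else:
        # nu2 ~ 0 exactly at P = 90/270; recover the amplitude from
        # nu0 = nu_max cos(P - 288 deg)
        nu_max = nu[0] / np.cos(np.radians(P - 288.0))
    return float(P % 360.0), float(abs(nu_max))


def pseudorotation(residue) -> tuple[float, float]:
    """Pseudorotation phase P and amplitude nu_max of a deoxyribose ring."""
    return pseudorotation_from_torsions(_ring_torsions(residue))


def classify_pucker(P: float) -> str:
    """North for P in [0,90) u [270,360), South for [90,270)."""
    P = float(P) % 360.0
    return "South" if 90.0 <= P < 270.0 else "North"


def chi_angle(residue) -> float:
    """Glycosidic torsion chi in degrees (purine O4'-C1'-N9-C4, pyrimidine
    O4'-C1'-N1-C2)."""
    quad = chi_reference_atoms(residue.base_type)
    missing = [n for n in quad if not residue.has_atom(n)]
    if missing:
        raise ValueError(
            f"residue {residue.chain_id}:{residue.index} is missing chi "
            f"atoms: {missing}")
    return dihedral(*(residue.atom(n).position for n in quad))


@dataclass(frozen=True)
class ChiBoundaries:
    """Half-open class boundaries for the glycosidic torsion, degrees."""

    anti: tuple[float, float] = (-180.0, -120.0)
    high_anti: tuple[float, float] = (-120.0, -60.0)
    syn: tuple[float, float] = (0.0, 90.0)


def classify_chi(chi: float, boundaries: ChiBoundaries | None = None) -> str:
    """anti | high-anti | syn | other under half-open interval rules."""
    b = boundaries or ChiBoundaries()
    if b.anti[0] <= chi < b.anti[1]:
        return "anti"
    if b.high_anti[0] <= chi < b.high_anti[1]:
        return "high-anti"
    if b.syn[0] <= chi < b.syn[1]:
        return "syn"
    return "other"


@dataclass(frozen=True)
class SugarConformation:
    """Pucker and glycosidic descriptors of one nucleotide."""

    P: float
    nu_max: float
    pucker_class: str
    chi: float
    chi_class: str


def sugar_conformation(residue,
                       boundaries: ChiBoundaries | None = None,
                       ) -> SugarConformation:
    P, nu_max = pseudorotation(residue)
    chi = chi_angle(residue)
    return SugarConformation(P, nu_max, classify_pucker(P), chi,
                             classify_chi(chi, boundaries))


@dataclass
class ConformationProfile:
    """Per base-pair North / anti fractions over an ensemble."""

    fraction_north: np.ndarray
    fraction_anti: np.ndarray
    n_frames: int
    per_strand: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(1, len(self.fraction_north) + 1),
            "fraction_north": self.fraction_north,
            "fraction_anti": self.fraction_anti,
            "n_frames": self.n_frames,
        })


def fraction_profiles(ensemble, duplex=None, pool_strands: bool = True,
                      boundaries: ChiBoundaries | None = None,
                      ) -> ConformationProfile:
    """North-pucker and anti-chi fractions per base-pair position.

    By default the two paired residues are pooled, giving one fraction per
    pair; with ``pool_strands=False`` only the Watson residue of each pair
    is counted.  Fractions are exact ratios of integer counts.
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    topo = duplex if duplex is not None else ensemble.topology
    pairs = topo.pairs
    north = np.zeros(len(pairs), dtype=int)
    anti = np.zeros(len(pairs), dtype=int)
    for snap in ensemble:
        watson, crick = snap.strand_watson, snap.strand_crick
        for k, (wi, ci) in enumerate(pairs):
            residues = [watson[wi - 1]]
            if pool_strands:
                residues.append(crick[ci - 1])
            for res in residues:
                P, _ = pseudorotation(res)
                if classify_pucker(P) == "North":
                    north[k] += 1
                if classify_chi(chi_angle(res), boundaries) == "anti":
                    anti[k] += 1
    denom = ensemble.n_frames * (2 if pool_strands else 1)
    return ConformationProfile(north / denom, anti / denom,
                               ensemble.n_frames, not pool_strands)
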