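"""Embedded standard-base heavy-atom geometry.

Coordinates of the four DNA bases (plus the glycosidic C1') expressed in the
standard nucleic-acid reference frame: the base lies in the xy-plane with
the frame origin near the ring centre, x pointing toward the major groove
and y toward the strand-I backbone.  These are the fixture constants used
both by the frame-fitting extractor and by the structure builder, so the
builder/extractor pair is exact by construction.  Values follow the widely
used standard reference-frame convention for right-handed DNA (Angstrom).
"""

from __future__ import annotations

import numpy as np

__all__ = ["standard_base", "ring_atoms_for", "chi_reference_atoms",
           "PURINES", "PYRIMIDINES", "COMPLEMENT"]

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

_BASES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
}

_RING = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

# atoms defining the glycosidic torsion chi: O4'-C1'-N-C
_CHI = {
    "A": ("O4'", "C1'", "N9", "C4"),
    "G": ("O4'", "C1'", "N9", "C4"),
    "T": ("O4'", "C1'", "N1", "C2"),
    "C": ("O4'", "C1'", "N1", "C2"),
}


def standard_base(base_type: str) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates of a standard base in its reference frame."""
    try:
        raw = _BASES[base_type.upper()]
    except KeyError:
        raise ValueError(f"unknown base type {base_type!r}") from None
    return {name: np.array(xyz) for name, xyz in raw.items()}


def ring_atoms_for(base_type: str) -> tuple[str, ...]:
    """Names of the base ring atoms used for frame fitting."""
    return _RING[base_type.upper()]


def chi_reference_atoms(base_type: str) -> tuple[str, str, str, str]:
    """The four atoms of the glycosidic torsion for this base class."""
    return _CHI[base_type.upper()]
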