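"""Groove widths, local helical axis, and bend magnitude/direction.

Groove widths follow the refined cross-strand phosphate-phosphate distance
convention: for each position the minimal P-P distance over a small window
of cross-strand offsets, minus 5.8 Angstrom for the two phosphate van der
Waals radii.  The local helical axis at a step is the z-axis of the
mid-step frame, smoothed over a sliding window; the overall bend is the
angle between the averaged axes of the first and last windows, and the
bend direction is measured against the minor-groove vector (the -y axis of
the central pair frame).  Only relative changes between ensembles are
meaningful at the ~0.1 A / ~1 deg level; all outputs are rigid-body
invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rigidbase import Frame, duplex_parameters, step_parameters

__all__ = ["GrooveProfile", "BendDescriptor", "groove_widths",
           "helical_axis", "bend_descriptor"]

_VDW_CORRECTION = 5.8  # Angstrom, two phosphate van der Waals radii

# cross-strand phosphate offset windows (in pair indices, see groove_widths)
MINOR_OFFSETS = (-2, -3)
MAJOR_OFFSETS = (2, 3)


@dataclass
class GrooveProfile:
    """Minor/major groove widths per base-pair position (NaN where
    undefined near the termini)."""

    minor_width: np.ndarray
    major_width: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(1, len(self.minor_width) + 1),
            "minor_width": self.minor_width,
            "major_width": self.major_width,
        })


@dataclass
class BendDescriptor:
    """Overall axis bend (deg), per-step bend, and bend direction relative
    to the central minor-groove vector (deg)."""

    total_bend: float
    per_step_bend: np.ndarray
    bend_direction: float
    at_boundary: bool = False


def _phosphate_by_pair(duplex) -> tuple[dict[int, np.ndarray],
                                        dict[int, np.ndarray]]:
    """Phosphate positions keyed by the *pair index* their residue sits in."""
    w = {}
    for res in duplex.strand_watson:
        if res.has_atom("P"):
            w[res.index] = res.atom("P").position
    L = duplex.length
    c = {}
    for res in duplex.strand_crick:
        if res.has_atom("P"):
            c[L + 1 - res.index] = res.atom("P").position
    return w, c


def groove_widths(duplex, minor_offsets=MINOR_OFFSETS,
                  major_offsets=MAJOR_OFFSETS) -> GrooveProfile:
    """Refined P-P groove widths along the duplex.

    At pair i the minor width is ``min_j |P_W(i+1) - P_C(i+j)| - 5.8`` over
    ``j in minor_offsets`` (Crick phosphates indexed by the pair they belong
    to); the major width uses ``major_offsets``.  Positions whose phosphates
    are absent (termini) are NaN.
    """
    L = duplex.length
    pw, pc = _phosphate_by_pair(duplex)
    minor = np.full(L, np.nan)
    major = np.full(L, np.nan)
    for i in range(1, L + 1):
        if i + 1 in pw:
            for out, offsets in ((minor, minor_offsets), (major, major_offsets)):
                ds = [np.linalg.norm(pw[i + 1] - pc[i + j])
                      for j in offsets if i + j in pc]
                if ds:
                    out[i - 1] = min(ds) - _VDW_CORRECTION
    return GrooveProfile(minor, major)


def _pair_and_axis_frames(duplex) -> list[Frame]:
    _, _, pair_frames = duplex_parameters(duplex)
    return pair_frames


def helical_axis(duplex, window: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed local helical axis per step.

    Returns (points, vectors): mid-step origins and unit axis vectors, the
    latter averaged (vector mean, renormalised) over a sliding window of
    ``window`` steps centred on each step.  The raw local axis of a step is
    the z-axis of its mid-step frame.
    """
    pair_frames = _pair_and_axis_frames(duplex)
    n_steps = len(pair_frames) - 1
    if window < 1 or window > n_steps:
        raise ValueError(
            f"window {window} outside [1, {n_steps}] for this duplex")
    points = []
    raw = []
    for i in range(n_steps):
        _, mid = step_parameters(pair_frames[i], pair_frames[i + 1])
        points.append(mid.origin)
        raw.append(mid.z)
    raw = np.array(raw)
    half = window // 2
    vectors = np.empty_like(raw)
    for i in range(n_steps):
        lo = max(0, i - half)
        hi = min(n_steps, lo + window)
        lo = max(0, hi - window)
        v = raw[lo:hi].mean(axis=0)
        vectors[i] = v / np.linalg.norm(v)
    return np.array(points), vectors


def bend_descriptor(duplex, window: int = 3) -> BendDescriptor:
    """Overall helix-axis bend of one duplex snapshot.

    total_bend is the angle between the mean local axis over the first
    ``window`` steps and over the last ``window`` steps; per-step bend is
    sqrt(roll^2 + tilt^2); bend_direction is the signed angle from the
    central pair's minor-groove vector (-y of the pair frame) to the bend
    plane normal component, in the plane perpendicular to the entry axis.
    """
    pair_frames = _pair_and_axis_frames(duplex)
    n_steps = len(pair_frames) - 1
    if window < 1 or window > n_steps:
        raise ValueError(
            f"window {window} outside [1, {n_steps}] for this duplex")
    per_step = []
    raw_axes = []
    for i in range(n_steps):
        sp, mid = step_parameters(pair_frames[i], pair_frames[i + 1])
        per_step.append(np.hypot(sp.roll, sp.tilt))
        raw_axes.append(mid.z)
    raw_axes = np.array(raw_axes)
    a0 = raw_axes[:window].mean(axis=0)
    a0 /= np.linalg.norm(a0)
    a1 = raw_axes[-window:].mean(axis=0)
    a1 /= np.linalg.norm(a1)
    total = float(np.degrees(np.arccos(np.clip(a0 @ a1, -1.0, 1.0))))

    central = pair_frames[len(pair_frames) // 2]
    minor_vec = -central.y
    # component of the exit axis perpendicular to the entry axis defines
    # the bend plane; measure its angle from the minor-groove vector
    perp = a1 - (a1 @ a0) * a0
    if np.linalg.norm(perp) < 1e-9:
        direction = 0.0
    else:
        perp /= np.linalg.norm(perp)
        m = minor_vec - (minor_vec @ a0) * a0
        if np.linalg.norm(m) < 1e-9:
            direction = 0.0
        else:
            m /= np.linalg.norm(m)
            direction = float(np.degrees(np.arctan2(
                np.cross(m, perp) @ a0, m @ perp)))
    return BendDescriptor(total, np.array(per_step), direction)


def ensemble_bend(ensemble, window: int = 3) -> pd.DataFrame:
    """Bend descriptor statistics over an ensemble."""
    rows = []
    for i, snap in enumerate(ensemble):
        bd = bend_descriptor(snap, window=window)
        rows.append({"frame": i, "total_bend": bd.total_bend,
                     "bend_direction": bd.bend_direction})
    return pd.DataFrame(rows)
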