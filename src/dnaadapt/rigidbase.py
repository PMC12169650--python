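"""Rigid base-pair and base-step parameters.

Each DNA base (or base pair) carries a right-handed orthonormal frame.  The
relative geometry of two frames is expressed as six parameters: three
rotational and three translational.  For two bases of a pair these are
(buckle, propeller, opening) and (shear, stretch, stagger); for two
consecutive pair frames they are (tilt, roll, twist) and (shift, slide,
rise).  The decomposition follows the mid-frame scheme used by the standard
reference-frame convention for nucleic acids: the relative rotation
``R1^T R2`` is written as a z-y-z factorisation ``Rz(w/2-phi) Ry(G)
Rz(w/2+phi)`` with twist ``w = alpha+gamma``, hinge magnitude ``G`` and
hinge phase ``phi``; roll/propeller is ``G cos(phi)`` and tilt/buckle is
``G sin(phi)``.  Translations are expressed in the half-rotation mid-frame.

The decomposition has an exact closed-form inverse (`compose_step`,
`compose_pair`), which the synthetic structure builder uses; the round trip
is exact to machine precision and is enforced by the test suite.

Angles are radians internally and degrees at every public boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Frame",
    "PairParameters",
    "StepParameters",
    "fit_base_frame",
    "pair_parameters",
    "step_parameters",
    "compose_step",
    "compose_pair",
    "parameter_timeseries",
    "ParameterTimeseries",
]

# 180 deg rotation about x: applied to a Crick base frame before pairing so
# that two ideal coincident bases give all-zero pair parameters.
_FLIP_X = np.diag([1.0, -1.0, -1.0])

_STEP_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")
_PAIR_NAMES = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")


class DegenerateHingeError(ValueError):
    """Relative rotation too close to 180 deg for a stable mid-frame."""


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal orientation triad plus origin (Angstrom)."""

    rotation: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        o = np.asarray(self.origin, dtype=float)
        if R.shape != (3, 3) or o.shape != (3,):
            raise ValueError("Frame needs a 3x3 rotation and a 3-vector origin")
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(o)):
            raise ValueError("Frame components must be finite")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation columns are not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is improper (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "origin", o)

    @classmethod
    def identity(cls) -> "Frame":
        return cls(np.eye(3), np.zeros(3))

    @property
    def x(self) -> np.ndarray:
        return self.rotation[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.rotation[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.rotation[:, 2]

    def transform_points(self, points: np.ndarray) -> np.ndarray:
        """Map points given in this frame into the lab frame."""
        return np.asarray(points, float) @ self.rotation.T + self.origin

    def flipped(self) -> "Frame":
        """Frame rotated 180 deg about its own x-axis (strand II convention)."""
        return Frame(self.rotation @ _FLIP_X, self.origin)


@dataclass(frozen=True)
class PairParameters:
    """Intra-base-pair parameters: angles deg, translations Angstrom."""

    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float

    def as_array(self) -> np.ndarray:
        return np.array([self.shear, self.stretch, self.stagger,
                         self.buckle, self.propeller, self.opening])

    @classmethod
    def zero(cls) -> "PairParameters":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class StepParameters:
    """Base-pair step parameters: angles deg, translations Angstrom."""

    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_array(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise,
                         self.tilt, self.roll, self.twist])


def _rotz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _roty(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _wrap_pi(a: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    a = (a + np.pi) % (2.0 * np.pi) - np.pi
    return np.pi if a == -np.pi else a


def _axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _decompose(R1: np.ndarray, o1: np.ndarray, R2: np.ndarray,
               o2: np.ndarray) -> tuple[np.ndarray, Frame]:
    """Six parameters (3 transl, 3 rot, radians) and mid-frame from two frames.

    Geometric hinge construction: both frames are rotated by half the
    bending angle about the hinge axis (z1 x z2) so their z-axes coincide;
    the twist is the remaining rotation about the common z, and the hinge
    phase phi is measured from the mid-frame y-axis.  This keeps the
    (bend, phase, twist) triple on the branch inverted exactly by
    ``Rz(w/2-phi) Ry(G) Rz(w/2+phi)``.
    """
    z1, z2 = R1[:, 2], R2[:, 2]
    hinge = np.cross(z1, z2)
    hinge_norm = float(np.linalg.norm(hinge))
    # atan2 form is well conditioned for nearly parallel z-axes, where
    # arccos of the dot product loses ~half the significant digits
    beta = float(np.arctan2(hinge_norm, z1 @ z2))
    if np.degrees(beta) >= 179.0:
        raise DegenerateHingeError(
            f"bending angle {np.degrees(beta):.1f} deg >= 179 deg")
    if hinge_norm > 1e-12:
        hinge /= hinge_norm
        R1p = _axis_rotation(hinge, beta / 2.0) @ R1
        R2p = _axis_rotation(hinge, -beta / 2.0) @ R2
    else:
        beta = 0.0
        hinge = None
        R1p, R2p = R1, R2
    zm = R1p[:, 2]
    x1, x2 = R1p[:, 0], R2p[:, 0]
    omega = float(np.arctan2(np.cross(x1, x2) @ zm, x1 @ x2))
    if abs(np.degrees(omega)) >= 179.0:
        raise DegenerateHingeError(
            f"twist angle {np.degrees(omega):.1f} deg >= 179 deg")
    xm = x1 + x2
    xm /= np.linalg.norm(xm)
    ym = np.cross(zm, xm)
    if hinge is None:
        phi = 0.0
    else:
        # phase of the hinge measured from the mid-frame y-axis, signed so
        # that the (bend, phase, twist) triple inverts through the z-y-z form
        phi = float(np.arctan2(np.cross(hinge, ym) @ zm, ym @ hinge))
    roll_like = beta * np.cos(phi)
    tilt_like = beta * np.sin(phi)
    Rm = np.column_stack([xm, ym, zm])
    trans = Rm.T @ (o2 - o1)
    mid = Frame(Rm, 0.5 * (o1 + o2))
    return np.array([trans[0], trans[1], trans[2],
                     tilt_like, roll_like, omega]), mid


def _compose(R1: np.ndarray, o1: np.ndarray,
             params: np.ndarray) -> tuple[np.ndarray, np.ndarray, Frame]:
    """Exact inverse of :func:`_decompose` (params radians/Angstrom)."""
    dx, dy, dz, tilt_like, roll_like, omega = params
    beta = float(np.hypot(tilt_like, roll_like))
    phi = float(np.arctan2(tilt_like, roll_like)) if beta > 0 else 0.0
    alpha = omega / 2.0 - phi
    gamma = omega / 2.0 + phi
    R2 = R1 @ _rotz(alpha) @ _roty(beta) @ _rotz(gamma)
    Rm = R1 @ _rotz(alpha) @ _roty(beta / 2.0) @ _rotz(phi)
    o2 = o1 + Rm @ np.array([dx, dy, dz])
    mid = Frame(Rm, 0.5 * (o1 + o2))
    return R2, o2, mid


def step_parameters(pair_frame_i: Frame, pair_frame_j: Frame,
                    ) -> tuple[StepParameters, Frame]:
    """Step parameters between consecutive base-pair frames plus mid-step frame.

    Angles are returned in degrees, translations in Angstrom.  Raises
    :class:`DegenerateHingeError` when the relative rotation approaches 180 deg.
    """
    p, mid = _decompose(pair_frame_i.rotation, pair_frame_i.origin,
                        pair_frame_j.rotation, pair_frame_j.origin)
    return StepParameters(p[0], p[1], p[2], *np.degrees(p[3:6])), mid


def compose_step(pair_frame_i: Frame, params: StepParameters) -> Frame:
    """Frame of pair i+1 from the frame of pair i and step parameters."""
    p = params.as_array()
    p[3:6] = np.radians(p[3:6])
    R2, o2, _ = _compose(pair_frame_i.rotation, pair_frame_i.origin, p)
    return Frame(R2, o2)


def pair_parameters(frame_watson: Frame, frame_crick: Frame,
                    crick_is_flipped: bool = False,
                    ) -> tuple[PairParameters, Frame]:
    """Pair parameters from the two base frames, plus the base-pair frame.

    The Crick frame is rotated 180 deg about its x-axis before pairing
    (pass ``crick_is_flipped=True`` if it already is).  The returned
    mid-frame is the base-pair frame used for step parameters.
    """
    fc = frame_crick if crick_is_flipped else frame_crick.flipped()
    p, mid = _decompose(fc.rotation, fc.origin,
                        frame_watson.rotation, frame_watson.origin)
    return PairParameters(p[0], p[1], p[2], *np.degrees(p[3:6])), mid


def compose_pair(pair_frame: Frame, params: PairParameters,
                 ) -> tuple[Frame, Frame]:
    """Watson and Crick base frames realising ``params`` about ``pair_frame``.

    Exact inverse of :func:`pair_parameters`; the returned Crick frame is
    un-flipped (its z-axis points along the Crick base normal).
    """
    p = params.as_array()
    p[3:6] = np.radians(p[3:6])
    dx, dy, dz, tilt_like, roll_like, omega = p
    beta = float(np.hypot(tilt_like, roll_like))
    phi = float(np.arctan2(tilt_like, roll_like)) if beta > 0 else 0.0
    alpha = omega / 2.0 - phi
    gamma = omega / 2.0 + phi
    Rm = pair_frame.rotation
    om = pair_frame.origin
    # invert Rm = R1 Rz(alpha) Ry(beta/2) Rz(phi)
    R1 = Rm @ _rotz(-phi) @ _roty(-beta / 2.0) @ _rotz(-alpha)
    R2 = R1 @ _rotz(alpha) @ _roty(beta) @ _rotz(gamma)
    t = Rm @ np.array([dx, dy, dz])
    o1 = om - 0.5 * t
    o2 = om + 0.5 * t
    crick = Frame(R1 @ _FLIP_X, o1)   # un-flip
    watson = Frame(R2, o2)
    return watson, crick


def fit_base_frame(residue, reference: dict[str, np.ndarray] | None = None,
                   ) -> Frame:
    """Fit the standard-base reference frame to an observed base.

    Least-squares superposition (proper rotation only) of the embedded
    standard base ring atoms onto the observed heavy atoms; the returned
    frame is the standard base's own frame carried along by the fit.
    """
    from .refbases import ring_atoms_for, standard_base

    if reference is None:
        reference = standard_base(residue.base_type)
        names = [n for n in ring_atoms_for(residue.base_type)
                 if residue.has_atom(n)]
    else:
        names = [n for n in reference if residue.has_atom(n)]
    if len(names) < 3:
        raise ValueError(
            f"residue {residue.chain_id}:{residue.index} has fewer than 3 "
            f"matched base atoms ({names})")
    obs = np.array([residue.atom(n).position for n in names])
    std = np.array([reference[n] for n in names])
    mo, ms = obs.mean(axis=0), std.mean(axis=0)
    H = (std - ms).T @ (obs - mo)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    origin = mo - R @ ms
    return Frame(R, origin)


@dataclass
class ParameterTimeseries:
    """Per-frame rigid-base parameters of an ensemble.

    ``pair`` has shape (n_frames, n_pairs, 6) ordered per
    ``PairParameters`` fields; ``step`` has shape (n_frames, n_steps, 6)
    ordered per ``StepParameters`` fields.
    """

    pair: np.ndarray
    step: np.ndarray
    pair_names: tuple[str, ...] = _PAIR_NAMES
    step_names: tuple[str, ...] = _STEP_NAMES

    @property
    def n_frames(self) -> int:
        return self.pair.shape[0]

    def summary(self):
        """Mean and SD per parameter per position as a tidy DataFrame."""
        import pandas as pd

        rows = []
        for kind, arr, names in (("pair", self.pair, self.pair_names),
                                 ("step", self.step, self.step_names)):
            for pos in range(arr.shape[1]):
                for k, name in enumerate(names):
                    series = arr[:, pos, k]
                    rows.append({"kind": kind, "position": pos + 1,
                                 "parameter": name,
                                 "mean": float(series.mean()),
                                 "sd": float(series.std(ddof=0))})
        return pd.DataFrame(rows)

    def to_frame(self):
        """Full per-frame series as a tidy DataFrame."""
        import pandas as pd

        records = []
        for kind, arr, names in (("pair", self.pair, self.pair_names),
                                 ("step", self.step, self.step_names)):
            nf, npos, _ = arr.shape
            for pos in range(npos):
                for k, name in enumerate(names):
                    records.append(pd.DataFrame({
                        "frame": np.arange(nf), "kind": kind,
                        "position": pos + 1, "parameter": name,
                        "value": arr[:, pos, k]}))
        return pd.concat(records, ignore_index=True)


def duplex_frames(duplex) -> tuple[list[Frame], list[Frame]]:
    """Base frames for every pair of a duplex: (watson_frames, crick_frames)."""
    wf, cf = [], []
    for wi, ci in duplex.pairs:
        wf.append(fit_base_frame(duplex.strand_watson[wi - 1]))
        cf.append(fit_base_frame(duplex.strand_crick[ci - 1]))
    return wf, cf


def duplex_parameters(duplex) -> tuple[list[PairParameters],
                                       list[StepParameters], list[Frame]]:
    """All pair and step parameters of one duplex snapshot."""
    wf, cf = duplex_frames(duplex)
    pair_params, pair_frames = [], []
    for fw, fc in zip(wf, cf):
        pp, mid = pair_parameters(fw, fc)
        pair_params.append(pp)
        pair_frames.append(mid)
    step_params = [step_parameters(pair_frames[i], pair_frames[i + 1])[0]
                   for i in range(len(pair_frames) - 1)]
    return pair_params, step_params, pair_frames


def parameter_timeseries(ensemble, duplex=None) -> ParameterTimeseries:
    """Extract rigid-base parameters for every frame of an ensemble."""
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    pair_rows, step_rows = [], []
    for i in range(ensemble.n_frames):
        snap = ensemble.frame(i)
        dup = snap if duplex is None else snap
        pp, sp, _ = duplex_parameters(dup.as_duplex()
                                      if hasattr(dup, "as_duplex") else dup)
        pair_rows.append([p.as_array() for p in pp])
        step_rows.append([s.as_array() for s in sp])
    return ParameterTimeseries(np.array(pair_rows), np.array(step_rows))
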