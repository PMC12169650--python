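"""Synthetic inputs for every stage of the pipeline.

This module is a first-class generator, not a test shim: it builds duplex
coordinates from rigid-base parameters and sugar pseudorotation targets,
samples perturbed ensembles with controlled fluctuations and neighbour
twist coupling (standing in for microsecond MD trajectories), plants
protein probe atoms at known distances for contact fixtures, runs an
overdamped-Langevin walker that deposits metadynamics hills over a twist
coordinate, and synthesises Hill-isotherm titrations and IRF-convolved
fluorescence decays with Poisson counting noise.

Bases are placed exactly by composing frames, so rigid-base extraction
after building reproduces the requested parameters to machine precision;
sugar rings are generated from (P, nu_max) by a puckered-pentagon model
solved numerically against the Altona-Sundaralingam definition, with the
glycosidic torsion set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .conformation import dihedral, pseudorotation_from_torsions, _NU_ATOMS
from .refbases import COMPLEMENT, chi_reference_atoms, standard_base
from .rigidbase import Frame, PairParameters, StepParameters, compose_pair, compose_step
from .structure import Atom, DuplexStructure, Ensemble, Residue, Structure

__all__ = [
    "SugarSpec", "CanonicalFormSpec", "DuplexSpec", "EnsembleSpec",
    "build_duplex", "sample_ensemble", "ProbeAtomSpec", "build_probe_complex",
    "FlatPotential", "DoubleWellPotential", "HarmonicPotential",
    "WalkerSpec", "generate_hills", "generate_titration", "generate_decay",
]

KT_298 = 2.494  # kJ/mol


# ---------------------------------------------------------------------------
# sugar ring construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SugarSpec:
    """Target deoxyribose geometry: pseudorotation phase P and amplitude
    nu_max (deg), plus the glycosidic torsion chi (deg)."""

    P: float = 162.0
    nu_max: float = 38.0
    chi: float = -100.0


_RING_ORDER = ("C1'", "C2'", "C3'", "C4'", "O4'")
_RING_RADIUS = 1.293          # planar pentagon radius giving ~1.52 A bonds
_ANGLE_N_C1_O4 = 108.2        # glycosidic attachment angles, deg
_ANGLE_N_C1_C2 = 113.7


def _pentagon(q: float, phase: float) -> np.ndarray:
    """Five ring atoms on a puckered pentagon (rows follow _RING_ORDER)."""
    j = np.arange(5)
    theta = 2.0 * np.pi * j / 5.0
    z = np.sqrt(2.0 / 5.0) * q * np.cos(4.0 * np.pi * j / 5.0 + phase)
    return np.column_stack([_RING_RADIUS * np.cos(theta),
                            _RING_RADIUS * np.sin(theta), z])


def _ring_pseudorotation(coords: np.ndarray) -> tuple[float, float]:
    pos = dict(zip(_RING_ORDER, coords))
    nu = np.array([dihedral(*(pos[n] for n in quad)) for quad in _NU_ATOMS])
    return pseudorotation_from_torsions(nu)


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def _nerf(A: np.ndarray, B: np.ndarray, C: np.ndarray,
          bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to C with angle D-C-B and torsion D-C-B-A (deg)."""
    theta, phi = np.radians(angle), np.radians(torsion)
    bc = C - B
    bc /= np.linalg.norm(bc)
    n = np.cross(B - A, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(theta),
                  bond * np.sin(theta) * np.cos(phi),
                  bond * np.sin(theta) * np.sin(phi)])
    return C + d[0] * bc + d[1] * m + d[2] * n


def _two_cone(a: np.ndarray, b: np.ndarray, cos_a: float, cos_b: float,
              normal: np.ndarray, side: float) -> np.ndarray:
    """Unit vector u with u.a=cos_a, u.b=cos_b and sign(u.normal)=side."""
    G = float(a @ b)
    det = 1.0 - G * G
    x = (cos_a - cos_b * G) / det
    y = (cos_b - cos_a * G) / det
    w = x * a + y * b
    z2 = max(0.0, 1.0 - float(w @ w))
    c = np.cross(a, b)
    c /= np.linalg.norm(c)
    for s in (1.0, -1.0):
        u = w + s * np.sqrt(z2) * c
        if np.sign(u @ normal) == np.sign(side) or z2 == 0.0:
            return u / np.linalg.norm(u)
    return w / np.linalg.norm(w)


_ring_cache: dict[tuple[float, float], dict[str, np.ndarray]] = {}


def _sugar_template(P: float, nu_max: float) -> dict[str, np.ndarray]:
    """Ring + exocyclic C5', O3', O5' and the glycosidic direction, in a
    local frame with C1' at a known position.  Cached per (P, nu_max)."""
    key = (round(P, 6), round(nu_max, 6))
    if key in _ring_cache:
        return _ring_cache[key]
    ring = _pentagon(*_solve_ring_params(P, nu_max))
    pos = dict(zip(_RING_ORDER, ring))
    zhat = np.array([0.0, 0.0, 1.0])
    # glycosidic direction at C1'
    a = pos["O4'"] - pos["C1'"]
    a /= np.linalg.norm(a)
    b = pos["C2'"] - pos["C1'"]
    b /= np.linalg.norm(b)
    # the attachment side fixes the natural D-deoxyribose handedness: the
    # backbone winds outward, not over the base rim
    n_dir = _two_cone(a, b, np.cos(np.radians(_ANGLE_N_C1_O4)),
                      np.cos(np.radians(_ANGLE_N_C1_C2)), zhat, -1.0)
    base_side = float(np.sign(n_dir @ zhat)) or 1.0
    # C5' on C4', same ring face as the base; O3' on C3', opposite face
    a4 = pos["C3'"] - pos["C4'"]
    a4 /= np.linalg.norm(a4)
    b4 = pos["O4'"] - pos["C4'"]
    b4 /= np.linalg.norm(b4)
    u5 = _two_cone(a4, b4, np.cos(np.radians(115.2)),
                   np.cos(np.radians(109.1)), zhat, base_side)
    pos["C5'"] = pos["C4'"] + 1.51 * u5
    a3 = pos["C2'"] - pos["C3'"]
    a3 /= np.linalg.norm(a3)
    b3 = pos["C4'"] - pos["C3'"]
    b3 /= np.linalg.norm(b3)
    u3 = _two_cone(a3, b3, np.cos(np.radians(110.0)),
                   np.cos(np.radians(110.0)), zhat, -base_side)
    pos["O3'"] = pos["C3'"] + 1.42 * u3
    pos["O5'"] = _nerf(pos["C3'"], pos["C4'"], pos["C5'"], 1.42, 110.5, 54.0)
    pos["_N"] = n_dir
    _ring_cache[key] = pos
    return pos


def _solve_ring_params(P_target: float, nu_max_target: float,
                       ) -> tuple[float, float]:
    from scipy.optimize import least_squares

    def residual(x):
        P, nmx = _ring_pseudorotation(_pentagon(x[0], x[1]))
        return [_wrap_deg(P - P_target), nmx - nu_max_target]

    best = None
    for phase0 in np.radians([0.0, 90.0, 180.0, 270.0]):
        sol = least_squares(residual, x0=[nu_max_target / 102.5, phase0],
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16:
            break
    if best.cost > 1.0:
        raise ValueError(
            f"sugar ring closure failed for P={P_target}, "
            f"nu_max={nu_max_target}")
    return float(best.x[0]), float(best.x[1])


def _rodrigues(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    ang = np.radians(angle_deg)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(ang) * K + (1.0 - np.cos(ang)) * (K @ K)


def _place_sugar(base_pos: dict[str, np.ndarray], base_type: str,
                 spec: SugarSpec) -> dict[str, np.ndarray]:
    """Global sugar atom positions attached to an already-placed base."""
    tmpl = _sugar_template(spec.P, spec.nu_max)
    _, _, n_name, cref_name = chi_reference_atoms(base_type)
    c1 = base_pos["C1'"]
    n_atom = base_pos[n_name]
    d = n_atom - c1
    d /= np.linalg.norm(d)
    n_local = tmpl["_N"]
    axis = np.cross(n_local, d)
    s = np.linalg.norm(axis)
    c = float(n_local @ d)
    if s < 1e-12:
        R0 = np.eye(3) if c > 0 else _rodrigues(
            _any_perpendicular(n_local), 180.0)
    else:
        R0 = _rodrigues(axis / s, np.degrees(np.arctan2(s, c)))
    placed = {name: R0 @ (p - tmpl["C1'"]) + c1
              for name, p in tmpl.items() if name != "_N"}
    # rotate about the glycosidic bond to realise the chi target exactly
    tau = dihedral(placed["O4'"], c1, n_atom, base_pos[cref_name])
    for delta in (spec.chi - tau, -(spec.chi - tau)):
        Rchi = _rodrigues(d, delta)
        trial = {name: Rchi @ (p - c1) + c1 for name, p in placed.items()}
        new_tau = dihedral(trial["O4'"], c1, n_atom, base_pos[cref_name])
        if abs(_wrap_deg(new_tau - spec.chi)) < 1e-6:
            placed = trial
            break
    else:  # pragma: no cover - sign convention is fixed, kept as guard
        raise RuntimeError("chi adjustment failed")
    placed["C1'"] = c1
    return placed


_nucleoside_cache: dict[tuple, tuple[list[str], np.ndarray]] = {}


def _nucleoside_template(base_type: str, spec: SugarSpec,
                         ) -> tuple[list[str], np.ndarray]:
    """Base + sugar heavy-atom coordinates in the standard base frame."""
    key = (base_type, round(spec.P, 9), round(spec.nu_max, 9),
           round(spec.chi, 9))
    if key not in _nucleoside_cache:
        pos = {n: p.copy() for n, p in standard_base(base_type).items()}
        pos.update(_place_sugar(pos, base_type, spec))
        names = list(pos)
        _nucleoside_cache[key] = (names, np.array([pos[n] for n in names]))
    return _nucleoside_cache[key]


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(v, w)
    return u / np.linalg.norm(u)


# ---------------------------------------------------------------------------
# duplex builder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanonicalFormSpec:
    """Canonical A- or B-form fixture constants (configurable).

    Step/pair parameter means in degrees and Angstrom, sugar target
    (P, nu_max) in degrees, glycosidic chi in degrees.  These are textbook
    fiber-model constants used as generator targets.
    """

    form: str
    step: StepParameters
    pair: PairParameters
    sugar: SugarSpec

    @classmethod
    def b_form(cls) -> "CanonicalFormSpec":
        return cls("B", StepParameters(0.0, 0.0, 3.38, 0.0, 0.0, 36.0),
                   PairParameters.zero(), SugarSpec(162.0, 38.0, -100.0))

    @classmethod
    def a_form(cls) -> "CanonicalFormSpec":
        return cls("A", StepParameters(0.0, -1.5, 2.56, 0.0, 8.0, 32.7),
                   PairParameters.zero(), SugarSpec(18.0, 38.0, -160.0))


APT_SEQUENCE = "GCATATATATGC"
GPC_SEQUENCE = "GCGCGCGCGCGC"

_SUGAR_ATOM_ORDER = ("O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'")


def _normalise_sugar_specs(sequence: str, sugar_specs) -> tuple[list, list]:
    L = len(sequence)
    if sugar_specs is None:
        sugar_specs = SugarSpec()
    if isinstance(sugar_specs, SugarSpec):
        return [sugar_specs] * L, [sugar_specs] * L
    if isinstance(sugar_specs, tuple) and len(sugar_specs) == 2:
        w, c = list(sugar_specs[0]), list(sugar_specs[1])
    else:
        w = list(sugar_specs)
        c = list(sugar_specs)
    if len(w) != L or len(c) != L:
        raise ValueError(
            f"sugar spec list length {len(w)} does not match sequence "
            f"length {L}")
    return w, c


def build_duplex(sequence: str,
                 pair_params: Sequence[PairParameters] | PairParameters | None = None,
                 step_params: Sequence[StepParameters] | StepParameters | None = None,
                 sugar_specs=None,
                 watson_chain: str = "A", crick_chain: str = "B",
                 ) -> DuplexStructure:
    """Build duplex coordinates from rigid-base parameters and sugar targets.

    ``sequence`` is the Watson strand 5'->3'; the Crick strand is its
    reverse complement.  Base atoms are placed exactly by composing frames
    from the requested parameters around embedded standard-base geometry;
    deoxyribose rings are generated from each residue's (P, nu_max, chi)
    and phosphates bridge consecutive sugars.  Sugar specs may be a single
    :class:`SugarSpec`, a per-pair list applied to both strands, or a
    ``(watson_list, crick_list)`` tuple (each 5'->3').
    """
    sequence = sequence.upper()
    L = len(sequence)
    if L < 2:
        raise ValueError("sequence must have at least 2 base pairs")
    if any(b not in "ACGT" for b in sequence):
        raise ValueError(f"sequence must be over A,C,G,T: {sequence!r}")
    if pair_params is None:
        pair_params = PairParameters.zero()
    if isinstance(pair_params, PairParameters):
        pair_params = [pair_params] * L
    if step_params is None:
        step_params = CanonicalFormSpec.b_form().step
    if isinstance(step_params, StepParameters):
        step_params = [step_params] * (L - 1)
    if len(pair_params) != L:
        raise ValueError(f"need {L} pair parameter sets, got {len(pair_params)}")
    if len(step_params) != L - 1:
        raise ValueError(f"need {L - 1} step parameter sets, got {len(step_params)}")
    sugar_w, sugar_c_by_pair = _normalise_sugar_specs(sequence, sugar_specs)

    # chain of pair frames along the helix
    pair_frames = [Frame.identity()]
    for sp in step_params:
        pair_frames.append(compose_step(pair_frames[-1], sp))

    # place bases + sugars; the nucleoside geometry relative to the base
    # frame is constant per (base, sugar spec), so it is cached and applied
    # with a single rigid transform per residue
    watson_atoms: list[dict[str, np.ndarray]] = []
    crick_atoms: list[dict[str, np.ndarray]] = []
    for i, base in enumerate(sequence):
        fw, fc = compose_pair(pair_frames[i], pair_params[i])
        comp = COMPLEMENT[base]
        wn, wc = _nucleoside_template(base, sugar_w[i])
        cn, cc = _nucleoside_template(comp, sugar_c_by_pair[i])
        wxyz = wc @ fw.rotation.T + fw.origin
        cxyz = cc @ fc.rotation.T + fc.origin
        watson_atoms.append(dict(zip(wn, wxyz)))
        crick_atoms.append(dict(zip(cn, cxyz)))
    # Crick strand 5'->3' runs over pairs L..1
    crick_atoms = crick_atoms[::-1]
    crick_seq = "".join(COMPLEMENT[b] for b in sequence[::-1])

    chains: dict[str, list[Residue]] = {}
    for cid, strand_seq, strand_atoms in (
            (watson_chain, sequence, watson_atoms),
            (crick_chain, crick_seq, crick_atoms)):
        residues = []
        for k, (base, pos) in enumerate(zip(strand_seq, strand_atoms), start=1):
            res = Residue(f"D{base}", cid, k, [])
            if k > 1:
                prev = strand_atoms[k - 2]
                res.add_atom(Atom("P", "P", _bridge_phosphate(
                    prev["O3'"], pos["O5'"], prev["C3'"], pos["C5'"]),
                    k, cid))
            for name in _SUGAR_ATOM_ORDER:
                res.add_atom(Atom(name, name[0], pos[name], k, cid))
            for name in standard_base(base):
                if name == "C1'":
                    continue
                res.add_atom(Atom(name, name[0], pos[name], k, cid))
            residues.append(res)
        chains[cid] = residues
    return DuplexStructure(chains, watson_chain, crick_chain)


def _bridge_phosphate(o3: np.ndarray, o5: np.ndarray,
                      c3: np.ndarray, c5: np.ndarray) -> np.ndarray:
    """Phosphorus on the O3'(i)->O5'(i+1) bridge with ideal P-O bonds when
    the gap allows, else at the midpoint.

    The off-axis direction is built from the local C-O bond vectors so the
    placement is covariant with the helix symmetry (uniform parameters give
    a uniform backbone).
    """
    d = float(np.linalg.norm(o5 - o3))
    mid = 0.5 * (o3 + o5)
    if d >= 3.2 or d < 1e-6:
        return mid
    h = np.sqrt(max(1.6 ** 2 - (d / 2.0) ** 2, 0.0))
    axis = (o5 - o3) / d
    v = (o3 - c3) + (o5 - c5)
    perp = v - (v @ axis) * axis
    nv = np.linalg.norm(perp)
    if nv < 1e-9:
        perp = _any_perpendicular(axis)
    else:
        perp /= nv
    return mid + h * perp


# ---------------------------------------------------------------------------
# perturbed ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplexSpec:
    """Mean geometry of a duplex: sequence plus canonical-form targets."""

    sequence: str = APT_SEQUENCE
    form: CanonicalFormSpec = field(default_factory=CanonicalFormSpec.b_form)

    def mean_step_params(self) -> list[StepParameters]:
        return [self.form.step] * (len(self.sequence) - 1)

    def mean_pair_params(self) -> list[PairParameters]:
        return [self.form.pair] * len(self.sequence)

    def build(self) -> DuplexStructure:
        return build_duplex(self.sequence, self.mean_pair_params(),
                            self.mean_step_params(), self.form.sugar)


@dataclass(frozen=True)
class EnsembleSpec:
    """Fluctuation magnitudes for a sampled ensemble.

    ``step_sds``/``pair_sds`` map parameter names to SDs (deg / Angstrom);
    ``rho_twist`` is the target Pearson correlation between adjacent step
    twists (|rho| < 1, nearest-neighbour coupling).
    """

    n_frames: int = 100
    seed: int = 0
    step_sds: dict[str, float] = field(default_factory=dict)
    pair_sds: dict[str, float] = field(default_factory=dict)
    rho_twist: float = 0.0
    dt_ns: float = 1.0

    def __post_init__(self):
        if any(v < 0 for v in {**self.step_sds, **self.pair_sds}.values()):
            raise ValueError("fluctuation SDs must be >= 0")
        if not abs(self.rho_twist) < 1.0:
            raise ValueError("|rho_twist| must be < 1")


def _twist_covariance(n_steps: int, sd: float, rho: float) -> np.ndarray:
    cov = np.eye(n_steps)
    idx = np.arange(n_steps - 1)
    cov[idx, idx + 1] = rho
    cov[idx + 1, idx] = rho
    cov *= sd ** 2
    return cov


def sample_ensemble(duplex_spec: DuplexSpec, ens_spec: EnsembleSpec,
                    ) -> Ensemble:
    """Sample an ensemble of rebuilt duplex conformations.

    Per-frame step parameters are drawn from a multivariate normal around
    the spec means with the requested SDs; adjacent step twists carry the
    nearest-neighbour correlation ``rho_twist``.  Coordinates are rebuilt
    per frame; bit-for-bit reproducible under a fixed seed.  The drawn
    parameters are attached as ``ensemble.step_parameter_draws`` (shape
    n_frames x n_steps x 6, ordered as StepParameters) for diagnostics.
    """
    rng = np.random.default_rng(ens_spec.seed)
    seq = duplex_spec.sequence
    L = len(seq)
    n_steps = L - 1
    mean_step = np.array([sp.as_array() for sp in duplex_spec.mean_step_params()])
    mean_pair = np.array([pp.as_array() for pp in duplex_spec.mean_pair_params()])
    step_names = ("shift", "slide", "rise", "tilt", "roll", "twist")
    pair_names = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")

    tw_sd = ens_spec.step_sds.get("twist", 0.0)
    if ens_spec.rho_twist != 0.0 and tw_sd > 0.0:
        cov = _twist_covariance(n_steps, tw_sd, ens_spec.rho_twist)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"requested twist covariance (rho={ens_spec.rho_twist}) is "
                f"not positive definite for {n_steps} steps") from None
    else:
        chol = None

    n = ens_spec.n_frames
    step_draws = np.broadcast_to(mean_step, (n, n_steps, 6)).copy()
    for k, name in enumerate(step_names):
        sd = ens_spec.step_sds.get(name, 0.0)
        if name == "twist" and chol is not None:
            step_draws[:, :, k] += rng.standard_normal((n, n_steps)) @ chol.T
        elif sd > 0:
            step_draws[:, :, k] += sd * rng.standard_normal((n, n_steps))
    pair_draws = np.broadcast_to(mean_pair, (n, L, 6)).copy()
    for k, name in enumerate(pair_names):
        sd = ens_spec.pair_sds.get(name, 0.0)
        if sd > 0:
            pair_draws[:, :, k] += sd * rng.standard_normal((n, L))

    sugar = duplex_spec.form.sugar
    topology = None
    coords = []
    for f in range(n):
        dup = build_duplex(
            seq,
            [PairParameters(*row) for row in pair_draws[f]],
            [StepParameters(*row) for row in step_draws[f]],
            sugar)
        if topology is None:
            topology = dup
        coords.append(dup.coords())
    times = ens_spec.dt_ns * np.arange(1, n + 1)
    ens = Ensemble(topology, np.stack(coords), times)
    ens.step_parameter_draws = step_draws
    ens.pair_parameter_draws = pair_draws
    return ens


# ---------------------------------------------------------------------------
# protein probe fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeAtomSpec:
    """One pseudo-protein atom placed at a set distance from a DNA atom."""

    name: str                      # e.g. "NE1", "CA"
    residue_name: str              # e.g. "TRP"
    residue_number: int            # e.g. 109
    target: tuple[str, int, str]   # (chain_id, residue_index, atom_name)
    distance: float                # Angstrom
    direction: tuple[float, float, float] | None = None


def _fibonacci_sphere(n: int) -> np.ndarray:
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def build_probe_complex(duplex: DuplexStructure,
                        probe_spec: Sequence[ProbeAtomSpec],
                        probe_chain: str = "P",
                        avoid_cutoff: float = 4.5,
                        avoid_names: Sequence[str] | None = None) -> Structure:
    """Plant pseudo-protein atoms at requested distances from DNA atoms.

    Each probe atom is placed exactly at its target distance; unless an
    explicit direction is given, the direction (from 256 candidates on a
    sphere) maximising the clearance to all other DNA atoms is chosen, so
    fixtures have exactly known contact counts.  Raises ``ValueError`` for
    infeasible constraints.
    """
    dna_coords = np.array([a.position for a in duplex.iter_atoms()
                           if a.element != "H"])
    dna_keys = [(a.chain_id, a.residue_index, a.name)
                for a in duplex.iter_atoms() if a.element != "H"]
    chains = {cid: list(chain) for cid, chain in duplex.chains.items()}
    residues: dict[int, Residue] = {}
    dirs = _fibonacci_sphere(256)
    for spec in probe_spec:
        if spec.distance <= 0:
            raise ValueError(
                f"infeasible distance {spec.distance} for probe {spec.name}")
        try:
            ti = dna_keys.index(spec.target)
        except ValueError:
            raise ValueError(f"probe target {spec.target} not found") from None
        target = dna_coords[ti]
        if spec.direction is not None:
            d = np.asarray(spec.direction, float)
            d /= np.linalg.norm(d)
            pos = target + spec.distance * d
        else:
            others = np.delete(dna_coords, ti, axis=0)
            if avoid_names is not None:
                keep = np.delete(np.array(
                    [k[2] in avoid_names for k in dna_keys]), ti)
                others = others[keep]
            candidates = target + spec.distance * dirs
            if len(others) == 0:
                pos = candidates[0]
            else:
                d = np.linalg.norm(
                    candidates[:, None, :] - others[None, :, :], axis=-1)
                # prefer directions leaving no stray atom of the avoided
                # group within the cutoff; break ties by clearance
                n_close = np.count_nonzero(d < avoid_cutoff, axis=1)
                clearance = d.min(axis=1)
                best = np.lexsort((-clearance, n_close))[0]
                pos = candidates[int(best)]
        if spec.residue_number not in residues:
            residues[spec.residue_number] = Residue(
                spec.residue_name, probe_chain, spec.residue_number, [])
        residues[spec.residue_number].add_atom(
            Atom(spec.name, spec.name[0], pos, spec.residue_number,
                 probe_chain))
    chains[probe_chain] = [residues[k] for k in sorted(residues)]
    return Structure(chains)


# ---------------------------------------------------------------------------
# metadynamics hill deposits
# ---------------------------------------------------------------------------

class FlatPotential:
    """Zero free-energy landscape."""

    def energy(self, s):
        return np.zeros_like(np.asarray(s, float))

    def force(self, s):
        return np.zeros_like(np.asarray(s, float))


@dataclass(frozen=True)
class DoubleWellPotential:
    """Symmetric double well U = b ((s-c)^2 - a^2)^2 / a^4 (kJ/mol, s deg).

    Minima at c +- a with U=0; barrier height b at s=c.
    """

    minima: tuple[float, float] = (25.0, 45.0)
    barrier: float = 5.0

    @property
    def _c(self) -> float:
        return 0.5 * (self.minima[0] + self.minima[1])

    @property
    def _a(self) -> float:
        return 0.5 * (self.minima[1] - self.minima[0])

    def energy(self, s):
        u = (np.asarray(s, float) - self._c)
        return self.barrier * (u * u - self._a ** 2) ** 2 / self._a ** 4

    def force(self, s):
        u = (np.asarray(s, float) - self._c)
        return -4.0 * self.barrier * (u * u - self._a ** 2) * u / self._a ** 4


@dataclass(frozen=True)
class HarmonicPotential:
    """U = k/2 (s - center)^2, k in kJ/mol/deg^2."""

    center: float = 35.0
    k: float = 0.05

    def energy(self, s):
        return 0.5 * self.k * (np.asarray(s, float) - self.center) ** 2

    def force(self, s):
        return -self.k * (np.asarray(s, float) - self.center)


@dataclass(frozen=True)
class WalkerSpec:
    """Overdamped-Langevin walker on the twist coordinate.

    Euler-Maruyama with timestep ``dt_ps``; the diffusion constant is
    kT/gamma.  Defaults give a walker that traverses the 10-60 deg window
    within a few nanoseconds on a flat landscape.
    """

    dt_ps: float = 0.5
    gamma: float = 1.25   # kJ/mol * ps / deg^2
    kT: float = KT_298
    s0: float = 35.0


def generate_hills(potential, walker: WalkerSpec | None = None,
                   sigma: float = 0.04, height: float = 0.1,
                   stride_ps: float = 4.0, duration_ns: float = 50.0,
                   boundaries: tuple[float, float] = (10.0, 60.0),
                   seed: int = 0, return_trajectory: bool = False):
    """Run a biased walker and return the deposited Gaussian hills.

    ``sigma`` is the hill width in radians and ``height`` the hill height
    in kJ/mol (deposited every ``stride_ps``); the bias force is zero
    outside ``boundaries`` (deg) and the walker reflects off them.
    Returns a list of :class:`~dnaadapt.metad.HillsRecord`; with
    ``return_trajectory=True`` also the (times_ps, cv_deg) series.
    """
    from .metad import HillsRecord

    if sigma <= 0 or height < 0:
        raise ValueError("sigma must be > 0 and height >= 0")
    walker = walker or WalkerSpec()
    lo, hi = boundaries
    sigma_deg = np.degrees(sigma)
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_ns * 1000.0 / walker.dt_ps))
    stride = max(1, int(round(stride_ps / walker.dt_ps)))

    # accumulated bias force tabulated on a fine grid inside the boundaries
    grid = np.arange(lo, hi + 1e-9, 0.1)
    bias_force = np.zeros_like(grid)
    inv_dx = 1.0 / 0.1

    s = float(np.clip(walker.s0, lo, hi))
    mob = walker.dt_ps / walker.gamma
    noise_sd = np.sqrt(2.0 * walker.kT * walker.dt_ps / walker.gamma)
    noise = rng.standard_normal(n_steps)

    records = []
    traj_t, traj_s = [], []
    for step in range(n_steps):
        if lo <= s <= hi:
            x = (s - lo) * inv_dx
            i0 = min(int(x), len(grid) - 2)
            w = x - i0
            fb = bias_force[i0] * (1.0 - w) + bias_force[i0 + 1] * w
        else:  # pragma: no cover - reflection keeps the walker inside
            fb = 0.0
        f = float(potential.force(s)) + fb
        s = s + mob * f + noise_sd * noise[step]
        if s < lo:
            s = 2.0 * lo - s
        if s > hi:
            s = 2.0 * hi - s
        s = float(np.clip(s, lo, hi))
        t_ps = (step + 1) * walker.dt_ps
        if return_trajectory:
            traj_t.append(t_ps)
            traj_s.append(s)
        if (step + 1) % stride == 0:
            records.append(HillsRecord(time=t_ps, center=np.radians(s),
                                       sigma=sigma, height=height))
            d = grid - s
            bias_force += height * d / sigma_deg ** 2 * np.exp(
                -0.5 * (d / sigma_deg) ** 2)
    if return_trajectory:
        return records, (np.array(traj_t), np.array(traj_s))
    return records


# ---------------------------------------------------------------------------
# spectroscopy data
# ---------------------------------------------------------------------------

def generate_titration(K: float, n: float, F0: float, F_inf: float,
                       concentrations: np.ndarray, noise_sd: float = 0.0,
                       seed: int = 0):
    """Fluorescence quenching titration obeying a Hill isotherm.

    F(c) = F0 - (F0 - F_inf) c^n / (K^n + c^n), plus Gaussian noise of SD
    ``noise_sd`` (same units as F).  Concentrations in nM, > 0, increasing.
    """
    from .binding import TitrationSeries

    if K <= 0 or n <= 0:
        raise ValueError("K and n must be positive")
    c = np.asarray(concentrations, float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    theta = c ** n / (K ** n + c ** n)
    F = F0 - (F0 - F_inf) * theta
    if noise_sd > 0:
        F = F + np.random.default_rng(seed).normal(0.0, noise_sd, size=c.shape)
    return TitrationSeries(concentration=c, F_obs=F,
                           A_ex=np.zeros_like(c), A_em=np.zeros_like(c))


def gaussian_irf(time_ns: np.ndarray, fwhm_ns: float,
                 t0_ns: float | None = None) -> np.ndarray:
    """Unit-area Gaussian instrument response on the data grid."""
    sd = fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if t0_ns is None:
        t0_ns = max(5.0 * sd, time_ns[1] - time_ns[0])
    irf = np.exp(-0.5 * ((time_ns - t0_ns) / sd) ** 2)
    return irf / irf.sum()


def generate_decay(amplitudes, lifetimes, irf_fwhm_ns: float = 1.0,
                   dt_ns: float = 0.05, n_channels: int = 1024,
                   total_counts: float = 1e6, seed: int = 0,
                   poisson_noise: bool = True):
    """Multi-exponential decay convolved with a Gaussian IRF, Poisson noise.

    Returns a :class:`~dnaadapt.binding.DecayHistogram` whose ``irf``
    attribute holds the IRF used (normalised, same grid).
    """
    from .binding import DecayHistogram

    amplitudes = np.asarray(amplitudes, float)
    lifetimes = np.asarray(lifetimes, float)
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    if np.any(amplitudes < 0) or not np.any(amplitudes > 0):
        raise ValueError("amplitudes must be >= 0 with at least one > 0")
    if dt_ns <= 0 or n_channels <= 0:
        raise ValueError("dt and channel count must be positive")
    t = dt_ns * np.arange(n_channels)
    decay = np.sum(amplitudes[:, None] * np.exp(-t[None, :] / lifetimes[:, None]),
                   axis=0)
    irf = gaussian_irf(t, irf_fwhm_ns)
    model = np.convolve(irf, decay)[:n_channels]
    if total_counts <= 0:
        counts = np.zeros(n_channels)
    else:
        model = model / model.sum() * total_counts
        if poisson_noise:
            counts = np.random.default_rng(seed).poisson(model).astype(float)
        else:
            counts = model
    return DecayHistogram(time=t, counts=counts, irf=irf)
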