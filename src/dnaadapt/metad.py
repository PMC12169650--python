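"""Metadynamics hill parsing and free-energy profile reconstruction.

A metadynamics run deposits repulsive Gaussians along the biased twist
coordinate; once the walker diffuses freely, the free-energy profile is
the negative of the accumulated bias,

    F(s) = - sum_k h_k exp(-(s - s_k)^2 / (2 sigma_k^2)),

shifted so min F = 0.  The production protocol takes sub-profiles at fixed
time increments (every 2 ns), min-aligns each, and reports the pointwise
mean and SD over a 40 ns window starting at 10 ns.  Runs in which more
than one central base pair opens and never re-pairs are pruned before
averaging.  Hills use the PLUMED HILLS text dialect: time in ps, the
collective variable in radians; profiles are reported over a twist grid in
degrees bounded to [10, 60] with the bias treated as zero outside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "HillsRecord", "FESProfile", "read_hills", "write_hills",
    "reconstruct_fes", "windowed_profiles", "free_diffusion_check",
    "prune_opened", "fes_minimum_and_width", "DEFAULT_BOUNDARIES",
]

DEFAULT_BOUNDARIES = (10.0, 60.0)   # deg
DEFAULT_GRID_SPACING = 0.25         # deg
KT_298 = 2.494                      # kJ/mol


@dataclass(frozen=True)
class HillsRecord:
    """One deposited Gaussian: time (ps), center and sigma (radians),
    height (kJ/mol)."""

    time: float
    center: float
    sigma: float
    height: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.height < 0:
            raise ValueError("height must be >= 0")

    @property
    def center_deg(self) -> float:
        return float(np.degrees(self.center))

    @property
    def sigma_deg(self) -> float:
        return float(np.degrees(self.sigma))


@dataclass
class FESProfile:
    """Free energy vs twist with per-point SD and provenance window."""

    grid: np.ndarray          # deg, strictly increasing
    F: np.ndarray             # kJ/mol, min-aligned to 0
    F_sd: np.ndarray          # kJ/mol
    window_ns: tuple[float, float]
    n_subprofiles: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"twist_deg": self.grid, "F_kJmol": self.F,
                             "F_sd": self.F_sd})


def write_hills(records: Sequence[HillsRecord], path) -> Path:
    """Write hills in the PLUMED HILLS text dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#! FIELDS time twist sigma_twist height biasf\n")
        for r in records:
            fh.write(f"{r.time:.6f} {r.center:.9f} {r.sigma:.9f} "
                     f"{r.height:.9f} 1.0\n")
    return path


def read_hills(path) -> list[HillsRecord]:
    """Parse a PLUMED-HILLS-dialect file.

    Expects a ``#! FIELDS`` header naming at least time, a CV column, a
    sigma column and a height column (in that order); times must be
    nondecreasing.  A biasfactor column other than 1 flags unsupported
    well-tempered rescaling (warned and ignored).
    """
    path = Path(path)
    fields: list[str] | None = None
    records: list[HillsRecord] = []
    biasfactor_seen = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#!") and "FIELDS" in line:
                    fields = line.split()[2:]
                continue
            if fields is None:
                raise ValueError(
                    f"{path}: line {ln}: data before a #! FIELDS header")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}: header names {len(fields)} columns, need at "
                    f"least time, cv, sigma, height")
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}: line {ln}: expected >= 4 columns, got "
                    f"{len(parts)}")
            try:
                t, c, s, h = (float(parts[k]) for k in range(4))
            except ValueError:
                raise ValueError(
                    f"{path}: line {ln}: unparseable number") from None
            if len(parts) > 4 and fields[4].lower().startswith("biasf"):
                if float(parts[4]) not in (0.0, 1.0):
                    biasfactor_seen = True
            if records and t < records[-1].time:
                raise ValueError(
                    f"{path}: line {ln}: non-monotone time {t}")
            records.append(HillsRecord(t, c, s, h))
    if biasfactor_seen:
        warnings.warn("biasfactor != 1 found: well-tempered rescaling is "
                      "not supported, hills used as deposited", stacklevel=2)
    return records


def default_grid(boundaries=DEFAULT_BOUNDARIES,
                 spacing=DEFAULT_GRID_SPACING) -> np.ndarray:
    lo, hi = boundaries
    return np.arange(lo, hi + spacing / 2.0, spacing)


def reconstruct_fes(hills: Sequence[HillsRecord],
                    grid: np.ndarray | None = None,
                    boundaries=DEFAULT_BOUNDARIES,
                    align: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Free energy on a twist grid as the negative accumulated bias.

    Returns (grid_deg, F); with ``align=True`` F is shifted so min F = 0.
    """
    if grid is None:
        grid = default_grid(boundaries)
    grid = np.asarray(grid, float)
    lo, hi = boundaries
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise ValueError(f"grid must lie within the boundaries [{lo}, {hi}]")
    F = np.zeros_like(grid)
    if hills:
        centers = np.array([h.center_deg for h in hills])
        sigmas = np.array([h.sigma_deg for h in hills])
        heights = np.array([h.height for h in hills])
        d = grid[:, None] - centers[None, :]
        F = -np.sum(heights[None, :] * np.exp(-0.5 * (d / sigmas[None, :]) ** 2),
                    axis=1)
    if align:
        F = F - F.min()
    return grid, F


def windowed_profiles(hills: Sequence[HillsRecord], every_ns: float = 2.0,
                      window_ns: tuple[float, float] = (10.0, 50.0),
                      grid: np.ndarray | None = None,
                      boundaries=DEFAULT_BOUNDARIES) -> FESProfile:
    """Averaged free-energy profile per the windowed production protocol.

    Sub-profiles are reconstructed from all hills deposited up to t for
    t = start, start+every, ..., end; each is min-aligned, then the
    pointwise mean (re-aligned to 0) and SD are reported.
    """
    if grid is None:
        grid = default_grid(boundaries)
    if not hills:
        raise ValueError("no hills provided")
    t_end_ns = hills[-1].time / 1000.0
    if t_end_ns + 1e-9 < window_ns[1]:
        raise ValueError(
            f"hills span only {t_end_ns:.3f} ns; the averaging window "
            f"requires >= {window_ns[1]:.3f} ns")
    times = np.array([h.time for h in hills])
    cuts = np.arange(window_ns[0], window_ns[1] + every_ns / 2.0, every_ns)
    profiles = []
    for t_ns in cuts:
        k = int(np.searchsorted(times, t_ns * 1000.0, side="right"))
        _, F = reconstruct_fes(hills[:k], grid, boundaries, align=True)
        profiles.append(F)
    profiles = np.array(profiles)
    mean = profiles.mean(axis=0)
    sd = profiles.std(axis=0, ddof=0)
    mean = mean - mean.min()
    return FESProfile(np.asarray(grid, float), mean, sd,
                      (float(cuts[0]), float(cuts[-1])), len(cuts))


def free_diffusion_check(times_ps: np.ndarray, cv_deg: np.ndarray,
                         boundaries=DEFAULT_BOUNDARIES,
                         edge_tolerance: float = 2.0,
                         deadline_ns: float = 10.0) -> dict:
    """Range coverage and boundary-to-boundary traversal diagnostics.

    A traversal is a move from within ``edge_tolerance`` of one boundary to
    within ``edge_tolerance`` of the other.  The check passes when at least
    one traversal completes before ``deadline_ns``.
    """
    cv = np.asarray(cv_deg, float)
    t = np.asarray(times_ps, float)
    if cv.size == 0:
        raise ValueError("empty CV series")
    lo, hi = boundaries
    nbins = 50
    visited = np.unique(np.clip(((cv - lo) / (hi - lo) * nbins).astype(int),
                                0, nbins - 1))
    coverage = len(visited) / nbins
    state = 0   # 0: unseen, +1 last touched high edge, -1 last touched low
    traversals = 0
    first_traversal_ps = np.inf
    for ti, s in zip(t, cv):
        if s <= lo + edge_tolerance:
            if state == 1:
                traversals += 1
                first_traversal_ps = min(first_traversal_ps, ti)
            state = -1
        elif s >= hi - edge_tolerance:
            if state == -1:
                traversals += 1
                first_traversal_ps = min(first_traversal_ps, ti)
            state = 1
    passed = traversals >= 1 and first_traversal_ps <= deadline_ns * 1000.0
    return {"coverage": coverage, "n_traversals": traversals,
            "first_traversal_ns": (first_traversal_ps / 1000.0
                                   if np.isfinite(first_traversal_ps) else None),
            "passed": bool(passed)}


def prune_opened(pair_intact: np.ndarray) -> bool:
    """Keep/drop decision for one run from central-pair pairing series.

    ``pair_intact`` has shape (n_frames, n_pairs) with True where the
    Watson-Crick pairing of a central pair is intact.  A pair "opened and
    did not recover" when it is open at every frame from its first opening
    to the end of the run.  The run is excluded (returns False) when more
    than one central pair did so.
    """
    intact = np.asarray(pair_intact, bool)
    if intact.ndim == 1:
        intact = intact[:, None]
    unrecovered = 0
    for p in range(intact.shape[1]):
        col = intact[:, p]
        open_idx = np.flatnonzero(~col)
        if open_idx.size and not col[open_idx[0]:].any():
            unrecovered += 1
    return unrecovered <= 1


def fes_minimum_and_width(profile: FESProfile | tuple[np.ndarray, np.ndarray],
                          level: float = KT_298) -> dict:
    """Location of the global minimum and width of its free-energy valley.

    The width is the extent of the contiguous region around the global
    minimum with F <= level (linear interpolation at the crossings).
    Returns a dict with s_min (deg), width (deg) and an at_boundary flag
    (minimum on the grid edge, or valley clipped by it).
    """
    if isinstance(profile, FESProfile):
        grid, F = profile.grid, profile.F
    else:
        grid, F = profile
    grid = np.asarray(grid, float)
    F = np.asarray(F, float)
    i_min = int(np.argmin(F))
    s_min = float(grid[i_min])
    at_boundary = i_min in (0, len(grid) - 1)

    # walk outward from the minimum to the first upward crossings of level
    lo_i = i_min
    while lo_i > 0 and F[lo_i - 1] <= level:
        lo_i -= 1
    hi_i = i_min
    while hi_i < len(grid) - 1 and F[hi_i + 1] <= level:
        hi_i += 1
    if lo_i == 0:
        left = grid[0]
        at_boundary = True
    else:
        f1, f0 = F[lo_i - 1], F[lo_i]
        left = grid[lo_i] - (grid[lo_i] - grid[lo_i - 1]) * (level - f0) / (f1 - f0)
    if hi_i == len(grid) - 1:
        right = grid[-1]
        at_boundary = True
    else:
        f0, f1 = F[hi_i], F[hi_i + 1]
        right = grid[hi_i] + (grid[hi_i + 1] - grid[hi_i]) * (level - f0) / (f1 - f0)
    return {"s_min": s_min, "width": float(right - left),
            "at_boundary": bool(at_boundary)}
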