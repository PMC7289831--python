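"""Rigid-body superposition and trajectory metrics.

Two trajectory observables drive the wild-type vs variant comparison:

* :func:`com_distance_series` — per-frame Euclidean distance between the
  mass-weighted centers of two domains (e.g. the D3 domain of GP130,
  residues 198–298, and the D3 domain of the α-receptor, residues 215–317).
  Distances are invariant under rigid motion, so no superposition is needed.
* :func:`rotamer_flexibility` — per-frame side-chain heavy-atom RMSD of one
  residue relative to its position at 0 ns, after superposing each frame
  onto frame 0 on backbone Cα atoms.  An anchored side chain (salt bridges,
  hydrogen bonds intact) shows a low mean RMSD; a side chain that has lost
  its partners jitters and the mean rises.

Superposition uses the Kabsch algorithm (SVD of the weighted covariance,
reflection-corrected so the rotation is always proper).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structio import (
    DomainSelection,
    SelectionError,
    StructureModel,
    Trajectory,
    select,
)

__all__ = [
    "SuperpositionResult",
    "DistanceSeries",
    "FlexibilitySeries",
    "kabsch_superpose",
    "center_of_mass",
    "com_distance_series",
    "rotamer_flexibility",
    "dihedral_angle",
    "place_internal",
    "BACKBONE_NAMES",
]

#: backbone atom names; everything else on a residue is side chain
BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


@dataclass
class SuperpositionResult:
    """Optimal proper rotation + translation and the post-fit RMSD (Å)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (n, 3) coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Parameters
    ----------
    mobile, reference : (n, 3) arrays, n >= 3, not all collinear.
    weights : optional per-point weights (e.g. masses) used in the fit.
        The reported RMSD is unweighted.

    Returns
    -------
    SuperpositionResult with ``rotation`` (det = +1), ``translation`` such
    that ``R @ x + t`` maps mobile onto reference, and the post-fit RMSD.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3), got {mob.shape} and {ref.shape}")
    n = mob.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs >= 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    mob_cen = wn @ mob
    ref_cen = wn @ ref
    mob_c = mob - mob_cen
    ref_c = ref - ref_cen
    _check_not_collinear(mob_c)
    _check_not_collinear(ref_c)
    cov = (mob_c * wn[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_cen - rot @ mob_cen
    fitted = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def _check_not_collinear(centered: np.ndarray) -> None:
    s = np.linalg.svd(centered, compute_uv=False)
    scale = s[0] if s[0] > 0 else 1.0
    if s[1] / scale < 1e-8:
        raise ValueError("degenerate (collinear) point configuration")


@dataclass
class DistanceSeries:
    """Per-frame interdomain distance (Å) with summary statistics."""

    values: np.ndarray
    dt: float
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(np.mean(self.values))
        # sample standard deviation; 0.0 for a single frame
        self.sd = float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt


@dataclass
class FlexibilitySeries:
    """Per-frame side-chain RMSD vs frame 0 (Å); ``values[0]`` is 0 by definition."""

    values: np.ndarray
    dt: float
    mean_rmsd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 1:
            raise ValueError("empty flexibility series")
        # mean over frames t >= 1 (frame 0 is the reference itself)
        self.mean_rmsd = float(np.mean(self.values[1:])) if len(self.values) > 1 else 0.0

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.dt


def center_of_mass(
    model: StructureModel,
    sel: DomainSelection | None = None,
    heavy_only: bool = True,
) -> np.ndarray:
    """Mass-weighted mean coordinate of (a selection of) a model.

    Hydrogens are excluded by default so that results do not depend on
    whether a frame set carries explicit protons.
    """
    sub = model if sel is None else select(model, sel)
    atoms = [a for a in sub.atoms if not (heavy_only and a.is_hydrogen)]
    if not atoms:
        raise SelectionError("center_of_mass: selection contains no (heavy) atoms")
    masses = np.array([a.mass for a in atoms])
    coords = np.array([a.coord for a in atoms])
    return (masses @ coords) / masses.sum()


def com_distance_series(
    traj: Trajectory,
    dom_a: DomainSelection,
    dom_b: DomainSelection,
    heavy_only: bool = True,
) -> DistanceSeries:
    """Per-frame distance between the centers of mass of two domains."""
    # resolve atom indices once against the shared topology
    idx_a = _selection_indices(traj.frames[0], dom_a, heavy_only)
    idx_b = _selection_indices(traj.frames[0], dom_b, heavy_only)
    masses = np.array([a.mass for a in traj.frames[0].atoms])
    w_a = masses[idx_a] / masses[idx_a].sum()
    w_b = masses[idx_b] / masses[idx_b].sum()
    values = np.empty(traj.n_frames)
    for t, frame in enumerate(traj.frames):
        coords = frame.coords
        com_a = w_a @ coords[idx_a]
        com_b = w_b @ coords[idx_b]
        values[t] = np.linalg.norm(com_a - com_b)
    return DistanceSeries(values=values, dt=traj.dt)


def _selection_indices(model: StructureModel, sel: DomainSelection, heavy_only: bool) -> np.ndarray:
    idx = [i for i, a in enumerate(model.atoms)
           if sel.contains(a) and not (heavy_only and a.is_hydrogen)]
    if not idx:
        raise SelectionError(f"selection {sel} matched no atoms")
    return np.asarray(idx, dtype=int)


def rotamer_flexibility(
    traj: Trajectory,
    residue: DomainSelection,
    align_on: DomainSelection | list[DomainSelection] | None = None,
    include_cb: bool = True,
) -> FlexibilitySeries:
    """Side-chain flexibility of one residue across a trajectory.

    Each frame is superposed onto frame 0 using the Cα atoms of ``align_on``
    (default: every Cα in the complex, mass-weighted — masses are equal so
    this is a plain least-squares fit), then the RMSD over the residue's
    side-chain heavy atoms (Cβ outward; set ``include_cb=False`` to start at
    Cγ) against their frame-0 positions is recorded.  ``mean_rmsd`` averages
    frames t >= 1.
    """
    if residue.start != residue.end:
        raise ValueError("residue must be a single-residue selection (start == end)")
    frame0 = traj.frames[0]
    ca_idx = _ca_indices(frame0, align_on)
    if len(ca_idx) < 3:
        raise ValueError("alignment selection must contain >= 3 Calpha atoms")
    side_idx = _side_chain_indices(frame0, residue, include_cb)
    masses = np.array([frame0.atoms[i].mass for i in ca_idx])

    coords0 = frame0.coords
    ca_ref = coords0[ca_idx]
    side_ref = coords0[side_idx]
    values = np.empty(traj.n_frames)
    values[0] = 0.0
    for t in range(1, traj.n_frames):
        coords = traj.frames[t].coords
        fit = kabsch_superpose(coords[ca_idx], ca_ref, weights=masses)
        moved = fit.apply(coords[side_idx])
        values[t] = math.sqrt(float(np.mean(np.sum((moved - side_ref) ** 2, axis=1))))
    return FlexibilitySeries(values=values, dt=traj.dt)


def _ca_indices(model: StructureModel, align_on) -> np.ndarray:
    if align_on is None:
        sels = None
    elif isinstance(align_on, DomainSelection):
        sels = [align_on]
    else:
        sels = list(align_on)
    idx = []
    for i, a in enumerate(model.atoms):
        if a.name != "CA" or a.is_hydrogen:
            continue
        if sels is None or any(s.contains(a) for s in sels):
            idx.append(i)
    if not idx:
        raise SelectionError("alignment selection contains no Calpha atoms")
    return np.asarray(idx, dtype=int)


def _side_chain_indices(model: StructureModel, residue: DomainSelection, include_cb: bool) -> np.ndarray:
    skip = set(BACKBONE_NAMES)
    if not include_cb:
        skip.add("CB")
    idx = [i for i, a in enumerate(model.atoms)
           if residue.contains(a) and not a.is_hydrogen and a.name not in skip]
    if not idx:
        raise SelectionError(
            f"residue {residue} has no side-chain heavy atoms (glycine/alanine "
            "side chains carry no rotamer signal)" if include_cb else
            f"residue {residue} has no side-chain heavy atoms beyond Cbeta")
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# Internal-coordinate helpers (shared with the mutation builder)

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, range (−180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0:
        raise ValueError("dihedral: coincident central atoms")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 + 1e-12 else ang


def place_internal(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms a–b–c.

    D is bonded to ``c`` at distance ``bond`` (Å), with angle b–c–D equal to
    ``angle_deg`` and dihedral a–b–c–D equal to ``torsion_deg`` (degrees,
    matching :func:`dihedral_angle`'s sign convention).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("place_internal: reference atoms a, b, c are collinear")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
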