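"""Buried interface area and contact inventories.

The buried area between two domains A and B of a complex is

    B = SASA(A alone) + SASA(B alone) − SASA(A ∪ B),

with SASA the Shrake–Rupley solvent-accessible surface area computed by
sphere sampling: each atom's sphere of radius (vdW + probe) carries a
deterministic golden-spiral point lattice, and the accessible fraction is
the fraction of points outside every neighbouring sphere.  This
solvent-accessible buried area stands in for the solvent-excluded (molecular)
buried surface: the wild-type vs variant *difference* is what the analysis
consumes, and the two surface definitions rank toy interfaces identically.
The approximation is deliberate and recorded here rather than hidden.

Contacts are geometric: hydrogen bonds as donor–acceptor N/O pairs within a
distance cutoff (with a D–H···A angle criterion when the structure carries
hydrogens), salt bridges as basic-nitrogen/carboxylate-oxygen pairs within
their own cutoff.  A pair that qualifies as a salt bridge is recorded as
a salt bridge only, never duplicated as a hydrogen bond.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import DomainSelection, SelectionError, StructureModel, Trajectory, select

__all__ = [
    "SASAResult",
    "BuriedAreaSeries",
    "ContactRecord",
    "ContactDiff",
    "sasa",
    "buried_area",
    "buried_area_series",
    "detect_contacts",
    "contact_diff",
    "timepoint_indices",
    "interface_residues",
]


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit-sphere points on the golden-spiral lattice."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SASAResult:
    """Solvent-accessible surface area: total, per atom and per residue (Å²)."""

    total: float
    per_atom: np.ndarray
    per_residue: dict[tuple[str, int], float]


def sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    n_points: int = 960,
    heavy_only: bool = True,
) -> SASAResult:
    """Shrake–Rupley solvent-accessible surface area.

    Per-atom area is ``4π(r_vdw + probe)²`` times the fraction of lattice
    points not buried inside any neighbour's expanded sphere.  The lattice
    is deterministic (no random numbers), so results are exactly
    reproducible at fixed ``n_points``.
    """
    if n_points < 64:
        raise ValueError(f"n_points must be >= 64, got {n_points}")
    atoms = [a for a in model.atoms if not (heavy_only and a.is_hydrogen)]
    if not atoms:
        raise SelectionError("sasa: no (heavy) atoms in model")
    coords = np.array([a.coord for a in atoms])
    radii = np.array([a.vdw_radius for a in atoms]) + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    r_max = radii.max()
    per_atom = np.empty(len(atoms))
    for i in range(len(atoms)):
        neighbours = tree.query_ball_point(coords[i], radii[i] + r_max)
        neighbours = [j for j in neighbours if j != i]
        pts = coords[i] + radii[i] * unit
        if neighbours:
            nb_coords = coords[neighbours]
            nb_r2 = radii[neighbours] ** 2
            d2 = ((pts[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            accessible = ~np.any(d2 < nb_r2[None, :], axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        per_atom[i] = 4.0 * math.pi * radii[i] ** 2 * frac
    per_residue: dict[tuple[str, int], float] = {}
    for a, area in zip(atoms, per_atom):
        key = (a.chain_id, a.res_seq)
        per_residue[key] = per_residue.get(key, 0.0) + float(area)
    return SASAResult(total=float(per_atom.sum()), per_atom=per_atom, per_residue=per_residue)


def _extract_domains(model: StructureModel, dom_a: DomainSelection, dom_b: DomainSelection):
    part_a = select(model, dom_a, heavy_only=True)
    part_b = select(model, dom_b, heavy_only=True)
    keys_a = set(a.key for a in part_a.atoms)
    overlap = [a.key for a in part_b.atoms if a.key in keys_a]
    if overlap:
        raise ValueError(f"domains {dom_a} and {dom_b} overlap (e.g. atom {overlap[0]})")
    return part_a, part_b


def buried_area(
    model: StructureModel,
    dom_a: DomainSelection,
    dom_b: DomainSelection,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Interface area (Å²) buried between two domains of one frame."""
    value, _ = buried_area_per_residue(model, dom_a, dom_b, probe, n_points)
    return value


def buried_area_per_residue(
    model: StructureModel,
    dom_a: DomainSelection,
    dom_b: DomainSelection,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, dict[tuple[str, int], float]]:
    """Buried area plus each residue's ΔSASA contribution (separate − complex)."""
    part_a, part_b = _extract_domains(model, dom_a, dom_b)
    both = StructureModel(part_a.atoms + part_b.atoms, model.model_id)
    res_a = sasa(part_a, probe, n_points)
    res_b = sasa(part_b, probe, n_points)
    res_ab = sasa(both, probe, n_points)
    value = res_a.total + res_b.total - res_ab.total
    separate = {**res_a.per_residue, **res_b.per_residue}
    delta = {key: separate[key] - res_ab.per_residue.get(key, 0.0) for key in separate}
    return max(value, 0.0), delta


def timepoint_indices(n_frames: int, n_timepoints: int) -> list[int]:
    """``n_timepoints`` equally distributed frame indices, endpoints included.

    Index i maps to ``round(i * (n_frames - 1) / (n_timepoints - 1))``, so the
    last evaluated frame is always the final one.
    """
    if n_timepoints > n_frames:
        raise ValueError(f"n_timepoints ({n_timepoints}) exceeds n_frames ({n_frames})")
    if n_timepoints == 1:
        return [n_frames - 1]
    step = (n_frames - 1) / (n_timepoints - 1)
    return [round(i * step) for i in range(n_timepoints)]


@dataclass
class BuriedAreaSeries:
    """Buried area at sampled frames plus last-frame per-residue contributions."""

    timepoints: list[int]
    values: np.ndarray
    per_residue_last_frame: list[tuple[tuple[str, int], float]]
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.timepoints):
            raise ValueError("values and timepoints length mismatch")
        self.mean = float(np.mean(self.values))


def buried_area_series(
    traj: Trajectory,
    dom_a: DomainSelection,
    dom_b: DomainSelection,
    n_timepoints: int = 10,
    probe: float = 1.4,
    n_points: int = 960,
    contribution_cutoff: float = 1.0,
) -> BuriedAreaSeries:
    """Buried area at equally distributed time points of a trajectory.

    ``per_residue_last_frame`` ranks interface residues of the final frame by
    their ΔSASA contribution; residues below ``contribution_cutoff`` (Å²)
    are treated as noise and dropped.
    """
    indices = timepoint_indices(traj.n_frames, n_timepoints)
    values = np.empty(len(indices))
    per_res_last: dict[tuple[str, int], float] = {}
    for k, idx in enumerate(indices):
        value, delta = buried_area_per_residue(traj.frames[idx], dom_a, dom_b, probe, n_points)
        values[k] = value
        if idx == indices[-1]:
            per_res_last = delta
    ranked = sorted(
        ((key, round(v, 6)) for key, v in per_res_last.items() if v > contribution_cutoff),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return BuriedAreaSeries(timepoints=indices, values=values, per_residue_last_frame=ranked)


# ---------------------------------------------------------------------------
# Contacts

# hydrogen-bond donor heavy atoms (N/O with an attachable proton)
_SIDE_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
    "TRP": {"NE1"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
}
# hydrogen-bond acceptors (N/O with a lone pair)
_SIDE_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}
_CATION_ATOMS = {
    "ARG": {"NH1", "NH2", "NE"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_ANION_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}

AtomId = tuple[str, int, str, str]  # (chain, res_seq, res_name, atom name)


@dataclass(frozen=True)
class ContactRecord:
    """One cross-domain contact (hydrogen bond or salt bridge)."""

    kind: str  # "hbond" | "saltbridge"
    atom_a: AtomId
    atom_b: AtomId
    distance: float
    angle: float | None = None

    @property
    def residue_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.atom_a[0], self.atom_a[1]), (self.atom_b[0], self.atom_b[1]))


def _atom_id(a) -> AtomId:
    return (a.chain_id, a.res_seq, a.res_name, a.name)


def _is_donor(a) -> bool:
    if a.name == "N" and a.res_name != "PRO":
        return True
    return a.name in _SIDE_DONORS.get(a.res_name, ())


def _is_acceptor(a) -> bool:
    if a.name in ("O", "OXT"):
        return True
    return a.name in _SIDE_ACCEPTORS.get(a.res_name, ())


def _attached_hydrogens(model: StructureModel, donor) -> list[np.ndarray]:
    out = []
    for a in model.atoms:
        if (a.is_hydrogen and a.chain_id == donor.chain_id and a.res_seq == donor.res_seq
                and np.linalg.norm(a.coord - donor.coord) <= 1.25):
            out.append(a.coord)
    return out


def detect_contacts(
    model: StructureModel,
    dom_a: DomainSelection,
    dom_b: DomainSelection,
    hbond_dist: float = 3.5,
    salt_dist: float = 4.0,
    hbond_angle: float = 120.0,
) -> list[ContactRecord]:
    """Cross-domain hydrogen bonds and salt bridges of one frame.

    The D–H···A angle criterion (>= ``hbond_angle``°) applies only when the
    structure carries explicit hydrogens; MD snapshot sets saved without
    protons are judged on donor–acceptor distance alone.
    """
    part_a = select(model, dom_a)
    part_b = select(model, dom_b)
    has_hydrogens = any(a.is_hydrogen for a in model.atoms)

    records: list[ContactRecord] = []
    salt_pairs: set[tuple[AtomId, AtomId]] = set()

    def heavy(part):
        return [a for a in part.atoms if not a.is_hydrogen]

    # salt bridges first; these pairs are excluded from the hydrogen-bond scan
    for a in heavy(part_a):
        for b in heavy(part_b):
            for x, y in ((a, b), (b, a)):
                if (x.name in _CATION_ATOMS.get(x.res_name, ()) and
                        y.name in _ANION_ATOMS.get(y.res_name, ())):
                    d = float(np.linalg.norm(a.coord - b.coord))
                    if d <= salt_dist:
                        records.append(ContactRecord("saltbridge", _atom_id(a), _atom_id(b), d))
                        salt_pairs.add((_atom_id(a), _atom_id(b)))
                    break

    for a in heavy(part_a):
        for b in heavy(part_b):
            if (_atom_id(a), _atom_id(b)) in salt_pairs:
                continue
            d = float(np.linalg.norm(a.coord - b.coord))
            if d > hbond_dist:
                continue
            for donor, acceptor in ((a, b), (b, a)):
                if not (_is_donor(donor) and _is_acceptor(acceptor)):
                    continue
                angle = None
                if has_hydrogens:
                    hydrogens = _attached_hydrogens(model, donor)
                    if hydrogens:
                        angles = [_dha_angle(donor.coord, h, acceptor.coord) for h in hydrogens]
                        angle = max(angles)
                        if angle < hbond_angle:
                            continue
                records.append(ContactRecord("hbond", _atom_id(a), _atom_id(b), d, angle))
                break
    records.sort(key=lambda r: (r.kind, r.atom_a, r.atom_b))
    return records


def _dha_angle(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray) -> float:
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


ContactKey = tuple[str, tuple[tuple[str, int], tuple[str, int]]]


@dataclass
class ContactDiff:
    """Wild-type vs variant contact comparison, keyed by (kind, residue pair)."""

    lost: list[ContactKey]
    gained: list[ContactKey]
    retained: list[ContactKey]


def _contact_keys(records: list[ContactRecord]) -> set[ContactKey]:
    keys = set()
    for r in records:
        pair = tuple(sorted(r.residue_pair))
        keys.add((r.kind, pair))
    return keys


def contact_diff(wt: list[ContactRecord], mut: list[ContactRecord]) -> ContactDiff:
    """Contacts lost, gained and retained going from ``wt`` to ``mut``."""
    wt_keys = _contact_keys(wt)
    mut_keys = _contact_keys(mut)
    return ContactDiff(
        lost=sorted(wt_keys - mut_keys),
        gained=sorted(mut_keys - wt_keys),
        retained=sorted(wt_keys & mut_keys),
    )


def interface_residues(
    model: StructureModel,
    dom_a: DomainSelection,
    dom_b: DomainSelection,
    cutoff: float = 1.0,
    probe: float = 1.4,
    n_points: int = 960,
) -> set[tuple[str, int]]:
    """Residues with per-residue ΔSASA above ``cutoff`` Å² at this frame."""
    _, delta = buried_area_per_residue(model, dom_a, dom_b, probe, n_points)
    return {key for key, v in delta.items() if v > cutoff}
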