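"""Synthetic inputs for every pipeline stage.

Real receptor-complex trajectories come from homology modelling plus
molecular dynamics; nothing here attempts physical realism.  What the
generators reproduce is the *statistical structure* the analysis consumes:

* :func:`build_toy_complex` — two idealised α-helical pseudo-domains
  (poly-alanine, chains A and B) docked so that an engineered
  Arg ↔ (Tyr, Thr, Asp) contact triad spans the interface: the arginine
  guanidinium salt-bridged to the aspartate carboxylate and hydrogen-bonded
  to the tyrosine hydroxyl and threonine OG1.  This mirrors the anchoring
  pattern of an arginine at a receptor D3/D3 interface that a
  glutamine substitution cannot maintain.
* :func:`simulate_ensemble` — a conformational ensemble around a complex:
  per frame the second domain is rigidly displaced along the interdomain
  axis by Normal(shift, σ²) (a destabilised variant breathes around a
  larger mean separation), and a designated residue's side chain is rebuilt
  with χ angles jittered by Normal(0, jitter²) (a side chain that lost its
  anchors explores more rotameric space).
* :func:`simulate_msa` — alignments with chosen fully conserved columns
  against a uniform-random background.

All generators are deterministic for a fixed seed, and seeds never change a
topology, only coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .conservation import AA20, MSA
from .geometry import center_of_mass, place_internal
from .mutate import build_cb, build_side_chain, measure_chi_angles, substitute_residue
from .structio import DomainSelection, StructureModel, Trajectory, make_atom

__all__ = [
    "EnsembleParams",
    "ToyComplexSpec",
    "ToyComplexLayout",
    "build_toy_complex",
    "toy_complex_layout",
    "simulate_ensemble",
    "simulate_msa",
    "InfeasibleComplexError",
]


class InfeasibleComplexError(RuntimeError):
    """No docking pose satisfied the requested interface contact geometry."""


@dataclass(frozen=True)
class ToyComplexSpec:
    """Layout of the toy two-helix complex.

    ``interface_triad`` installs Arg on chain A facing Tyr/Thr/Asp on chain
    B with salt-bridge / hydrogen-bond geometry; without it both chains are
    plain poly-alanine helices in loose van-der-Waals contact.
    """

    n_res_a: int = 40
    n_res_b: int = 40
    interface_triad: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_res_a < 3 or self.n_res_b < 3:
            raise ValueError("helices need at least 3 residues")
        if self.interface_triad and (self.n_res_a < 12 or self.n_res_b < 16):
            raise ValueError("the interface triad needs helices of >= 12/16 residues")


@dataclass(frozen=True)
class ToyComplexLayout:
    """Designed residues and domain selections of a toy complex."""

    dom_a: DomainSelection
    dom_b: DomainSelection
    arg: tuple[str, int]
    tyr: tuple[str, int]
    thr: tuple[str, int]
    asp: tuple[str, int]


#: author numbering of the designed residues
_ARG_NUMBER = 281
_TYR_NUMBER = 260


def toy_complex_layout(spec: ToyComplexSpec) -> ToyComplexLayout:
    """Residue numbering of :func:`build_toy_complex` for the same spec."""
    start_a = _ARG_NUMBER - spec.n_res_a // 2
    tyr_idx = spec.n_res_b // 2 - 2
    start_b = _TYR_NUMBER - tyr_idx
    return ToyComplexLayout(
        dom_a=DomainSelection("A", start_a, start_a + spec.n_res_a - 1),
        dom_b=DomainSelection("B", start_b, start_b + spec.n_res_b - 1),
        arg=("A", _ARG_NUMBER),
        tyr=("B", _TYR_NUMBER),
        thr=("B", _TYR_NUMBER + 3),
        asp=("B", _TYR_NUMBER + 4),
    )


# ideal backbone internal coordinates (α-helix)
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _build_backbone(n_res: int) -> list[dict[str, np.ndarray]]:
    """Poly-peptide backbone (N, CA, C, O) of an ideal α-helix."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    ang = math.radians(180.0 - 111.2)
    c0 = ca0 + 1.525 * np.array([math.cos(math.pi - ang), math.sin(math.pi - ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n = place_internal(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, _PSI)
        ca = place_internal(prev["CA"], prev["C"], n, 1.458, 121.7, _OMEGA)
        c = place_internal(prev["C"], n, ca, 1.525, 111.2, _PHI)
        prev["O"] = place_internal(n, prev["CA"], prev["C"], 1.231, 120.8, _PSI + 180.0)
        res.append({"N": n, "CA": ca, "C": c})
    last = res[-1]
    # carbonyl O of the final residue: place trans to an extrapolated psi
    virtual_n = place_internal(last["N"], last["CA"], last["C"], 1.329, 116.2, _PSI)
    last["O"] = place_internal(virtual_n, last["CA"], last["C"], 1.231, 120.8, _PSI + 180.0)
    return res


def _helix_axis(backbone: list[dict[str, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares axis (unit vector) and centroid of the Cα trace."""
    cas = np.array([r["CA"] for r in backbone])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    return vt[0], centroid


def _build_chain(
    chain_id: str,
    start_num: int,
    sequence: dict[int, tuple[str, tuple[float, ...]]],
    n_res: int,
) -> list:
    """Helical chain; ``sequence`` maps residue index to (res_name, chis)."""
    backbone = _build_backbone(n_res)
    atoms = []
    for i, bb in enumerate(backbone):
        res_name, chis = sequence.get(i, ("ALA", ()))
        num = start_num + i
        for name in ("N", "CA", "C", "O"):
            atoms.append(make_atom(0, name, res_name, chain_id, num, bb[name]))
        side = build_side_chain(res_name, bb["N"], bb["CA"], bb["C"], chis)
        for name, coord in side:
            atoms.append(make_atom(0, name, res_name, chain_id, num, coord))
    return atoms


def _pick_outward_rotamer(n_res: int, idx: int, res_name: str,
                          candidates: list[tuple[float, ...]]) -> tuple[float, ...]:
    """The candidate rotamer whose side-chain tip points farthest off the helix axis."""
    backbone = _build_backbone(n_res)
    axis, centroid = _helix_axis(backbone)
    bb = backbone[idx]
    best, best_d = candidates[0], -1.0
    for chis in candidates:
        side = build_side_chain(res_name, bb["N"], bb["CA"], bb["C"], chis)
        tip = side[-1][1]
        v = tip - centroid
        radial = v - np.dot(v, axis) * axis
        d = float(np.linalg.norm(radial))
        if d > best_d:
            best, best_d = chis, d
    return best


def build_toy_complex(spec: ToyComplexSpec) -> StructureModel:
    """Two docked helical pseudo-domains on chains A and B.

    With ``interface_triad`` the pose is found by a deterministic rigid-body
    search that places the chain-B acceptors (Asp carboxylate, Tyr hydroxyl,
    Thr OG1) against the chain-A arginine guanidinium, then verified against
    the contact thresholds (salt bridge <= 3.5 Å, hydrogen bonds <= 3.3 Å);
    an infeasible spec raises :class:`InfeasibleComplexError`.  Coordinates
    are bit-reproducible for a fixed seed.
    """
    layout = toy_complex_layout(spec)
    rng = np.random.default_rng(spec.seed)

    arg_idx = layout.arg[1] - layout.dom_a.start
    tyr_idx = layout.tyr[1] - layout.dom_b.start
    thr_idx = layout.thr[1] - layout.dom_b.start
    asp_idx = layout.asp[1] - layout.dom_b.start

    if not spec.interface_triad:
        atoms_a = _build_chain("A", layout.dom_a.start, {}, spec.n_res_a)
        atoms_b = _build_chain("B", layout.dom_b.start, {}, spec.n_res_b)
        model = _assemble(atoms_a, atoms_b, rng)
        return _dock_parallel(model, separation=9.5)

    arg_chis = _pick_outward_rotamer(
        spec.n_res_a, arg_idx, "ARG",
        [(-60.0, 180.0, 180.0, 180.0), (180.0, 180.0, 180.0, 180.0),
         (60.0, 180.0, 180.0, 180.0)])
    atoms_a = _build_chain("A", layout.dom_a.start,
                           {arg_idx: ("ARG", arg_chis)}, spec.n_res_a)

    tyr_options = [(180.0, 80.0), (-60.0, 90.0), (60.0, 90.0)]
    thr_options = [(60.0,), (180.0,), (-60.0,)]
    asp_options = [(-60.0, -15.0), (180.0, 0.0), (60.0, 10.0)]

    for tyr_chis in tyr_options:
        for asp_chis in asp_options:
            for thr_chis in thr_options:
                atoms_b = _build_chain(
                    "B", layout.dom_b.start,
                    {tyr_idx: ("TYR", tyr_chis), thr_idx: ("THR", thr_chis),
                     asp_idx: ("ASP", asp_chis)}, spec.n_res_b)
                pose = _dock_triad(atoms_a, atoms_b, layout)
                if pose is not None:
                    return _assemble(atoms_a, pose[1], rng)
    raise InfeasibleComplexError(
        "no rigid placement of chain B satisfied the triad contact geometry")


def _assemble(atoms_a: list, atoms_b: list, rng: np.random.Generator) -> StructureModel:
    atoms = atoms_a + atoms_b
    jitter = rng.normal(0.0, 0.02, size=(len(atoms), 3))
    for i, a in enumerate(atoms):
        a.serial = i + 1
        a.coord = a.coord + jitter[i]
    return StructureModel(atoms, model_id=0)


def _dock_parallel(model: StructureModel, separation: float) -> StructureModel:
    """Shift chain B so the two helix axes sit ``separation`` Å apart in x."""
    coords = model.coords
    idx_b = [i for i, a in enumerate(model.atoms) if a.chain_id == "B"]
    idx_a = [i for i, a in enumerate(model.atoms) if a.chain_id == "A"]
    shift = coords[idx_a].mean(axis=0) - coords[idx_b].mean(axis=0)
    shift[0] += separation
    coords[idx_b] += shift
    return model.with_coords(coords)


def _chain_arrays(atoms: list) -> tuple[np.ndarray, dict[tuple[int, str], int]]:
    coords = np.array([a.coord for a in atoms])
    index = {(a.res_seq, a.name): i for i, a in enumerate(atoms)}
    return coords, index


def _dock_triad(atoms_a: list, atoms_b: list, layout: ToyComplexLayout):
    """Rigid placement of chain B against the chain-A arginine.

    Returns (penalty, placed_atoms) for an acceptable pose, else None.
    Deterministic: fixed starting poses, derivative-free local refinement.
    """
    coords_a, idx_a = _chain_arrays(atoms_a)
    coords_b, idx_b = _chain_arrays(atoms_b)
    arg_n = np.array([coords_a[idx_a[(layout.arg[1], nm)]] for nm in ("NE", "NH1", "NH2")])
    acceptors = {
        "asp": np.array([idx_b[(layout.asp[1], "OD1")], idx_b[(layout.asp[1], "OD2")]]),
        "tyr": np.array([idx_b[(layout.tyr[1], "OH")]]),
        "thr": np.array([idx_b[(layout.thr[1], "OG1")]]),
    }
    targets = {"asp": 2.9, "tyr": 3.05, "thr": 3.05}
    # clash screen on backbone + CB + the designed side chains; the designed
    # contact pairs sit above the clash cutoff so no exclusion is needed
    designed_b = {layout.tyr[1], layout.thr[1], layout.asp[1]}
    coarse_a = np.array([a.coord for a in atoms_a
                         if a.name in ("N", "CA", "C", "O", "CB")
                         or a.res_seq == layout.arg[1]])
    coarse_b_idx = [i for i, a in enumerate(atoms_b)
                    if a.name in ("N", "CA", "C", "O", "CB") or a.res_seq in designed_b]
    center_b = coords_b.mean(axis=0)

    # outward direction from chain A at the arginine tip
    axis_a, centroid_a = _helix_axis_from_atoms(atoms_a)
    tip = arg_n.mean(axis=0)
    outward = tip - centroid_a
    outward -= np.dot(outward, axis_a) * axis_a
    outward /= np.linalg.norm(outward)

    def transform(params: np.ndarray) -> np.ndarray:
        rot = Rotation.from_rotvec(params[:3])
        return rot.apply(coords_b - center_b) + center_b + params[3:]

    def penalty(params: np.ndarray) -> float:
        moved = transform(params)
        p = 0.0
        for key, target in targets.items():
            d = np.linalg.norm(moved[acceptors[key]][:, None, :] - arg_n[None, :, :], axis=2)
            p += (d.min() - target) ** 2
        coarse = moved[coarse_b_idx]
        d2 = ((coarse[:, None, :] - coarse_a[None, :, :]) ** 2).sum(axis=2)
        close = np.sqrt(d2[d2 < 2.7 ** 2])
        p += 5.0 * float(((2.7 - close) ** 2).sum())
        return p

    for flip_angle in (0.0, math.pi / 2, math.pi, 3 * math.pi / 2):
        rot0 = Rotation.from_rotvec(flip_angle * axis_a) * Rotation.from_rotvec(
            math.pi * _perp(axis_a))
        moved0 = rot0.apply(coords_b - center_b) + center_b
        # translate so the Asp carboxylate midpoint lands just outside the Arg tip
        asp_mid = moved0[acceptors["asp"]].mean(axis=0)
        t0 = (tip + 3.0 * outward) - asp_mid
        params0 = np.concatenate([rot0.as_rotvec(), t0])
        res = minimize(penalty, params0, method="Nelder-Mead",
                       options={"maxfev": 1500, "xatol": 1e-4, "fatol": 1e-8})
        moved = transform(res.x)
        if _pose_acceptable(moved, atoms_b, acceptors, arg_n, coords_a):
            placed = [make_atom(a.serial, a.name, a.res_name, a.chain_id, a.res_seq, coord,
                                element=a.element)
                      for a, coord in zip(atoms_b, moved)]
            return res.fun, placed
    return None


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _helix_axis_from_atoms(atoms: list) -> tuple[np.ndarray, np.ndarray]:
    cas = np.array([a.coord for a in atoms if a.name == "CA"])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    return vt[0], centroid


def _pose_acceptable(moved_b, atoms_b, acceptors, arg_n, coords_a) -> bool:
    d_asp = np.linalg.norm(moved_b[acceptors["asp"]][:, None, :] - arg_n[None, :, :], axis=2).min()
    d_tyr = np.linalg.norm(moved_b[acceptors["tyr"]][:, None, :] - arg_n[None, :, :], axis=2).min()
    d_thr = np.linalg.norm(moved_b[acceptors["thr"]][:, None, :] - arg_n[None, :, :], axis=2).min()
    if d_asp > 3.4 or d_tyr > 3.25 or d_thr > 3.25:
        return False
    heavy_b = np.array([c for a, c in zip(atoms_b, moved_b) if not a.is_hydrogen])
    d2 = ((heavy_b[:, None, :] - coords_a[None, :, :]) ** 2).sum(axis=2)
    return bool(math.sqrt(float(d2.min())) >= 2.2)


# ---------------------------------------------------------------------------
# Conformational ensembles


@dataclass(frozen=True)
class EnsembleParams:
    """Statistical knobs of a simulated ensemble.

    ``com_shift`` displaces the mobile domain along the interdomain axis by
    Normal(shift, sigma²) per frame (a destabilised complex breathes around
    a larger separation); ``chi_jitter_deg`` is the per-frame Gaussian
    spread of the watched residue's χ angles.  ``dt`` defaults to 0.1 ns
    (one snapshot every 0.1 ns of a 1 ns run); dense distance sampling (500
    frames over 1 ns) corresponds to dt = 0.002 ns.
    """

    n_frames: int = 500
    dt: float = 0.002
    com_mean: float | None = None
    com_sigma: float = 0.3
    com_shift: float = 0.0
    chi_jitter_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        if self.com_sigma < 0 or self.chi_jitter_deg < 0:
            raise ValueError("spreads must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def simulate_ensemble(
    model: StructureModel,
    params: EnsembleParams,
    mutated_residue: tuple[str, int] | None = None,
    mobile_chain: str | None = None,
) -> Trajectory:
    """Simulate a conformational ensemble around ``model``.

    Frame 0 is the (re-idealised) input pose; each later frame translates
    the mobile chain (default: the last chain) along the interdomain axis
    by an independent Normal(com_shift, com_sigma²) draw and, when
    ``mutated_residue`` is given, rebuilds that residue's side chain with
    χ angles jittered by Normal(0, chi_jitter_deg²).  The topology is
    identical in every frame.
    """
    chains = model.chain_ids
    if len(chains) < 2:
        raise ValueError("ensemble simulation needs a two-chain complex")
    mobile = mobile_chain if mobile_chain is not None else chains[-1]
    if mobile not in chains:
        raise ValueError(f"mobile chain {mobile!r} not in model")
    fixed = [c for c in chains if c != mobile]

    rng = np.random.default_rng(params.seed)

    base_chis: list[float] | None = None
    res_name = None
    if mutated_residue is not None:
        chain_id, res_seq = mutated_residue
        res_atoms = model.residue_atoms(chain_id, res_seq)  # raises if absent
        res_name = res_atoms[0].res_name
        base_chis = measure_chi_angles(model, chain_id, res_seq)
        # rebuild once at the measured angles so every frame (including
        # frame 0) shares the template atom ordering
        model = substitute_residue(model, chain_id, res_seq, res_name,
                                   chi_angles=base_chis)

    idx_mobile = np.array([i for i, a in enumerate(model.atoms) if a.chain_id == mobile])
    masses = np.array([a.mass for a in model.atoms])
    heavy = np.array([not a.is_hydrogen for a in model.atoms])
    coords0 = model.coords

    def chain_com(coords: np.ndarray, chain_ids: list[str]) -> np.ndarray:
        idx = np.array([i for i, a in enumerate(model.atoms)
                        if a.chain_id in chain_ids and heavy[i]])
        w = masses[idx] / masses[idx].sum()
        return w @ coords[idx]

    axis = chain_com(coords0, [mobile]) - chain_com(coords0, fixed)
    axis = axis / np.linalg.norm(axis)

    if params.com_mean is not None:
        current = float(np.linalg.norm(chain_com(coords0, [mobile]) - chain_com(coords0, fixed)))
        coords0 = coords0.copy()
        coords0[idx_mobile] += (params.com_mean - current) * axis
        model = model.with_coords(coords0)

    deltas = np.concatenate([[0.0], rng.normal(params.com_shift, params.com_sigma,
                                               size=params.n_frames - 1)])
    frames: list[StructureModel] = []
    for t in range(params.n_frames):
        frame = model
        if mutated_residue is not None and t > 0 and params.chi_jitter_deg > 0:
            chain_id, res_seq = mutated_residue
            jit = rng.normal(0.0, params.chi_jitter_deg, size=len(base_chis))
            chis = [c + j for c, j in zip(base_chis, jit)]
            frame = substitute_residue(frame, chain_id, res_seq, res_name, chi_angles=chis)
        coords = frame.coords
        coords[idx_mobile] += deltas[t] * axis
        frames.append(frame.with_coords(coords, model_id=t))
    return Trajectory(frames, dt=params.dt)


# ---------------------------------------------------------------------------
# Synthetic alignments


def simulate_msa(
    n_seqs: int,
    length: int,
    conserved_columns: set[int] | None = None,
    seed: int = 0,
    gap_fraction: float = 0.0,
) -> MSA:
    """An alignment with chosen fully conserved columns (1-based indices).

    Conserved columns carry one fixed residue (drawn once per column);
    every other position is i.i.d. uniform over the 20 amino acids.  With
    ``gap_fraction`` > 0, that fraction of non-conserved cells is gapped.
    """
    conserved = set(conserved_columns or ())
    bad = [c for c in conserved if not 1 <= c <= length]
    if bad:
        raise ValueError(f"conserved columns {bad} outside 1..{length}")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AA20))
    mat = aas[rng.integers(0, 20, size=(n_seqs, length))]
    for col in conserved:
        mat[:, col - 1] = aas[rng.integers(0, 20)]
    if gap_fraction > 0:
        mask = rng.random(size=(n_seqs, length)) < gap_fraction
        for col in conserved:
            mask[:, col - 1] = False
        mat[mask] = GAP_CHAR
    rows = ["".join(r) for r in mat]
    ids = [f"seq{i + 1}" for i in range(n_seqs)]
    return MSA(ids=ids, rows=rows)


GAP_CHAR = "-"
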