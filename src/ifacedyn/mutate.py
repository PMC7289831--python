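"""In-silico point substitution with a backbone-independent mini rotamer library.

A substitution (e.g. Arg → Gln at GP130 position 281) keeps the backbone
fixed and rebuilds the side chain from ideal bond lengths/angles at the
rotamer with the highest probability in the library (ties broken by file
order).  The library ships in-repo as a TSV
(``res_name  chi1  chi2  chi3  chi4  probability``) holding a handful of
canonical backbone-independent rotamers per residue type; the point of the
module is the selection rule and the geometric rebuild, not the statistics
of any particular published library.

No steric relaxation is performed: the rebuilt side chain is ideal-geometry
only.  Proline's ring closure (CD–N bond) is not enforced, so substitutions
to proline are geometrically approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np

from .geometry import BACKBONE_NAMES, dihedral_angle, place_internal
from .structio import SelectionError, StructureModel, make_atom

__all__ = [
    "RotamerDefinition",
    "load_rotamer_library",
    "substitute_residue",
    "measure_chi_angles",
    "build_side_chain",
    "build_cb",
    "CHI_ATOMS",
    "SIDE_CHAIN_TEMPLATES",
    "N_CHI",
]


@dataclass(frozen=True)
class RotamerDefinition:
    """One canonical rotamer: χ angles (degrees) and its population probability."""

    res_name: str
    chi_angles: tuple[float, ...]
    probability: float


# χ dihedral definitions (standard; χ1 = N-CA-CB-CG etc.)
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [],
    "GLY": [],
}

N_CHI = {name: len(chis) for name, chis in CHI_ATOMS.items()}

# Side-chain build templates beyond CB.  Each atom is placed by internal
# coordinates (bond to parent c, angle b-c-atom, dihedral a-b-c-atom) where
# the dihedral is chi[k] + delta degrees.  (name, (a, b, c), bond, angle,
# chi_index (1-based), delta).
_T = tuple[str, tuple[str, str, str], float, float, int, float]
SIDE_CHAIN_TEMPLATES: dict[str, list[_T]] = {
    "ALA": [],
    "GLY": [],
    "SER": [("OG", ("N", "CA", "CB"), 1.42, 111.1, 1, 0.0)],
    "CYS": [("SG", ("N", "CA", "CB"), 1.81, 114.0, 1, 0.0)],
    "THR": [("OG1", ("N", "CA", "CB"), 1.43, 109.6, 1, 0.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, 1, -120.0)],
    "VAL": [("CG1", ("N", "CA", "CB"), 1.52, 110.5, 1, 0.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, 1, 122.0)],
    "ILE": [("CG1", ("N", "CA", "CB"), 1.53, 110.4, 1, 0.0),
            ("CG2", ("N", "CA", "CB"), 1.52, 110.5, 1, -122.0),
            ("CD1", ("CA", "CB", "CG1"), 1.51, 113.8, 2, 0.0)],
    "LEU": [("CG", ("N", "CA", "CB"), 1.53, 116.3, 1, 0.0),
            ("CD1", ("CA", "CB", "CG"), 1.52, 110.7, 2, 0.0),
            ("CD2", ("CA", "CB", "CG"), 1.52, 110.7, 2, 122.0)],
    "ASP": [("CG", ("N", "CA", "CB"), 1.52, 112.6, 1, 0.0),
            ("OD1", ("CA", "CB", "CG"), 1.25, 118.3, 2, 0.0),
            ("OD2", ("CA", "CB", "CG"), 1.25, 118.3, 2, 180.0)],
    "ASN": [("CG", ("N", "CA", "CB"), 1.52, 112.6, 1, 0.0),
            ("OD1", ("CA", "CB", "CG"), 1.23, 120.8, 2, 0.0),
            ("ND2", ("CA", "CB", "CG"), 1.33, 116.4, 2, 180.0)],
    "GLU": [("CG", ("N", "CA", "CB"), 1.52, 114.1, 1, 0.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, 2, 0.0),
            ("OE1", ("CB", "CG", "CD"), 1.25, 118.3, 3, 0.0),
            ("OE2", ("CB", "CG", "CD"), 1.25, 118.3, 3, 180.0)],
    "GLN": [("CG", ("N", "CA", "CB"), 1.52, 114.1, 1, 0.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 112.6, 2, 0.0),
            ("OE1", ("CB", "CG", "CD"), 1.23, 120.8, 3, 0.0),
            ("NE2", ("CB", "CG", "CD"), 1.33, 116.4, 3, 180.0)],
    "MET": [("CG", ("N", "CA", "CB"), 1.52, 114.1, 1, 0.0),
            ("SD", ("CA", "CB", "CG"), 1.80, 112.7, 2, 0.0),
            ("CE", ("CB", "CG", "SD"), 1.79, 100.9, 3, 0.0)],
    "LYS": [("CG", ("N", "CA", "CB"), 1.52, 114.1, 1, 0.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.8, 2, 0.0),
            ("CE", ("CB", "CG", "CD"), 1.52, 111.8, 3, 0.0),
            ("NZ", ("CG", "CD", "CE"), 1.49, 111.9, 4, 0.0)],
    "ARG": [("CG", ("N", "CA", "CB"), 1.52, 114.1, 1, 0.0),
            ("CD", ("CA", "CB", "CG"), 1.52, 111.8, 2, 0.0),
            ("NE", ("CB", "CG", "CD"), 1.46, 111.9, 3, 0.0),
            ("CZ", ("CG", "CD", "NE"), 1.33, 124.2, 4, 0.0),
            # planar guanidinium: NH1 cis, NH2 trans to CD about NE-CZ
            ("NH1", ("CD", "NE", "CZ"), 1.33, 120.0, 0, 0.0),
            ("NH2", ("CD", "NE", "CZ"), 1.33, 120.0, 0, 180.0)],
    "PHE": [("CG", ("N", "CA", "CB"), 1.50, 113.8, 1, 0.0),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, 2, 0.0),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, 2, 180.0),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 120.1, 0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 120.1, 0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0, 0.0)],
    "TYR": [("CG", ("N", "CA", "CB"), 1.51, 113.9, 1, 0.0),
            ("CD1", ("CA", "CB", "CG"), 1.39, 120.8, 2, 0.0),
            ("CD2", ("CA", "CB", "CG"), 1.39, 120.8, 2, 180.0),
            ("CE1", ("CB", "CG", "CD1"), 1.39, 121.1, 0, 180.0),
            ("CE2", ("CB", "CG", "CD2"), 1.39, 121.1, 0, 180.0),
            ("CZ", ("CG", "CD1", "CE1"), 1.38, 119.5, 0, 0.0),
            ("OH", ("CD1", "CE1", "CZ"), 1.38, 119.8, 0, 180.0)],
    "HIS": [("CG", ("N", "CA", "CB"), 1.49, 113.7, 1, 0.0),
            ("ND1", ("CA", "CB", "CG"), 1.38, 122.7, 2, 0.0),
            ("CD2", ("CA", "CB", "CG"), 1.35, 131.0, 2, 180.0),
            ("CE1", ("CB", "CG", "ND1"), 1.32, 109.0, 0, 180.0),
            ("NE2", ("CB", "CG", "CD2"), 1.37, 107.2, 0, 180.0)],
    "TRP": [("CG", ("N", "CA", "CB"), 1.50, 113.6, 1, 0.0),
            ("CD1", ("CA", "CB", "CG"), 1.37, 126.9, 2, 0.0),
            ("CD2", ("CA", "CB", "CG"), 1.43, 126.8, 2, 180.0),
            ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 0, 180.0),
            ("CE2", ("CG", "CD1", "NE1"), 1.37, 109.0, 0, 0.0),
            ("CE3", ("CG", "CD1", "CD2"), 1.40, 133.9, 0, 180.0),
            ("CZ2", ("CD1", "NE1", "CE2"), 1.39, 130.1, 0, 180.0),
            ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.8, 0, 180.0),
            ("CH2", ("CD2", "CE3", "CZ3"), 1.40, 121.1, 0, 0.0)],
    "PRO": [("CG", ("N", "CA", "CB"), 1.50, 104.5, 1, 0.0),
            ("CD", ("CA", "CB", "CG"), 1.51, 106.1, 2, 0.0)],
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@lru_cache(maxsize=1)
def load_rotamer_library(path: str | None = None) -> dict[str, list[RotamerDefinition]]:
    """Load the rotamer library TSV (the bundled one by default).

    Returns a mapping res_name -> rotamers in file order.  Probabilities of
    each residue type must sum to <= 1 and the χ count must match the
    residue type.
    """
    if path is None:
        text = resources.files("ifacedyn.data").joinpath("rotamers.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    expected = ["res_name", "chi1", "chi2", "chi3", "chi4", "probability"]
    if header != expected:
        raise ValueError(f"rotamer library header {header} != {expected}")
    lib: dict[str, list[RotamerDefinition]] = {}
    for ln in lines[1:]:
        fields = ln.split("\t")
        name = fields[0].upper()
        chis = tuple(float(f) for f in fields[1:5] if f.strip() != "")
        prob = float(fields[5])
        if name not in N_CHI:
            raise ValueError(f"unknown residue {name!r} in rotamer library")
        if len(chis) != N_CHI[name]:
            raise ValueError(f"{name}: expected {N_CHI[name]} chi angles, got {len(chis)}")
        if not 0 <= prob <= 1:
            raise ValueError(f"{name}: probability {prob} outside [0, 1]")
        lib.setdefault(name, []).append(RotamerDefinition(name, chis, prob))
    for name, rots in lib.items():
        if sum(r.probability for r in rots) > 1 + 1e-9:
            raise ValueError(f"{name}: rotamer probabilities sum above 1")
    return lib


def best_rotamer(res_name: str, library=None) -> RotamerDefinition:
    """The rotamer with the highest probability (ties: first in file order)."""
    res_name = res_name.upper()
    if N_CHI.get(res_name) == 0:
        return RotamerDefinition(res_name, (), 1.0)
    lib = library if library is not None else load_rotamer_library()
    if res_name not in lib:
        raise KeyError(f"no rotamers for residue {res_name!r}")
    rots = lib[res_name]
    best = max(range(len(rots)), key=lambda i: (rots[i].probability, -i))
    return rots[best]


def build_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal Cβ position from backbone N, CA, C (L-amino-acid chirality)."""
    return place_internal(c, n, ca, 1.53, 110.5, -122.5)


def build_side_chain(
    res_name: str,
    n: np.ndarray,
    ca: np.ndarray,
    c: np.ndarray,
    chi_angles: Sequence[float],
    cb: np.ndarray | None = None,
) -> list[tuple[str, np.ndarray]]:
    """Heavy side-chain atoms (CB outward) for one residue at given χ angles.

    Atoms are returned in template order.  For glycine the list is empty;
    for alanine it contains CB only.
    """
    res_name = res_name.upper()
    if res_name not in SIDE_CHAIN_TEMPLATES:
        raise KeyError(f"unknown residue code {res_name!r}")
    need = N_CHI[res_name]
    if len(chi_angles) < need:
        raise ValueError(f"{res_name} needs {need} chi angles, got {len(chi_angles)}")
    if res_name == "GLY":
        return []
    pos: dict[str, np.ndarray] = {"N": np.asarray(n, float), "CA": np.asarray(ca, float),
                                  "C": np.asarray(c, float)}
    pos["CB"] = build_cb(pos["N"], pos["CA"], pos["C"]) if cb is None else np.asarray(cb, float)
    out: list[tuple[str, np.ndarray]] = [("CB", pos["CB"])]
    for name, (a, b, cn), bond, angle, chi_idx, delta in SIDE_CHAIN_TEMPLATES[res_name]:
        torsion = delta if chi_idx == 0 else chi_angles[chi_idx - 1] + delta
        coord = place_internal(pos[a], pos[b], pos[cn], bond, angle, torsion)
        pos[name] = coord
        out.append((name, coord))
    return out


def substitute_residue(
    model: StructureModel,
    chain_id: str,
    res_seq: int,
    new_res: str,
    library=None,
    chi_angles: Sequence[float] | None = None,
) -> StructureModel:
    """Replace one residue's side chain, keeping the backbone fixed.

    The new side chain is built from ideal geometry at ``chi_angles`` if
    given, otherwise at the library rotamer with the highest probability.
    All atoms outside the target residue are untouched; within the residue
    the backbone (N, CA, C, O, OXT) is kept and everything else (old side
    chain, hydrogens) replaced.  Serial numbers are renumbered 1..n; atom
    order is otherwise preserved.
    """
    new_res = new_res.upper()
    if new_res not in SIDE_CHAIN_TEMPLATES:
        raise KeyError(f"unknown residue code {new_res!r}")
    res_atoms = model.residue_atoms(chain_id, res_seq)
    by_name = {a.name: a for a in res_atoms}
    missing = [nm for nm in ("N", "CA", "C", "O") if nm not in by_name]
    if missing:
        raise SelectionError(
            f"residue {chain_id}:{res_seq} lacks backbone atoms {missing}; cannot substitute")
    if chi_angles is None:
        chi_angles = best_rotamer(new_res, library).chi_angles
    cb = by_name["CB"].coord if "CB" in by_name and new_res != "GLY" else None
    side = build_side_chain(new_res, by_name["N"].coord, by_name["CA"].coord,
                            by_name["C"].coord, chi_angles, cb=cb)

    new_atoms = []
    inserted = False
    for a in model.atoms:
        if a.chain_id == chain_id and a.res_seq == res_seq:
            if a.name in BACKBONE_NAMES:
                new_atoms.append(replace(a, res_name=new_res))
            elif not inserted:
                # side chain goes where the old one started
                for name, coord in side:
                    new_atoms.append(make_atom(0, name, new_res, chain_id, res_seq, coord))
                inserted = True
        else:
            new_atoms.append(a)
    if not inserted and side:
        # original residue had no side-chain atoms (e.g. glycine): append
        # the new side chain after the residue's backbone block
        new_atoms = []
        for a in model.atoms:
            new_atoms.append(replace(a, res_name=new_res)
                             if (a.chain_id == chain_id and a.res_seq == res_seq) else a)
            if (a.chain_id == chain_id and a.res_seq == res_seq and a.name == "O"):
                for name, coord in side:
                    new_atoms.append(make_atom(0, name, new_res, chain_id, res_seq, coord))
    for i, a in enumerate(new_atoms):
        a.serial = i + 1
    return StructureModel(new_atoms, model.model_id)


def measure_chi_angles(model: StructureModel, chain_id: str, res_seq: int) -> list[float]:
    """The residue's χ dihedrals (degrees, (−180, 180]) from its coordinates."""
    res_atoms = model.residue_atoms(chain_id, res_seq)
    res_name = res_atoms[0].res_name.upper()
    if res_name not in CHI_ATOMS:
        raise KeyError(f"unknown residue code {res_name!r}")
    by_name = {a.name: a.coord for a in res_atoms}
    chis = []
    for quad in CHI_ATOMS[res_name]:
        missing = [nm for nm in quad if nm not in by_name]
        if missing:
            raise SelectionError(
                f"residue {chain_id}:{res_seq} ({res_name}) lacks atoms {missing} "
                f"for chi{len(chis) + 1}")
        chis.append(dihedral_angle(*(by_name[nm] for nm in quad)))
    return chis
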