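"""Structure and sequence I/O: PDB frames/trajectories, aligned FASTA, variant tables.

Multi-MODEL PDB files are treated as a trajectory of frames sharing one
topology, the way an MD snapshot series saved as PDB is organised.  Atom
masses and van-der-Waals radii come from a small built-in element table, so
downstream mass-weighted and surface metrics need no external dictionaries.

Conventions:

* residue numbering is author numbering; residue ranges are inclusive on
  both ends;
* alternate locations: only altloc ``' '`` or ``'A'`` is kept; insertion
  codes are rejected;
* HETATM records (ligands, waters) are dropped; dropped waters are counted
  and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Trajectory",
    "DomainSelection",
    "PDBParseError",
    "TopologyError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "select",
    "read_alignment",
    "read_variant_table",
]

#: atomic mass (amu) and van-der-Waals radius (Å, Bondi) per element
ELEMENT_TABLE: dict[str, tuple[float, float]] = {
    "H": (1.008, 1.20),
    "C": (12.011, 1.70),
    "N": (14.007, 1.55),
    "O": (15.999, 1.52),
    "S": (32.06, 1.80),
    "P": (30.974, 1.80),
    "SE": (78.971, 1.90),
}

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


class PDBParseError(ValueError):
    """Malformed PDB content; message names the offending line number."""


class TopologyError(ValueError):
    """Frames of a multi-MODEL file do not share one atom topology."""


class SelectionError(ValueError):
    """A domain selection matched no atoms (never a silent empty set)."""


@dataclass
class AtomRecord:
    """One atom of one coordinate frame."""

    serial: int
    name: str
    element: str
    res_name: str
    chain_id: str
    res_seq: int
    coord: np.ndarray
    mass: float
    vdw_radius: float

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValueError(f"coord must be a 3-vector, got shape {self.coord.shape}")
        if self.mass <= 0:
            raise ValueError(f"atom mass must be positive, got {self.mass}")
        if self.vdw_radius <= 0:
            raise ValueError(f"vdW radius must be positive, got {self.vdw_radius}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.name)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


def make_atom(
    serial: int,
    name: str,
    res_name: str,
    chain_id: str,
    res_seq: int,
    coord: Sequence[float],
    element: str | None = None,
) -> AtomRecord:
    """Build an :class:`AtomRecord`, inferring element/mass/radius from the name."""
    if element is None:
        element = infer_element(name)
    element = element.upper()
    if element not in ELEMENT_TABLE:
        raise ValueError(f"element {element!r} (atom {name!r}) not in built-in table")
    mass, vdw = ELEMENT_TABLE[element]
    return AtomRecord(serial, name, element, res_name, chain_id, res_seq,
                      np.asarray(coord, dtype=float), mass, vdw)


def infer_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name (heavy atoms + H)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two == "SE":
        return "SE"
    return stripped[0].upper()


@dataclass
class StructureModel:
    """One coordinate frame: an ordered list of atoms.

    ``(chain_id, res_seq, name)`` is unique within a model and serves as the
    topology key shared by all frames of a :class:`Trajectory`.
    """

    atoms: list[AtomRecord]
    model_id: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a StructureModel needs at least one atom")
        keys = [a.key for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen: set[tuple[str, int, str]] = set()
            for k in keys:
                if k in seen:
                    raise ValueError(f"duplicate atom {k} in model {self.model_id}")
                seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (a copy)."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def topology(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(a.key for a in self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "StructureModel":
        """A new model sharing atom metadata but with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [replace(a, coord=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return StructureModel(atoms, self.model_id if model_id is None else model_id)

    def atom(self, chain_id: str, res_seq: int, name: str) -> AtomRecord:
        for a in self.atoms:
            if a.key == (chain_id, res_seq, name):
                return a
        raise SelectionError(f"no atom {(chain_id, res_seq, name)} in model {self.model_id}")

    def residue_atoms(self, chain_id: str, res_seq: int) -> list[AtomRecord]:
        out = [a for a in self.atoms if a.chain_id == chain_id and a.res_seq == res_seq]
        if not out:
            raise SelectionError(f"no residue {chain_id}:{res_seq} in model {self.model_id}")
        return out

    def residues(self) -> list[tuple[str, int, str]]:
        """(chain_id, res_seq, res_name) triples in order of first appearance."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.res_seq), a.res_name)
        return [(c, r, n) for (c, r), n in seen.items()]


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, with a time step ``dt`` in ns."""

    frames: list[StructureModel]
    dt: float = 0.1

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a Trajectory needs at least one frame")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        ref = self.frames[0].topology
        for i, f in enumerate(self.frames[1:], start=1):
            if f.topology != ref:
                raise TopologyError(_topology_mismatch_msg(ref, f.topology, i))

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def _topology_mismatch_msg(ref, other, frame_index: int) -> str:
    if len(ref) != len(other):
        return (f"frame {frame_index} has {len(other)} atoms, frame 0 has {len(ref)}")
    for a, b in zip(ref, other):
        if a != b:
            return f"frame {frame_index}: atom {b} where frame 0 has {a}"
    return f"frame {frame_index} topology differs from frame 0"


@dataclass(frozen=True)
class DomainSelection:
    """A chain plus an inclusive author-numbered residue range."""

    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start ({self.start}) must be <= end ({self.end})")

    def contains(self, atom: AtomRecord) -> bool:
        return atom.chain_id == self.chain_id and self.start <= atom.res_seq <= self.end

    @classmethod
    def parse(cls, text: str) -> "DomainSelection":
        """Parse ``"A:198-298"`` or ``"A:281"`` (single residue)."""
        try:
            chain, rng = text.split(":")
            if "-" in rng.lstrip("-"):
                lo, hi = rng.rsplit("-", 1)
                return cls(chain, int(lo), int(hi))
            return cls(chain, int(rng), int(rng))
        except (ValueError, IndexError) as exc:
            raise ValueError(f"cannot parse domain selection {text!r}") from exc

    def __str__(self) -> str:
        if self.start == self.end:
            return f"{self.chain_id}:{self.start}"
        return f"{self.chain_id}:{self.start}-{self.end}"


def select(model: StructureModel, sel: DomainSelection, heavy_only: bool = False) -> StructureModel:
    """Atoms of ``model`` falling inside ``sel``, order preserved.

    Raises :class:`SelectionError` if the selection is empty — a silent empty
    set would make downstream means/COMs fail obscurely.
    """
    atoms = [a for a in model.atoms if sel.contains(a)]
    if heavy_only:
        atoms = [a for a in atoms if not a.is_hydrogen]
    if not atoms:
        raise SelectionError(f"selection {sel} matched no atoms in model {model.model_id}")
    return StructureModel(atoms, model.model_id)


# ---------------------------------------------------------------------------
# PDB reading / writing (fixed-column ATOM / MODEL / ENDMDL / TER records)

def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    """Parse one ATOM record; returns None for skipped altlocs."""
    altloc = line[16:17]
    if altloc not in (" ", "A"):
        return None
    icode = line[26:27]
    if icode.strip():
        raise PDBParseError(f"line {lineno}: insertion codes are unsupported ({icode!r})")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21:22]
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM record: {line.rstrip()!r}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    try:
        return make_atom(serial, name, res_name, chain_id, res_seq, (x, y, z),
                         element=element or None)
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: {exc}") from exc


def read_pdb(path: str | Path, dt: float = 0.1) -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file into a :class:`Trajectory`.

    One frame per MODEL record; a file without MODEL records yields a single
    frame.  Element symbols are taken from columns 77–78 when present and
    inferred from the atom name otherwise.  HETATM records are dropped
    (waters with a logged count).
    """
    path = Path(path)
    frames: list[StructureModel] = []
    current: list[AtomRecord] = []
    model_ids: list[int] = []
    in_model = False
    n_waters = 0
    n_hetero = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current:
                    raise PDBParseError(f"line {lineno}: MODEL record inside an open model")
                in_model = True
                try:
                    model_ids.append(int(line[10:14]))
                except ValueError:
                    model_ids.append(len(frames) + 1)
            elif rec == "ENDMDL":
                if not current:
                    raise PDBParseError(f"line {lineno}: ENDMDL without atoms")
                frames.append(StructureModel(current, model_ids[-1] if model_ids else len(frames)))
                current = []
                in_model = False
            elif rec == "ATOM  ":
                atom = _parse_atom_line(line, lineno)
                if atom is not None:
                    current.append(atom)
            elif rec == "HETATM":
                res_name = line[17:20].strip()
                if res_name in _WATER_RESNAMES:
                    n_waters += 1
                else:
                    n_hetero += 1
    if current:
        if in_model:
            raise PDBParseError(f"{path}: final MODEL not closed by ENDMDL")
        frames.append(StructureModel(current, model_ids[0] if model_ids else 0))
    if n_waters or n_hetero:
        logger.info("%s: dropped %d water and %d other HETATM records", path, n_waters, n_hetero)
    if not frames:
        raise PDBParseError(f"{path}: no ATOM records found")
    return Trajectory(frames, dt=dt)


def _format_atom_name(name: str) -> str:
    # one-letter elements start in column 14, four-character names in column 13
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def write_pdb(traj: Trajectory | StructureModel, path: str | Path) -> Path:
    """Write a trajectory (MODEL/ENDMDL per frame) or a single frame (no MODEL).

    Round-trips through :func:`read_pdb` reproduce coordinates to 1e-3 Å
    (the PDB fixed-width limit) and topology exactly.
    """
    if isinstance(traj, StructureModel):
        traj = Trajectory([traj], dt=0.1)
    path = Path(path)
    multi = traj.n_frames > 1
    lines: list[str] = []
    for i, frame in enumerate(traj.frames):
        if multi:
            lines.append(f"MODEL {i + 1:>8d}")
        prev_chain: str | None = None
        serial = 0
        last: AtomRecord | None = None
        for a in frame.atoms:
            if prev_chain is not None and a.chain_id != prev_chain and last is not None:
                serial += 1
                lines.append(_ter_line(serial, last))
            serial += 1
            x, y, z = a.coord
            lines.append(
                f"ATOM  {serial:>5d} {_format_atom_name(a.name)} {a.res_name:>3s} "
                f"{a.chain_id}{a.res_seq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
            )
            prev_chain = a.chain_id
            last = a
        if last is not None:
            serial += 1
            lines.append(_ter_line(serial, last))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def _ter_line(serial: int, last: AtomRecord) -> str:
    return (f"TER   {serial:>5d}      {last.res_name:>3s} "
            f"{last.chain_id}{last.res_seq:>4d}")


# ---------------------------------------------------------------------------
# Aligned FASTA and variant-frequency tables

def read_alignment(path: str | Path):
    """Read an aligned FASTA file into an :class:`ifacedyn.conservation.MSA`.

    All sequences must have equal (aligned) length; case is normalised to
    upper; ``.`` gaps are mapped to ``-``.
    """
    from Bio import AlignIO

    from .conservation import MSA

    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValueError(f"{path}: not a valid aligned FASTA ({exc})") from exc
    ids = [rec.id for rec in aln]
    rows = [str(rec.seq).upper().replace(".", "-") for rec in aln]
    return MSA(ids=ids, rows=rows)


VARIANT_TABLE_COLUMNS = ["res_seq", "ref_aa", "alt_aa", "maf"]


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of population variants: ``res_seq  ref_aa  alt_aa  maf``.

    Minor allele frequencies must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: variant table missing columns {missing}")
    df = df[VARIANT_TABLE_COLUMNS].copy()
    df["res_seq"] = df["res_seq"].astype(int)
    df["maf"] = df["maf"].astype(float)
    bad = df[(df["maf"] < 0) | (df["maf"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: maf outside [0, 1] at res_seq "
                         f"{bad['res_seq'].tolist()}")
    return df
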