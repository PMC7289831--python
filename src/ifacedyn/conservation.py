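"""Entropy-based per-column conservation of a multiple sequence alignment.

For each alignment column the amino-acid frequencies :math:`p_i` over the
non-gap symbols give a Shannon entropy :math:`H = -\\sum_i p_i \\ln p_i`,
normalised to a conservation score

    score = 1 − H / ln 20,

so a fully conserved column scores 1 and a column uniform over the 20 amino
acids scores 0.  This is the unweighted entropy measure of the AL2CO family
of column-conservation statistics.  Columns whose gap fraction exceeds a
threshold are marked undefined (NaN) rather than given a misleading number.

Scores can be mapped onto a structure chain through a reference alignment
row and annotated with population minor-allele frequencies, mirroring how
conservation and ExAC variant maps are painted onto receptor-interface
structures.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import StructureModel

logger = logging.getLogger(__name__)

__all__ = [
    "MSA",
    "ConservationProfile",
    "conservation_scores",
    "map_profile",
    "annotate_frequencies",
    "interface_conservation_summary",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AA20)
GAP = "-"


@dataclass
class MSA:
    """Aligned sequences over the 20 amino acids plus gap.

    Unknown symbols are normalised to ``X`` and excluded from frequency
    counts, like gaps.
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if not self.rows:
            raise ValueError("empty alignment")
        length = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != length:
                raise ValueError(
                    f"ragged alignment: sequence {self.ids[i]!r} has length "
                    f"{len(row)}, expected {length}")
        self.rows = ["".join(c if (c in _AA_SET or c == GAP) else "X"
                             for c in row.upper()) for row in self.rows]

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"sequence {seq_id!r} not in alignment") from None

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


@dataclass
class ConservationProfile:
    """Per-column conservation scores in [0, 1]; NaN marks undefined columns."""

    scores: np.ndarray
    gap_fraction: np.ndarray
    msa: MSA
    column_to_residue: dict[int, tuple[str, int]] | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.scores)


def conservation_scores(msa: MSA, gap_threshold: float = 0.5) -> ConservationProfile:
    """Score every alignment column; needs at least two sequences.

    Scores are frequency-based, hence invariant under row permutation and
    duplication of existing sequences.
    """
    if msa.n_seqs < 2:
        raise ValueError("conservation scoring needs >= 2 sequences")
    ln20 = math.log(20.0)
    scores = np.empty(msa.length)
    gap_frac = np.empty(msa.length)
    for j in range(msa.length):
        col = msa.column(j)
        n_gap = col.count(GAP) + col.count("X")
        gap_frac[j] = n_gap / len(col)
        counts = np.array([col.count(aa) for aa in AA20], dtype=float)
        total = counts.sum()
        if gap_frac[j] > gap_threshold or total == 0:
            scores[j] = np.nan
            continue
        p = counts[counts > 0] / total
        entropy = float(-(p * np.log(p)).sum())
        scores[j] = 1.0 - entropy / ln20
    return ConservationProfile(scores=scores, gap_fraction=gap_frac, msa=msa)


def map_profile(
    profile: ConservationProfile,
    reference_id: str,
    model: StructureModel,
    chain: str,
) -> pd.DataFrame:
    """Map column scores onto the residues of a structure chain.

    The reference row's ungapped sequence must equal the chain's residue
    sequence (1-letter codes) exactly; the k-th non-gap column maps to the
    k-th residue of the chain, whatever its author number.  Returns a frame
    with columns ``column, chain, res_seq, res_name, score, gap_fraction``.
    """
    from .mutate import THREE_TO_ONE

    ref_row = profile.msa.row(reference_id)
    chain_residues = [(c, r, n) for (c, r, n) in model.residues() if c == chain]
    if not chain_residues:
        raise ValueError(f"chain {chain!r} not present in structure")
    chain_seq = "".join(THREE_TO_ONE.get(n, "X") for (_, _, n) in chain_residues)
    ungapped = [(j, sym) for j, sym in enumerate(ref_row) if sym != GAP]
    if len(ungapped) != len(chain_seq):
        raise ValueError(
            f"reference row {reference_id!r} has {len(ungapped)} residues but chain "
            f"{chain!r} has {len(chain_seq)}")
    for k, ((j, sym), expected) in enumerate(zip(ungapped, chain_seq)):
        if sym != expected:
            _, res_seq, res_name = chain_residues[k]
            raise ValueError(
                f"sequence/structure mismatch at ungapped position {k} "
                f"(alignment column {j}): alignment has {sym!r}, structure has "
                f"{expected!r} ({res_name} {chain}:{res_seq})")
    records = []
    mapping: dict[int, tuple[str, int]] = {}
    for k, (j, sym) in enumerate(ungapped):
        _, res_seq, res_name = chain_residues[k]
        mapping[j] = (chain, res_seq)
        records.append({
            "column": j,
            "chain": chain,
            "res_seq": res_seq,
            "res_name": res_name,
            "score": profile.scores[j],
            "gap_fraction": profile.gap_fraction[j],
        })
    profile.column_to_residue = mapping
    return pd.DataFrame.from_records(records)


def annotate_frequencies(per_residue_scores: pd.DataFrame, vtable: pd.DataFrame) -> pd.DataFrame:
    """Join population minor-allele frequencies onto per-residue scores.

    Residues without a tabulated variant get ``maf = 0``; several variants
    at one residue are summed (and logged).  Output is sorted by res_seq.
    """
    out = per_residue_scores.copy()
    if len(vtable):
        bad = vtable[(vtable["maf"] < 0) | (vtable["maf"] > 1)]
        if len(bad):
            raise ValueError(f"maf outside [0, 1] at res_seq {bad['res_seq'].tolist()}")
        dup = vtable["res_seq"].duplicated()
        if dup.any():
            logger.info("summing %d duplicate variant rows per residue", int(dup.sum()))
        maf = vtable.groupby("res_seq")["maf"].sum()
        out["maf"] = out["res_seq"].map(maf).fillna(0.0)
    else:
        out["maf"] = 0.0
    return out.sort_values("res_seq", kind="stable").reset_index(drop=True)


def interface_conservation_summary(
    per_residue_scores: pd.DataFrame,
    interface_residues: set[int],
) -> dict[str, float]:
    """Mean/median conservation inside vs outside an interface residue set.

    ``interface_residues`` holds res_seq numbers; undefined (NaN) scores are
    excluded from the statistics.
    """
    if not interface_residues:
        raise ValueError("interface residue set is empty")
    df = per_residue_scores.dropna(subset=["score"])
    inside = df[df["res_seq"].isin(interface_residues)]["score"]
    outside = df[~df["res_seq"].isin(interface_residues)]["score"]
    return {
        "mean_inside": float(inside.mean()) if len(inside) else float("nan"),
        "mean_outside": float(outside.mean()) if len(outside) else float("nan"),
        "median_inside": float(inside.median()) if len(inside) else float("nan"),
        "median_outside": float(outside.median()) if len(outside) else float("nan"),
        "mean_difference": (float(inside.mean()) - float(outside.mean())
                            if len(inside) and len(outside) else float("nan")),
        "n_inside": int(len(inside)),
        "n_outside": int(len(outside)),
    }
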