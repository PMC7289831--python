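"""End-to-end wild-type vs variant interface comparison.

:func:`analyze_pair` runs the whole battery on two trajectories — the
interdomain center-of-mass distance series with a two-sided Mann–Whitney U
test, the watched residue's rotamer-flexibility RMSD, the buried interface
area at equally distributed time points, and the cross-domain contact
inventory with a wild-type vs variant diff — and collects everything in an
:class:`InterfaceReport`, the machine-readable counterpart of a
receptor-complex destabilisation figure panel.

Defaults mirror the receptor-complex analysis this pipeline was built
around: domain A residues 198–298, domain B residues 215–317, residue of
interest 281, ten buried-area time points.

Reports serialise to a directory of TSV series plus a ``summary.json`` that
is byte-identical across runs on identical inputs (no timestamps; sorted
keys), so end-to-end determinism can be asserted with a file compare.
"""

from __future__ import annotations

import json
import logging
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import DistanceSeries, FlexibilitySeries, com_distance_series, rotamer_flexibility
from .interface import (
    BuriedAreaSeries,
    ContactDiff,
    ContactRecord,
    buried_area_series,
    contact_diff,
    detect_contacts,
)
from .stats import TestResult, mann_whitney_u
from .structio import DomainSelection, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "InterfaceReport",
    "StageError",
    "analyze_pair",
    "report_to_tables",
    "read_tables",
    "DEFAULT_DOM_A",
    "DEFAULT_DOM_B",
    "DEFAULT_RESIDUE",
]

DEFAULT_DOM_A = DomainSelection("A", 198, 298)
DEFAULT_DOM_B = DomainSelection("B", 215, 317)
DEFAULT_RESIDUE = ("A", 281)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and sampling parameters of one pipeline run."""

    probe: float = 1.4
    sasa_points: int = 960
    hbond_dist: float = 3.5
    salt_dist: float = 4.0
    n_timepoints: int = 10
    include_cb: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@contextmanager
def _stage(name: str, **params):
    start = time.perf_counter()
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError(name, exc) from exc
    logger.info("stage %s done in %.2fs (%s)", name, time.perf_counter() - start,
                ", ".join(f"{k}={v}" for k, v in params.items()))


@dataclass
class InterfaceReport:
    """All computed series, inventories and test results of one comparison."""

    distance_wt: DistanceSeries
    distance_variant: DistanceSeries
    distance_test: TestResult
    flexibility_wt: FlexibilitySeries
    flexibility_variant: FlexibilitySeries
    buried_wt: BuriedAreaSeries
    buried_variant: BuriedAreaSeries
    contacts_wt_first: list[ContactRecord]
    contacts_wt_last: list[ContactRecord]
    contacts_variant_first: list[ContactRecord]
    contacts_variant_last: list[ContactRecord]
    diff: ContactDiff
    conservation: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        """JSON-ready summary (deterministic: no timestamps, sorted on dump)."""
        def series(s):
            return {"mean": s.mean, "sd": s.sd, "n": len(s)}

        def flex(s):
            return {"mean_rmsd": s.mean_rmsd, "n": len(s)}

        def buried(s):
            return {"mean": s.mean, "timepoints": list(s.timepoints),
                    "values": [float(v) for v in s.values]}

        def contacts(records):
            return {
                "n": len(records),
                "n_saltbridge_pairs": len({tuple(sorted(r.residue_pair))
                                           for r in records if r.kind == "saltbridge"}),
                "n_hbond_pairs": len({tuple(sorted(r.residue_pair))
                                      for r in records if r.kind == "hbond"}),
            }

        return {
            "com_distance": {
                "wt": series(self.distance_wt),
                "variant": series(self.distance_variant),
                "mean_difference": self.distance_variant.mean - self.distance_wt.mean,
                "mann_whitney": {
                    "U": self.distance_test.statistic,
                    "p_value": self.distance_test.p_value,
                    "method": self.distance_test.method,
                },
            },
            "flexibility": {"wt": flex(self.flexibility_wt),
                            "variant": flex(self.flexibility_variant)},
            "buried_area": {"wt": buried(self.buried_wt),
                            "variant": buried(self.buried_variant),
                            "mean_difference": self.buried_variant.mean - self.buried_wt.mean},
            "contacts": {
                "wt_last": contacts(self.contacts_wt_last),
                "variant_last": contacts(self.contacts_variant_last),
                "lost": [_key_str(k) for k in self.diff.lost],
                "gained": [_key_str(k) for k in self.diff.gained],
                "retained": [_key_str(k) for k in self.diff.retained],
            },
            "conservation_included": self.conservation is not None,
            "provenance": self.provenance,
        }


def _key_str(key) -> str:
    kind, pair = key
    (c1, r1), (c2, r2) = pair
    return f"{kind}:{c1}{r1}-{c2}{r2}"


def analyze_pair(
    wt: Trajectory,
    variant: Trajectory,
    dom_a: DomainSelection = DEFAULT_DOM_A,
    dom_b: DomainSelection = DEFAULT_DOM_B,
    residue: tuple[str, int] = DEFAULT_RESIDUE,
    config: AnalysisConfig | None = None,
    conservation: pd.DataFrame | None = None,
    provenance: dict | None = None,
) -> InterfaceReport:
    """Compare a wild-type and a variant trajectory over one interface.

    Any stage failure propagates as :class:`StageError` naming the stage;
    no partial output is produced (writing is a separate step).
    """
    cfg = config or AnalysisConfig()
    res_sel = DomainSelection(residue[0], residue[1], residue[1])

    with _stage("com_distance", dom_a=str(dom_a), dom_b=str(dom_b)):
        dist_wt = com_distance_series(wt, dom_a, dom_b)
        dist_var = com_distance_series(variant, dom_a, dom_b)
    with _stage("distance_test", n_x=len(dist_wt), n_y=len(dist_var)):
        test = mann_whitney_u(dist_wt.values, dist_var.values)
    with _stage("rotamer_flexibility", residue=str(res_sel)):
        flex_wt = rotamer_flexibility(wt, res_sel, include_cb=cfg.include_cb)
        flex_var = rotamer_flexibility(variant, res_sel, include_cb=cfg.include_cb)
    with _stage("buried_area", n_timepoints=cfg.n_timepoints):
        buried_wt = buried_area_series(wt, dom_a, dom_b, cfg.n_timepoints,
                                       cfg.probe, cfg.sasa_points)
        buried_var = buried_area_series(variant, dom_a, dom_b, cfg.n_timepoints,
                                        cfg.probe, cfg.sasa_points)
    with _stage("contacts", hbond=cfg.hbond_dist, salt=cfg.salt_dist):
        c_wt_first = detect_contacts(wt.frames[0], dom_a, dom_b, cfg.hbond_dist, cfg.salt_dist)
        c_wt_last = detect_contacts(wt.frames[-1], dom_a, dom_b, cfg.hbond_dist, cfg.salt_dist)
        c_var_first = detect_contacts(variant.frames[0], dom_a, dom_b,
                                      cfg.hbond_dist, cfg.salt_dist)
        c_var_last = detect_contacts(variant.frames[-1], dom_a, dom_b,
                                     cfg.hbond_dist, cfg.salt_dist)
        diff = contact_diff(c_wt_last, c_var_last)

    prov = {"version": __version__, "config": cfg.to_dict(),
            "dom_a": str(dom_a), "dom_b": str(dom_b),
            "residue": f"{residue[0]}:{residue[1]}",
            "n_frames_wt": wt.n_frames, "n_frames_variant": variant.n_frames,
            "dt_wt": wt.dt, "dt_variant": variant.dt}
    if provenance:
        prov.update(provenance)
    return InterfaceReport(
        distance_wt=dist_wt, distance_variant=dist_var, distance_test=test,
        flexibility_wt=flex_wt, flexibility_variant=flex_var,
        buried_wt=buried_wt, buried_variant=buried_var,
        contacts_wt_first=c_wt_first, contacts_wt_last=c_wt_last,
        contacts_variant_first=c_var_first, contacts_variant_last=c_var_last,
        diff=diff, conservation=conservation, provenance=prov,
    )


def report_to_tables(report: InterfaceReport, outdir: str | Path) -> dict[str, Path]:
    """Write a report as TSV series + ``summary.json``; returns written paths.

    All file content is assembled in memory first, so a failure never leaves
    a partial report behind.  Output bytes are a pure function of the report.
    """
    outdir = Path(outdir)
    files: dict[str, str] = {}

    def frame_tsv(name, columns: dict[str, np.ndarray], times: np.ndarray) -> None:
        df = pd.DataFrame({"frame": np.arange(len(times)), "time_ns": times, **columns})
        files[name] = df.to_csv(sep="\t", index=False, float_format="%.6f")

    frame_tsv("distance.tsv",
              {"wt": report.distance_wt.values, "variant": report.distance_variant.values},
              report.distance_wt.times)
    frame_tsv("flexibility.tsv",
              {"wt": report.flexibility_wt.values, "variant": report.flexibility_variant.values},
              report.flexibility_wt.times)
    files["buried_area.tsv"] = pd.DataFrame({
        "timepoint_frame": report.buried_wt.timepoints,
        "wt": report.buried_wt.values,
        "variant": report.buried_variant.values,
    }).to_csv(sep="\t", index=False, float_format="%.6f")

    rows = []
    for genotype, frame_tag, records in (
        ("wt", "first", report.contacts_wt_first),
        ("wt", "last", report.contacts_wt_last),
        ("variant", "first", report.contacts_variant_first),
        ("variant", "last", report.contacts_variant_last),
    ):
        for r in records:
            rows.append({
                "genotype": genotype, "frame": frame_tag, "kind": r.kind,
                "chain_a": r.atom_a[0], "res_seq_a": r.atom_a[1],
                "res_name_a": r.atom_a[2], "atom_a": r.atom_a[3],
                "chain_b": r.atom_b[0], "res_seq_b": r.atom_b[1],
                "res_name_b": r.atom_b[2], "atom_b": r.atom_b[3],
                "distance": round(r.distance, 6),
                "angle": "" if r.angle is None else round(r.angle, 3),
            })
    files["contacts.tsv"] = pd.DataFrame(
        rows, columns=["genotype", "frame", "kind", "chain_a", "res_seq_a", "res_name_a",
                       "atom_a", "chain_b", "res_seq_b", "res_name_b", "atom_b",
                       "distance", "angle"]).to_csv(sep="\t", index=False)

    if report.conservation is not None:
        files["conservation.tsv"] = report.conservation.to_csv(sep="\t", index=False,
                                                               float_format="%.6f")
    files["summary.json"] = json.dumps(report.summary_dict(), sort_keys=True, indent=2) + "\n"

    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, content in files.items():
        path = outdir / name
        path.write_text(content)
        written[name] = path
    return written


def read_tables(outdir: str | Path) -> dict:
    """Load a written report directory back and self-check its consistency.

    Returns the parsed summary plus the series frames.  Raises ``ValueError``
    if a stored mean disagrees with recomputation from the stored series by
    more than 1e-9 (guards against hand-edited or truncated outputs).
    """
    outdir = Path(outdir)
    summary = json.loads((outdir / "summary.json").read_text())
    distance = pd.read_csv(outdir / "distance.tsv", sep="\t")
    flexibility = pd.read_csv(outdir / "flexibility.tsv", sep="\t")
    buried = pd.read_csv(outdir / "buried_area.tsv", sep="\t")
    contacts = pd.read_csv(outdir / "contacts.tsv", sep="\t")
    for col in ("wt", "variant"):
        stored = summary["com_distance"][col]["mean"]
        recomputed = float(distance[col].mean())
        # TSVs round to 1e-6; allow that plus float error on the mean
        if abs(stored - recomputed) > 1e-5:
            raise ValueError(f"summary distance mean ({col}) inconsistent with series")
        stored_b = summary["buried_area"][col]["mean"]
        if abs(stored_b - float(buried[col].mean())) > 1e-5:
            raise ValueError(f"summary buried-area mean ({col}) inconsistent with series")
    out = {"summary": summary, "distance": distance, "flexibility": flexibility,
           "buried_area": buried, "contacts": contacts}
    cons_path = outdir / "conservation.tsv"
    if cons_path.exists():
        out["conservation"] = pd.read_csv(cons_path, sep="\t")
    return out
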