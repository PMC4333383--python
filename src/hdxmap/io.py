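"""Readers, writers and pipeline configuration.

File dialects (all plain text):

* peptide table — CSV ``protein,start,end,sequence,charge`` (1-based
  inclusive coordinates);
* envelopes — long-format TSV ``peptide_id,protein,state,kind,time_s,
  replicate,charge,mz,intensity`` (one row per peak);
* annotation track — BED-like TSV ``protein,start,end,role,name`` with
  1-based inclusive coordinates;
* uptake / differential tables — CSV written by the pipeline stages.

Every table written by the pipeline carries the hash of the configuration
that produced it in a ``# config:`` comment line.
"""
from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .diffstats import DEFAULT_ALPHA, DEFAULT_DELTA_MIN, DifferentialRecord
from .envelopes import IsotopicEnvelope
from .mapping import AnnotationInterval, AnnotationTrack, InterfaceReport
from .peptides import PeptideID
from .synthetic import StudyDesign
from .uptake import UptakeRecord

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "read_peptide_table",
    "write_peptide_table",
    "read_envelope_tsv",
    "write_envelope_tsv",
    "read_annotation_track",
    "write_annotation_track",
    "write_uptake_tables",
    "write_differential_table",
    "write_woods_table",
]


class ConfigError(ValueError):
    """Invalid configuration or malformed input file."""


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, loadable from one YAML file."""

    fixture: str | None = "rigi_card2"
    outdir: str = "hdxmap_out"
    # design
    time_points: tuple[float, ...] = (10.0, 30.0, 60.0, 300.0, 900.0, 3600.0)
    replicates: int = 3
    f_D: float = 0.80
    recovery: float = 0.70
    intensity_sigma: float = 0.05
    mz_jitter_sd: float = 0.0
    seed: int | None = None
    # analysis
    alpha: float = DEFAULT_ALPHA
    delta_min: float = DEFAULT_DELTA_MIN
    baseline: str = "measured_t0"  # or "theoretical"
    n_term_skip: int = 1
    ex1_delta_bic: float = 10.0
    ex1_min_separation: float = 2.0
    ex1_min_weight: float = 0.15
    ex1_min_dprime: float = 2.0
    ex1_restarts: int = 20
    ex1_pseudo_n: float = 200.0
    rotation_per_monomer_deg: float = 74.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.delta_min < 0:
            raise ConfigError("delta_min must be >= 0")
        if self.baseline not in ("measured_t0", "theoretical"):
            raise ConfigError("baseline must be 'measured_t0' or 'theoretical'")
        if (self.intensity_sigma > 0 or self.mz_jitter_sd > 0) and self.seed is None:
            raise ConfigError("a seed is mandatory when any noise is enabled")
        self.time_points = tuple(float(t) for t in self.time_points)

    def design(self, states: tuple[str, ...] = ("apo", "bound")) -> StudyDesign:
        return StudyDesign(
            states=states,
            time_points=self.time_points,
            replicates=self.replicates,
            f_D=self.f_D,
            recovery=self.recovery,
            intensity_sigma=self.intensity_sigma,
            mz_jitter_sd=self.mz_jitter_sd,
            seed=self.seed,
        )

    def hash(self) -> str:
        """Short digest of the scientific parameters (output paths excluded),
        so identical analyses written to different directories share a hash."""
        payload = asdict(self)
        payload.pop("outdir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def raw_from_yaml(cls, path: str | Path) -> dict:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return raw

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            return cls(**cls.raw_from_yaml(path))
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["time_points"] = list(self.time_points)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _write_with_header(path: Path, frame: pd.DataFrame, config_hash: str | None, sep: str) -> None:
    with open(path, "w", newline="") as fh:
        if config_hash:
            fh.write(f"# config: {config_hash}\n")
        frame.to_csv(fh, index=False, sep=sep)


# --------------------------------------------------------------------------
# peptide tables
# --------------------------------------------------------------------------

PEPTIDE_COLUMNS = ["protein", "start", "end", "sequence", "charge"]


def read_peptide_table(path: str | Path, protein_sequences: dict[str, str] | None = None) -> list[PeptideID]:
    """Read and validate a peptide identification CSV.

    Rejects malformed rows (naming the line number), duplicate
    (protein, start, end, charge) entries, and — when the parent protein
    sequence is supplied — peptides whose sequence does not match the
    protein at their coordinates.
    """
    peptides: list[PeptideID] = []
    seen: set[tuple] = set()
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise ConfigError(f"{path}: empty peptide table")
    header = [c.strip() for c in rows[0]]
    if header != PEPTIDE_COLUMNS:
        raise ConfigError(f"{path}: expected header {PEPTIDE_COLUMNS}, got {header}")
    for lineno, row in enumerate(rows[1:], start=2):
        try:
            protein, start, end, sequence, charge = (c.strip() for c in row)
            pep = PeptideID(protein, int(start), int(end), sequence, int(charge))
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"{path}:{lineno}: {exc}") from exc
        if pep.key() in seen:
            raise ConfigError(f"{path}:{lineno}: duplicate peptide {pep.label} (z={pep.charge})")
        seen.add(pep.key())
        if protein_sequences and pep.protein in protein_sequences:
            ref = protein_sequences[pep.protein]
            if pep.end > len(ref) or ref[pep.start - 1 : pep.end] != pep.sequence:
                raise ConfigError(
                    f"{path}:{lineno}: peptide {pep.label} does not match "
                    f"protein {pep.protein} at its coordinates"
                )
        peptides.append(pep)
    return peptides


def write_peptide_table(path: str | Path, peptides: list[PeptideID], config_hash: str | None = None) -> None:
    frame = pd.DataFrame(
        [(p.protein, p.start, p.end, p.sequence, p.charge) for p in peptides],
        columns=PEPTIDE_COLUMNS,
    )
    _write_with_header(Path(path), frame, config_hash, sep=",")


# --------------------------------------------------------------------------
# envelopes
# --------------------------------------------------------------------------

ENVELOPE_COLUMNS = [
    "peptide_id", "protein", "state", "kind", "time_s", "replicate", "charge", "mz", "intensity",
]


def write_envelope_tsv(path: str | Path, envelopes: list[IsotopicEnvelope], config_hash: str | None = None) -> None:
    rows = []
    for env in envelopes:
        p = env.peptide
        for mz, inten in zip(env.mz, env.intensity):
            rows.append(
                (p.label, p.protein, env.state, env.kind, env.time_s, env.replicate,
                 p.charge, f"{mz:.5f}", f"{inten:.6e}")
            )
    frame = pd.DataFrame(rows, columns=ENVELOPE_COLUMNS)
    _write_with_header(Path(path), frame, config_hash, sep="\t")


def read_envelope_tsv(path: str | Path, peptides: list[PeptideID]) -> list[IsotopicEnvelope]:
    """Re-assemble envelope records from the long-format TSV."""
    lookup = {(p.label, p.protein, p.charge): p for p in peptides}
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ENVELOPE_COLUMNS) - set(frame.columns)
    if missing:
        raise ConfigError(f"{path}: missing envelope columns {sorted(missing)}")
    envelopes = []
    keys = ["peptide_id", "protein", "state", "kind", "time_s", "replicate", "charge"]
    for (pid, protein, state, kind, t, rep, charge), grp in frame.groupby(keys, sort=False):
        pep = lookup.get((pid, protein, int(charge)))
        if pep is None:
            raise ConfigError(f"{path}: envelope for unknown peptide {pid} ({protein})")
        envelopes.append(
            IsotopicEnvelope(pep, state, float(t), int(rep),
                             grp["mz"].to_numpy(), grp["intensity"].to_numpy(), kind=kind)
        )
    return envelopes


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------

def read_annotation_track(path: str | Path) -> AnnotationTrack:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ConfigError(f"{path}:{lineno}: expected >= 4 tab-separated fields")
            protein, start, end, role = parts[:4]
            name = parts[4] if len(parts) > 4 else ""
            try:
                intervals.append(AnnotationInterval(protein, int(start), int(end), role, name))
            except ValueError as exc:
                raise ConfigError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationTrack(intervals)


def write_annotation_track(path: str | Path, track: AnnotationTrack) -> None:
    with open(path, "w") as fh:
        fh.write("# protein\tstart\tend\trole\tname (1-based inclusive)\n")
        for iv in track.intervals:
            fh.write(f"{iv.protein}\t{iv.start}\t{iv.end}\t{iv.role}\t{iv.name}\n")


# --------------------------------------------------------------------------
# analysis tables
# --------------------------------------------------------------------------

def write_uptake_tables(
    outdir: Path,
    aggregated: list[UptakeRecord],
    replicate_rows: list[dict],
    config_hash: str | None = None,
) -> tuple[Path, Path]:
    agg = pd.DataFrame(
        [
            {
                "peptide_id": r.peptide.label,
                "protein": r.peptide.protein,
                "start": r.peptide.start,
                "end": r.peptide.end,
                "state": r.state,
                "time_s": r.time_s,
                "n_rep": r.n_rep,
                "D_abs": round(r.d_abs, 5),
                "D_percent": round(r.d_percent, 4),
                "sd": round(r.sd, 4) if r.sd is not None else "",
                "D_percent_fd": round(r.d_percent_fd, 4) if r.d_percent_fd is not None else "",
                "qc_flags": ";".join(r.qc_flags),
            }
            for r in aggregated
        ]
    )
    agg_path = outdir / "uptake.csv"
    _write_with_header(agg_path, agg, config_hash, sep=",")
    rep_path = outdir / "uptake_replicates.csv"
    _write_with_header(rep_path, pd.DataFrame(replicate_rows), config_hash, sep=",")
    return agg_path, rep_path


def write_differential_table(
    path: Path, records: list[DifferentialRecord], config_hash: str | None = None
) -> None:
    rows = []
    for rec in records:
        row = {
            "peptide_id": rec.peptide.label,
            "protein": rec.peptide.protein,
            "start": rec.peptide.start,
            "end": rec.peptide.end,
            "state_a": rec.state_a,
            "state_b": rec.state_b,
            "mean_delta_d": round(rec.mean_delta_d, 4),
            "min_p": rec.min_p if rec.min_p is not None else "",
            "class": rec.perturbation,
        }
        for t, d, p in zip(rec.times, rec.delta_d, rec.p_values):
            row[f"dD_{t:g}s"] = round(d, 4)
            row[f"p_{t:g}s"] = p if p is not None else ""
        rows.append(row)
    _write_with_header(path, pd.DataFrame(rows), config_hash, sep=",")


def write_woods_table(path: Path, records: list[DifferentialRecord], config_hash: str | None = None) -> None:
    """Woods-plot-ready export: position span, mean difference, class."""
    rows = [
        {
            "start": rec.peptide.start,
            "end": rec.peptide.end,
            "mean_delta_d": round(rec.mean_delta_d, 4),
            "class": rec.perturbation,
        }
        for rec in records
    ]
    _write_with_header(path, pd.DataFrame(rows), config_hash, sep=",")
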