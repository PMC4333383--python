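"""Sequence-level consolidation and structural mapping.

Coverage and redundancy of a peptide map, per-residue consolidation of
peptide-level uptake differences, partition of protected peptides into an
RNA-binding footprint versus a protein-protein (cooperative) interface with
front/back face assignment, the helical packing arithmetic for cooperative
filaments, and export of per-residue values into the B-factor column of a
PDB file for surface colouring.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .diffstats import DifferentialRecord
from .peptides import PeptideID

__all__ = [
    "ROLES",
    "AnnotationInterval",
    "AnnotationTrack",
    "InterfacePeptide",
    "InterfaceReport",
    "sequence_coverage",
    "consolidate_residue",
    "infer_interface",
    "helical_packing",
    "export_residue_map",
]

ROLES = frozenset(
    {
        "rna_binding_motif",
        "latch",
        "gate",
        "capping_loop",
        "front_face",
        "back_face",
        "linker",
        "other",
    }
)


@dataclass(frozen=True)
class AnnotationInterval:
    """One labelled residue interval (1-based, inclusive)."""

    protein: str
    start: int
    end: int
    role: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid annotation interval {self.start}-{self.end}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end

    def overlap_length(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start) + 1)


@dataclass
class AnnotationTrack:
    """Collection of labelled intervals for one or more proteins."""

    intervals: list[AnnotationInterval]

    def for_protein(self, protein: str) -> list[AnnotationInterval]:
        return [iv for iv in self.intervals if iv.protein == protein]

    def overlapping(self, peptide: PeptideID, role: str) -> list[AnnotationInterval]:
        return [
            iv
            for iv in self.for_protein(peptide.protein)
            if iv.role == role and iv.overlaps(peptide.start, peptide.end)
        ]

    def validate_lengths(self, lengths: dict[str, int]) -> None:
        for iv in self.intervals:
            L = lengths.get(iv.protein)
            if L is not None and iv.end > L:
                raise ValueError(
                    f"annotation {iv.name or iv.role} {iv.start}-{iv.end} beyond "
                    f"{iv.protein} length {L}"
                )


# --------------------------------------------------------------------------
# coverage and per-residue consolidation
# --------------------------------------------------------------------------

def sequence_coverage(
    peptides: list[PeptideID], protein_length: int
) -> tuple[float, np.ndarray]:
    """Covered fraction and per-residue redundancy of a peptide map.

    Redundancy counts every peptide covering a residue, so duplicated
    peptides raise redundancy but the coverage fraction is invariant under
    reordering and duplication.
    """
    redundancy = np.zeros(protein_length, dtype=int)
    for p in peptides:
        if p.end > protein_length:
            raise ValueError(f"peptide {p.label} beyond protein length {protein_length}")
        redundancy[p.start - 1 : p.end] += 1
    coverage = float((redundancy > 0).mean()) if protein_length else 0.0
    return coverage, redundancy


def consolidate_residue(
    records: list[DifferentialRecord], protein_length: int
) -> np.ndarray:
    """Per-residue mean uptake difference from overlapping peptides.

    Each residue's value is the mean of the covering peptides' mean
    uptake differences, weighted by 1/peptide-length (shorter peptides
    localise better).  Uncovered residues are NaN.
    """
    num = np.zeros(protein_length)
    den = np.zeros(protein_length)
    for rec in records:
        p = rec.peptide
        w = 1.0 / p.length
        num[p.start - 1 : p.end] += w * rec.mean_delta_d
        den[p.start - 1 : p.end] += w
    out = np.full(protein_length, np.nan)
    covered = den > 0
    out[covered] = num[covered] / den[covered]
    return out


# --------------------------------------------------------------------------
# interface inference
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InterfacePeptide:
    """One protected surface peptide attributed to the inter-molecular interface."""

    peptide: PeptideID
    face: str  # "front" | "back" | "unassigned"
    mean_delta_d: float
    dual_rna_binding: bool  # also overlaps an RNA-binding motif


@dataclass
class InterfaceReport:
    """Partition of protections into ligand footprint vs cooperative interface."""

    interface: list[InterfacePeptide]
    footprint: list[PeptideID]  # protected peptides overlapping RNA-binding motifs
    n_front: int
    n_back: int
    rotation_per_monomer_deg: float | None = None
    monomers_per_repeat: float | None = None
    monomers_per_repeat_rounded: int | None = None

    @property
    def n_interface(self) -> int:
        return len(self.interface)


def infer_interface(
    records: list[DifferentialRecord],
    annotations: AnnotationTrack,
    *,
    rotation_per_monomer_deg: float | None = None,
) -> InterfaceReport:
    """Separate protected peptides into RNA footprint and cooperative interface.

    A protected peptide sharing >= 1 residue with an ``rna_binding_motif``
    interval belongs to the ligand footprint.  A protected peptide
    overlapping a ``front_face``/``back_face`` interval belongs to the
    inter-molecular interface and is assigned to the face with the larger
    residue overlap.  Peptides overlapping both a motif and a face are
    genuinely ambiguous (partial RNA involvement); they are reported in
    BOTH lists and carry a ``dual_rna_binding`` flag rather than being
    silently dropped.
    """
    if annotations is None or not annotations.intervals:
        raise ValueError("annotation track required for interface inference")

    interface: list[InterfacePeptide] = []
    footprint: list[PeptideID] = []
    for rec in records:
        if rec.perturbation != "protected":
            continue
        p = rec.peptide
        motif_hit = bool(annotations.overlapping(p, "rna_binding_motif"))
        front = sum(
            iv.overlap_length(p.start, p.end)
            for iv in annotations.overlapping(p, "front_face")
        )
        back = sum(
            iv.overlap_length(p.start, p.end)
            for iv in annotations.overlapping(p, "back_face")
        )
        face_hit = front > 0 or back > 0

        if motif_hit:
            footprint.append(p)
        if face_hit:
            face = "front" if front >= back else "back"
            interface.append(
                InterfacePeptide(p, face, rec.mean_delta_d, dual_rna_binding=motif_hit)
            )
        elif not motif_hit:
            # protected but unannotated: neither footprint nor interface
            continue

    n_front = sum(1 for ip in interface if ip.face == "front")
    n_back = sum(1 for ip in interface if ip.face == "back")
    report = InterfaceReport(interface, footprint, n_front, n_back)
    if rotation_per_monomer_deg is not None:
        per_repeat, rounded = helical_packing(rotation_per_monomer_deg)
        report.rotation_per_monomer_deg = rotation_per_monomer_deg
        report.monomers_per_repeat = per_repeat
        report.monomers_per_repeat_rounded = rounded
    return report


def helical_packing(rotation_per_monomer_deg: float) -> tuple[float, int]:
    """Monomers per helical repeat from the rotation between neighbours.

    Neighbouring monomers of a cooperative filament that interface every
    ``r`` degrees around the duplex-RNA axis complete one repetitive unit
    after ``360 / r`` monomers.

    >>> helical_packing(90.0)
    (4.0, 4)
    """
    if not 0 < rotation_per_monomer_deg <= 360:
        raise ValueError("rotation per monomer must be in (0, 360] degrees")
    per_repeat = 360.0 / rotation_per_monomer_deg
    return per_repeat, int(round(per_repeat))


# --------------------------------------------------------------------------
# structure export
# --------------------------------------------------------------------------

def export_residue_map(
    values: dict[int, float] | np.ndarray,
    structure_path: str | Path,
    out_path: str | Path,
    *,
    chain: str = "A",
    residue_offset: int = 0,
    sentinel: float = 999.0,
) -> dict[str, int]:
    """Write per-residue values into the B-factor column of a PDB copy.

    ``values`` maps 1-based protein residue numbers to values (an array is
    interpreted as residues 1..len, NaN = missing).  Structure residue
    ``seqid`` is matched to protein residue ``seqid - residue_offset``.
    Unmapped residues receive ``sentinel``.  Returns match statistics; a
    complete numbering mismatch (zero matched residues while values were
    supplied) raises ``ValueError``.
    """
    import gemmi

    if isinstance(values, np.ndarray):
        values = {
            i + 1: float(v) for i, v in enumerate(values) if np.isfinite(v)
        }
    structure = gemmi.read_structure(str(structure_path))
    matched = 0
    unmatched = 0
    for model in structure:
        for ch in model:
            for residue in ch:
                resnum = residue.seqid.num - residue_offset
                if ch.name == chain and resnum in values:
                    b = float(values[resnum])
                    matched += 1
                else:
                    b = sentinel
                    unmatched += 1
                for atom in residue:
                    atom.b_iso = b
    if values and matched == 0:
        raise ValueError(
            f"residue numbering mismatch: 0 of {len(values)} values matched "
            f"chain {chain!r} (offset {residue_offset}); {unmatched} residues unmatched"
        )
    structure.setup_entities()
    structure.write_pdb(str(out_path))
    return {"matched": matched, "unmatched": unmatched, "n_values": len(values)}
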