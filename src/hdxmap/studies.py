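"""Bundled synthetic study fixtures.

Two ready-made ground-truth studies emulate the biology the pipeline is
designed to resolve:

* ``mda5_polyic`` — an MDA5-like 1025-residue sensor whose helicase-CTD ring
  binds long duplex RNA cooperatively.  The bound state plants protections
  for the RNA-binding motifs AND for eleven surface peptides (six on the
  front face of the ring, five on the back face) that form the
  inter-molecular interface between neighbouring monomers of the filament.
  Interface inference on this study should recover exactly those eleven.
* ``rigi_card2`` — a compact 230-residue CARD2-like domain whose latch
  peptide is released by RNA binding: deprotections plus cooperative (EX1)
  unfolding segments that produce bimodal envelopes only at late time
  points.

Protein sequences are synthetic: drawn once from typical vertebrate
amino-acid frequencies with fixed seeds, with the first residue of every
planted peptide anchored so that peptide labels read like the field's
conventions (e.g. ``F374-391``).  Planted mean uptake differences are
calibrated exactly: the bound-state exchange rate of each planted region is
root-solved so that the noiseless time-averaged percent-uptake difference
equals the stated target.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .mapping import AnnotationInterval, AnnotationTrack
from .peptides import PeptideID
from .synthetic import (
    CleavageParams,
    Ex1Segment,
    ExchangeModel,
    StudyDataset,
    StudyDesign,
    build_exchange_model,
    generate_peptide_map,
    generate_study,
)

__all__ = [
    "PlantedPeptide",
    "Fixture",
    "FIXTURES",
    "mda5_polyic_fixture",
    "rigi_card2_fixture",
    "build_fixture_study",
    "synthetic_protein_sequence",
]

# typical vertebrate proteome amino-acid frequencies (rounded)
_AA_FREQ = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037, "G": 0.066,
    "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100, "M": 0.021, "N": 0.036,
    "P": 0.063, "Q": 0.048, "R": 0.056, "S": 0.083, "T": 0.053, "V": 0.060,
    "W": 0.012, "Y": 0.028,
}


def synthetic_protein_sequence(
    length: int, seed: int, anchors: dict[int, str] | None = None
) -> str:
    """Random protein sequence with fixed anchored residues (1-based)."""
    rng = np.random.default_rng(seed)
    aas = list(_AA_FREQ)
    p = np.array(list(_AA_FREQ.values()))
    seq = list(rng.choice(aas, size=length, p=p / p.sum()))
    for pos, aa in (anchors or {}).items():
        seq[pos - 1] = aa
    return "".join(seq)


@dataclass(frozen=True)
class PlantedPeptide:
    """A peptide with a ground-truth mean uptake difference (bound - apo, %)."""

    start: int
    end: int
    target_delta: float
    charge: int = 2
    note: str = ""


@dataclass
class Fixture:
    """Declarative ground truth for one bundled synthetic study."""

    name: str
    protein: str
    sequence: str
    state_apo: str
    state_bound: str
    planted: tuple[PlantedPeptide, ...]
    annotations: AnnotationTrack
    ex1_bound: tuple[Ex1Segment, ...] = ()
    ex1_closed_protection: float = 100_000.0
    baseline_protection: float = 300.0
    background_coverage: float = 0.85
    map_seed: int = 911

    @property
    def length(self) -> int:
        return len(self.sequence)

    def planted_spans(self) -> list[tuple[int, int]]:
        spans = [(p.start, p.end) for p in self.planted]
        spans += [(s.start, s.end) for s in self.ex1_bound]
        return spans


# --------------------------------------------------------------------------
# effect-size calibration
# --------------------------------------------------------------------------

def _mean_uptake_fraction(k: float, times: tuple[float, ...]) -> float:
    """Time-averaged exchanged fraction of a uniform-rate region."""
    t = np.asarray(times)
    return float(np.mean(-np.expm1(-k * t)))


def calibrate_bound_rate(
    apo_rate: float, target_delta_percent: float, times: tuple[float, ...]
) -> float:
    """Observed rate reproducing a planted mean uptake difference exactly.

    Solves ``mean_t(1 - e^{-k t}) = mean_t(1 - e^{-k_apo t}) + target/100``
    for k.  Percent uptake under theory normalisation equals 100 x the
    exchanged fraction, so D2O content and recovery cancel and the
    calibration is exact for noiseless data.
    """
    goal = _mean_uptake_fraction(apo_rate, times) + target_delta_percent / 100.0
    if not 0.0 < goal < 1.0:
        raise ValueError(
            f"target shift {target_delta_percent}% infeasible from apo rate {apo_rate}"
        )
    return 10.0 ** brentq(
        lambda lk: _mean_uptake_fraction(10.0**lk, times) - goal, -9.0, 3.0, xtol=1e-12
    )


# --------------------------------------------------------------------------
# the MDA5-like cooperative-filament study
# --------------------------------------------------------------------------

# RNA-binding footprint protections (overlap rna_binding_motif annotations)
_MDA5_FOOTPRINT = (
    PlantedPeptide(410, 422, -20.0, note="motif Ic"),
    PlantedPeptide(441, 459, -13.0, note="motif IIa"),
    PlantedPeptide(992, 1006, -11.0, note="CTD RNA strand contact"),
)
# front-face inter-molecular interface (six peptides)
_MDA5_FRONT = (
    PlantedPeptide(374, 391, -20.0, note="HEL1 outer rim"),
    PlantedPeptide(398, 409, -7.0, note="HEL1 short helix"),
    PlantedPeptide(630, 642, -15.0, note="HEL2i helix C-terminus"),
    PlantedPeptide(745, 762, -11.0, note="HEL2 major-groove loop (dual)"),
    PlantedPeptide(763, 785, -17.0, note="HEL2 helix alpha18"),
    PlantedPeptide(940, 959, -20.0, note="CTD capping-loop analogue"),
)
# back-face inter-molecular interface (five peptides)
_MDA5_BACK = (
    PlantedPeptide(489, 512, -12.0, note="motif III / Pincer axel (dual)"),
    PlantedPeptide(560, 581, -5.0, note="HEL2i surface"),
    PlantedPeptide(850, 868, -14.0, note="Pincer turn"),
    PlantedPeptide(877, 902, -12.0, note="HEL-CTD connector"),
    PlantedPeptide(913, 938, -3.0, note="CTD RNA-proximal (dual)"),
)
# solvent-exposed loop that stays unchanged in both states
_MDA5_UNCHANGED = (PlantedPeptide(643, 674, 0.0, note="HEL2i surface loop"),)


def mda5_polyic_fixture() -> Fixture:
    """MDA5-like study: apo vs long-duplex-RNA-bound cooperative filament."""
    protein = "MDA5L"
    anchors = {
        374: "F", 398: "K", 410: "V", 441: "I", 489: "T", 560: "A", 630: "F",
        643: "N", 745: "A", 763: "V", 850: "R", 877: "Q", 913: "L", 940: "I",
        992: "K",
    }
    sequence = synthetic_protein_sequence(1025, seed=20141, anchors=anchors)
    planted = _MDA5_FOOTPRINT + _MDA5_FRONT + _MDA5_BACK + _MDA5_UNCHANGED

    motif = [
        (410, 422, "motif Ic"),
        (441, 459, "motif IIa"),
        (489, 514, "motif III / Pincer axel"),
        (745, 762, "major-groove loop"),
        (913, 938, "CTD RNA-proximal strands"),
        (992, 1006, "CTD strand contact"),
    ]
    intervals = [
        AnnotationInterval(protein, a, b, "rna_binding_motif", n) for a, b, n in motif
    ]
    intervals += [
        AnnotationInterval(protein, p.start, p.end, "front_face", p.note)
        for p in _MDA5_FRONT
    ]
    intervals += [
        AnnotationInterval(protein, p.start, p.end, "back_face", p.note)
        for p in _MDA5_BACK
    ]
    return Fixture(
        name="mda5_polyic",
        protein=protein,
        sequence=sequence,
        state_apo="apo",
        state_bound="+polyIC",
        planted=planted,
        annotations=AnnotationTrack(intervals),
        background_coverage=0.82,
        map_seed=911,
    )


# --------------------------------------------------------------------------
# the RIG-I-CARD2-like autoinhibition study
# --------------------------------------------------------------------------

def rigi_card2_fixture() -> Fixture:
    """CARD2-like study: latch release with cooperative (EX1) unfolding.

    The bound state deprotects the latch region and two neighbouring
    helices; the latch and the C-terminal helix additionally carry EX1
    segments whose opening rate makes the heavy envelope mode cross the
    detection thresholds only at the two late time points (900 s, 3600 s).
    """
    protein = "CARD2L"
    anchors = {12: "F", 103: "Y", 139: "I", 160: "L"}
    sequence = synthetic_protein_sequence(230, seed=4031, anchors=anchors)
    planted = (
        PlantedPeptide(12, 26, 6.0, note="CARD1 helix"),
        PlantedPeptide(139, 155, 11.0, note="CARD2 helix"),
    )
    ex1 = (
        Ex1Segment(103, 114, 4.0e-4),  # latch
        Ex1Segment(160, 175, 4.0e-4),  # C-terminal helix at the linker
    )
    intervals = [
        AnnotationInterval(protein, 103, 114, "latch", "CARD2 latch"),
        AnnotationInterval(protein, 160, 175, "linker", "CARD2-linker helix"),
    ]
    return Fixture(
        name="rigi_card2",
        protein=protein,
        sequence=sequence,
        state_apo="apo",
        state_bound="+3p10L",
        planted=planted,
        annotations=AnnotationTrack(intervals),
        ex1_bound=ex1,
        background_coverage=0.89,
        map_seed=912,
    )


FIXTURES = {
    "mda5_polyic": mda5_polyic_fixture,
    "rigi_card2": rigi_card2_fixture,
}


# --------------------------------------------------------------------------
# fixture -> models + peptides + study
# --------------------------------------------------------------------------

def build_fixture_models(
    fixture: Fixture, design: StudyDesign
) -> tuple[dict[str, ExchangeModel], dict]:
    """Ground-truth exchange models for both states, with calibrated rates."""
    base_p = fixture.baseline_protection
    apo_rate = 1.0 / base_p  # k_int = 1 /s throughout
    bound_intervals = []
    truth = {}
    for p in fixture.planted:
        if p.target_delta == 0.0:
            continue
        k_bound = calibrate_bound_rate(apo_rate, p.target_delta, design.time_points)
        bound_intervals.append((p.start, p.end, 1.0 / k_bound))
        truth[f"{fixture.sequence[p.start - 1]}{p.start}-{p.end}"] = {
            "target_delta_percent": p.target_delta,
            "bound_rate_per_s": k_bound,
            "note": p.note,
        }
    ex1_intervals = [
        (s.start, s.end, fixture.ex1_closed_protection) for s in fixture.ex1_bound
    ]
    apo = build_exchange_model(
        fixture.sequence,
        {"intervals": [(s, e, fixture.ex1_closed_protection) for s, e, _ in ex1_intervals]},
        fixture.state_apo,
        base_protection=base_p,
    )
    bound = build_exchange_model(
        fixture.sequence,
        {
            "intervals": bound_intervals + ex1_intervals,
            "ex1": [(s.start, s.end, s.k_op) for s in fixture.ex1_bound],
        },
        fixture.state_bound,
        base_protection=base_p,
    )
    ground_truth = {
        "fixture": fixture.name,
        "baseline_protection": base_p,
        "planted": truth,
        "ex1_segments_bound": [
            {"start": s.start, "end": s.end, "k_op_per_s": s.k_op}
            for s in fixture.ex1_bound
        ],
    }
    return {fixture.state_apo: apo, fixture.state_bound: bound}, ground_truth


def build_fixture_peptides(fixture: Fixture) -> list[PeptideID]:
    """Planted peptides plus a non-overlapping background pepsin map.

    Background peptides are generated by the stochastic digestion simulator
    and any that share residues with a planted (perturbed or EX1) region are
    dropped, so the study's differential signal is carried exactly by the
    declared peptides; everything else is unperturbed background.
    """
    rng = np.random.default_rng(fixture.map_seed)
    params = CleavageParams(target_coverage=fixture.background_coverage)
    background = generate_peptide_map(fixture.sequence, params, rng, fixture.protein)
    spans = fixture.planted_spans()
    background = [
        p
        for p in background
        if not any(p.start <= e and s <= p.end for s, e in spans)
    ]
    planted = [
        PeptideID(
            fixture.protein,
            p.start,
            p.end,
            fixture.sequence[p.start - 1 : p.end],
            p.charge,
        )
        for p in fixture.planted
    ]
    ex1_peptides = [
        PeptideID(
            fixture.protein, s.start, s.end, fixture.sequence[s.start - 1 : s.end], 2
        )
        for s in fixture.ex1_bound
    ]
    return sorted(planted + ex1_peptides + background, key=lambda p: (p.start, p.end))


def build_fixture_study(fixture: Fixture, design: StudyDesign) -> StudyDataset:
    """Simulate the full factorial study for a bundled fixture."""
    if set(design.states) != {fixture.state_apo, fixture.state_bound}:
        design = StudyDesign(
            states=(fixture.state_apo, fixture.state_bound),
            time_points=design.time_points,
            replicates=design.replicates,
            f_D=design.f_D,
            recovery=design.recovery,
            intensity_sigma=design.intensity_sigma,
            mz_jitter_sd=design.mz_jitter_sd,
            seed=design.seed,
        )
    models, truth = build_fixture_models(fixture, design)
    peptides = build_fixture_peptides(fixture)
    return generate_study(
        models, peptides, design, manifest_extra={"ground_truth": truth}
    )
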