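"""Synthetic HDX-MS study generator.

Produces complete in-silico studies — isotopic envelopes for every peptide x
state x time point x replicate, plus undeuterated (t0) and fully-deuterated
(FD) controls — from an explicit ground-truth exchange model, so that every
downstream analysis stage can be exercised and validated without any
instrument data.

The exchange model follows the two-state (Linderstrom-Lang) picture:

* EX2 residues exchange independently with observed rate ``k_int / P`` where
  ``P >= 1`` is the protection factor; the deuteration probability at time t
  in a ``f_D`` fraction D2O bath is ``f_D * (1 - exp(-(k_int/P) * t))``.
* EX1 segments are cooperative units that open with rate ``k_op``; once a
  molecule's segment has opened (probability ``1 - exp(-k_op * t)``) all of
  its amides exchange to ``f_D``.  Mixing over the open/closed populations
  is what produces the characteristic bimodal envelope.

Back-exchange during quench and chromatography is a per-deuteron Bernoulli
survival with probability ``recovery``, which for independent labels is
exactly equivalent to scaling every deuteration probability by ``recovery``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import DH_MASS_DIFF, ISOTOPE_SPACING, PROTON_MASS
from .envelopes import IsotopicEnvelope, natural_isotope_distribution
from .peptides import PeptideID, exchangeable_mask

__all__ = [
    "Ex1Segment",
    "ExchangeModel",
    "StudyDesign",
    "CleavageParams",
    "StudyDataset",
    "d2o_fraction",
    "build_exchange_model",
    "residue_exchange_prob",
    "deuteration_distribution",
    "simulate_envelope",
    "generate_peptide_map",
    "generate_study",
]


def d2o_fraction(sample_ul: float, buffer_ul: float, buffer_purity: float = 0.9999) -> float:
    """Final D2O fraction after mixing a protiated sample into D2O buffer.

    The standard labelling setup dilutes a small aqueous sample into excess
    deuterated buffer: 4 ul sample + 16 ul 99.99 % D2O gives a final D2O
    content of ~0.80.
    """
    if sample_ul < 0 or buffer_ul <= 0:
        raise ValueError("volumes must be positive")
    if not 0 < buffer_purity <= 1:
        raise ValueError("buffer purity must be in (0, 1]")
    return buffer_ul * buffer_purity / (sample_ul + buffer_ul)


# --------------------------------------------------------------------------
# ground-truth exchange model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Ex1Segment:
    """Cooperative unfolding unit: residues ``start..end`` opening at ``k_op`` /s."""

    start: int
    end: int
    k_op: float

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid EX1 segment {self.start}-{self.end}")
        if self.k_op <= 0:
            raise ValueError("EX1 opening rate k_op must be > 0")


@dataclass
class ExchangeModel:
    """Per-residue exchange behaviour of one protein state.

    ``k_int`` and ``protection`` are per-residue arrays (1-based residue i is
    element i-1).  Residues inside an EX1 segment use their protection factor
    only while the segment is closed.
    """

    sequence: str
    k_int: np.ndarray
    protection: np.ndarray
    ex1_segments: tuple[Ex1Segment, ...] = ()
    state_label: str = "apo"
    n_term_skip: int = 1

    def __post_init__(self) -> None:
        self.k_int = np.asarray(self.k_int, dtype=float)
        self.protection = np.asarray(self.protection, dtype=float)
        L = len(self.sequence)
        if self.k_int.shape != (L,) or self.protection.shape != (L,):
            raise ValueError("k_int and protection must be per-residue arrays")
        if np.any(self.k_int <= 0):
            raise ValueError("intrinsic rates must be > 0")
        if np.any(self.protection < 1):
            raise ValueError("protection factors must be >= 1")
        spans = []
        for seg in self.ex1_segments:
            if seg.end > L:
                raise ValueError(f"EX1 segment {seg.start}-{seg.end} beyond sequence")
            spans.append((seg.start, seg.end))
        for (a1, b1), (a2, b2) in zip(sorted(spans), sorted(spans)[1:]):
            if a2 <= b1:
                raise ValueError("EX1 segments must not overlap")
        self.ex1_segments = tuple(sorted(self.ex1_segments, key=lambda s: s.start))

    @property
    def length(self) -> int:
        return len(self.sequence)

    def exchangeable(self) -> np.ndarray:
        return exchangeable_mask(self.sequence, self.n_term_skip)


def build_exchange_model(
    sequence: str,
    protection_spec: dict | None = None,
    state_label: str = "apo",
    *,
    base_k_int: float = 1.0,
    base_protection: float = 100.0,
    n_term_skip: int = 1,
) -> ExchangeModel:
    """Translate a declarative protection spec into per-residue parameters.

    ``protection_spec`` maps options to values:

    ``intervals``
        list of ``(start, end, P)`` 1-based inclusive intervals assigning a
        protection factor to a region (later intervals override earlier);
    ``ex1``
        list of ``(start, end, k_op)`` cooperative segments;
    ``k_int``
        optional per-residue table ``{residue_index: rate}`` overriding the
        single base rate.

    Unspecified residues keep ``base_protection``.  Requests for P < 1 or
    intervals outside the sequence raise ``ValueError``.
    """
    spec = dict(protection_spec or {})
    L = len(sequence)
    k_int = np.full(L, float(base_k_int))
    for idx, rate in dict(spec.get("k_int", {})).items():
        if not 1 <= int(idx) <= L:
            raise ValueError(f"k_int override at residue {idx} outside sequence")
        k_int[int(idx) - 1] = float(rate)
    protection = np.full(L, float(base_protection))
    for start, end, p in spec.get("intervals", []):
        if not (1 <= start <= end <= L):
            raise ValueError(f"protection interval {start}-{end} outside 1..{L}")
        if p < 1:
            raise ValueError(f"protection factor {p} < 1 requested for {start}-{end}")
        protection[start - 1 : end] = float(p)
    segments = tuple(Ex1Segment(int(a), int(b), float(k)) for a, b, k in spec.get("ex1", []))
    for seg in segments:
        if seg.end > L:
            raise ValueError(f"EX1 segment {seg.start}-{seg.end} outside sequence")
    return ExchangeModel(
        sequence, k_int, protection, segments, state_label, n_term_skip=n_term_skip
    )


def residue_exchange_prob(model: ExchangeModel, residue: int, t: float, f_D: float) -> float:
    """EX2 deuteration probability of one residue at time t (before back-exchange).

    ``p = f_D * (1 - exp(-(k_int/P) * t))``; zero for prolines and the
    excluded N-terminal residue(s).  ``residue`` is 1-based.
    """
    if t < 0:
        raise ValueError("negative exchange time")
    if not 1 <= residue <= model.length:
        raise ValueError(f"residue {residue} outside sequence")
    if not model.exchangeable()[residue - 1]:
        return 0.0
    k_obs = model.k_int[residue - 1] / model.protection[residue - 1]
    return float(f_D * -np.expm1(-k_obs * t))


# --------------------------------------------------------------------------
# study design
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyDesign:
    """Factorial design of an HDX time-course experiment.

    Defaults mirror a standard bottom-up differential HDX protocol: six
    on-exchange times between 10 s and 1 h, 80 % final D2O, an estimated
    average deuterium recovery of 70 %, three replicates, and mild
    multiplicative intensity noise.
    """

    states: tuple[str, ...] = ("apo", "bound")
    time_points: tuple[float, ...] = (10.0, 30.0, 60.0, 300.0, 900.0, 3600.0)
    replicates: int = 3
    f_D: float = 0.80
    recovery: float = 0.70
    intensity_sigma: float = 0.05
    mz_jitter_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.f_D <= 1:
            raise ValueError("f_D must be in (0, 1]")
        if not 0 < self.recovery <= 1:
            raise ValueError("recovery must be in (0, 1]")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        tp = tuple(float(t) for t in self.time_points)
        if any(b <= a for a, b in zip(tp, tp[1:])) or any(t <= 0 for t in tp):
            raise ValueError("time points must be positive and strictly increasing")
        if self.intensity_sigma < 0 or self.mz_jitter_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def noisy(self) -> bool:
        return self.intensity_sigma > 0 or self.mz_jitter_sd > 0


# --------------------------------------------------------------------------
# envelope simulation
# --------------------------------------------------------------------------

def _poisson_binomial(probs: np.ndarray) -> np.ndarray:
    """Exact distribution of the number of successes of independent Bernoullis."""
    dist = np.array([1.0])
    for p in probs:
        dist = np.convolve(dist, [1.0 - p, p])
    return dist


def deuteration_distribution(
    model: ExchangeModel,
    peptide: PeptideID,
    t: float,
    f_D: float,
    recovery: float = 1.0,
) -> np.ndarray:
    """Exact deuteron-count distribution for one peptide at time t.

    Independent blocks are convolved: EX2 residues contribute a
    Poisson-binomial over their individual probabilities, and each EX1
    segment contributes a two-population mixture (closed: residues exchange
    as EX2 under their protection factors; open, with weight
    ``1 - exp(-k_op t)``: a Binomial at ``f_D``).  Back-exchange thins every
    probability by ``recovery``.  The returned vector has length
    ``N_exch + 1`` and sums to 1.
    """
    if t < 0:
        raise ValueError("negative exchange time")
    if not (1 <= peptide.start <= peptide.end <= model.length):
        raise ValueError(f"peptide {peptide.label} outside model sequence")
    if model.sequence[peptide.start - 1 : peptide.end] != peptide.sequence:
        raise ValueError(f"peptide {peptide.label} sequence mismatch with protein")

    # global exchangeability is evaluated on the protein, then restricted to
    # the peptide span; the peptide's own N-terminal residues additionally
    # lose their label during digestion/desalting
    mask = model.exchangeable().copy()
    pep_mask = exchangeable_mask(peptide.sequence, model.n_term_skip)
    span = slice(peptide.start - 1, peptide.end)
    mask[span] &= pep_mask

    residues = np.flatnonzero(mask[span]) + peptide.start  # 1-based, exchangeable
    in_segment = np.zeros(residues.size, dtype=bool)
    blocks: list[np.ndarray] = []
    for seg in model.ex1_segments:
        inside = (residues >= seg.start) & (residues <= seg.end)
        if not inside.any():
            continue
        in_segment |= inside
        seg_res = residues[inside]
        k_obs = model.k_int[seg_res - 1] / model.protection[seg_res - 1]
        closed_p = f_D * -np.expm1(-k_obs * t) * recovery
        closed = _poisson_binomial(closed_p)
        m = seg_res.size
        open_dist = _poisson_binomial(np.full(m, f_D * recovery))
        w_open = -np.expm1(-seg.k_op * t)
        # pad to common length before mixing
        n = max(closed.size, open_dist.size)
        mix = np.zeros(n)
        mix[: closed.size] += (1.0 - w_open) * closed
        mix[: open_dist.size] += w_open * open_dist
        blocks.append(mix)

    ex2_res = residues[~in_segment]
    k_obs = model.k_int[ex2_res - 1] / model.protection[ex2_res - 1]
    probs = f_D * -np.expm1(-k_obs * t) * recovery
    dist = _poisson_binomial(probs)
    for block in blocks:
        dist = np.convolve(dist, block)
    return dist


def fd_deuteration_distribution(
    model: ExchangeModel, peptide: PeptideID, f_D: float, recovery: float
) -> np.ndarray:
    """Fully-deuterated control: every exchangeable amide at ``f_D``, then thinned."""
    mask = model.exchangeable().copy()
    span = slice(peptide.start - 1, peptide.end)
    mask[span] &= exchangeable_mask(peptide.sequence, model.n_term_skip)
    m = int(mask[span].sum())
    return _poisson_binomial(np.full(m, f_D * recovery))


def _envelope_from_distribution(
    peptide: PeptideID,
    d_dist: np.ndarray,
    state: str,
    time_s: float,
    replicate: int,
    design: StudyDesign,
    rng: np.random.Generator | None,
    kind: str = "exchange",
    prune: float = 1e-6,
) -> IsotopicEnvelope:
    """Convolve a deuteration distribution with the natural isotope profile.

    Peaks are merged by nominal index; each merged peak keeps the
    intensity-weighted exact mass, so envelope centroids are exact.
    """
    profile = natural_isotope_distribution(peptide.sequence)
    iso = profile.probs
    n_k = iso.size + d_dist.size - 1
    intensity = np.convolve(iso, d_dist)
    mass_num = np.zeros(n_k)
    for d, pd in enumerate(d_dist):
        if pd <= 0:
            continue
        masses = profile.monoisotopic_mass + np.arange(iso.size) * ISOTOPE_SPACING + d * DH_MASS_DIFF
        mass_num[d : d + iso.size] += pd * iso * masses
    keep = intensity > prune * intensity.max()
    intensity = intensity[keep]
    position = mass_num[keep] / intensity

    if design.noisy:
        if rng is None:
            raise ValueError("rng required when simulating with noise")
        if design.intensity_sigma > 0:
            intensity = intensity * rng.lognormal(
                0.0, design.intensity_sigma, size=intensity.size
            )
        if design.mz_jitter_sd > 0:
            position = position + rng.normal(0.0, design.mz_jitter_sd, size=position.size)

    z = peptide.charge
    mz = (position + z * PROTON_MASS) / z
    return IsotopicEnvelope(peptide, state, time_s, replicate, mz, intensity, kind=kind)


def simulate_envelope(
    model: ExchangeModel,
    peptide: PeptideID,
    t: float,
    design: StudyDesign,
    rng: np.random.Generator | None = None,
    replicate: int = 1,
    kind: str = "exchange",
) -> IsotopicEnvelope:
    """Simulate one isotopic envelope (peak list) for a peptide at time t.

    At ``t = 0`` with noise disabled the result is exactly the natural
    isotope distribution of the undeuterated peptide.
    """
    if kind == "fd":
        d_dist = fd_deuteration_distribution(model, peptide, design.f_D, design.recovery)
    else:
        d_dist = deuteration_distribution(model, peptide, t, design.f_D, design.recovery)
    return _envelope_from_distribution(
        peptide, d_dist, model.state_label, t, replicate, design, rng, kind=kind
    )


# --------------------------------------------------------------------------
# in-silico pepsin map
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CleavageParams:
    """Stochastic pepsin-like digestion parameters.

    Pepsin cleaves preferentially after bulky hydrophobic and acidic
    residues; digestion is simulated as independent cut decisions per bond
    over several passes, pooling fragments of plausible length, then
    sampling peptides until the target sequence coverage is reached (MS
    detection loses some fragments, so coverage < 1).
    """

    preferred: str = "FLWYE"
    p_preferred: float = 0.4
    p_other: float = 0.02
    min_length: int = 5
    max_length: int = 25
    target_coverage: float = 0.89
    n_passes: int = 40
    redundancy_keep: float = 0.35


def _assign_charge(length: int) -> int:
    return 2 if length <= 18 else 3


def generate_peptide_map(
    sequence: str,
    params: CleavageParams | None = None,
    rng: np.random.Generator | None = None,
    protein: str = "protein",
) -> list[PeptideID]:
    """Generate an overlapping peptic peptide map with controlled coverage.

    Deterministic for a fixed ``rng`` state.  Raises ``ValueError`` when the
    sequence is shorter than the minimum peptide length or when the
    parameters yield no usable fragments.
    """
    params = params or CleavageParams()
    rng = np.random.default_rng() if rng is None else rng
    L = len(sequence)
    if L < params.min_length:
        raise ValueError(
            f"sequence length {L} shorter than minimum peptide length {params.min_length}"
        )

    cut_p = np.array(
        [params.p_preferred if aa in params.preferred else params.p_other for aa in sequence]
    )
    pool: dict[tuple[int, int], None] = {}
    for _ in range(params.n_passes):
        cuts = np.flatnonzero(rng.random(L) < cut_p) + 1  # cut AFTER these residues
        bounds = np.concatenate([[0], cuts[cuts < L], [L]])
        for a, b in zip(bounds, bounds[1:]):
            if params.min_length <= b - a <= params.max_length:
                pool.setdefault((int(a) + 1, int(b)), None)
    if not pool:
        raise ValueError("cleavage parameters produced no peptides in the allowed length range")

    order = list(pool)
    rng.shuffle(order)
    covered = np.zeros(L, dtype=bool)
    chosen: list[tuple[int, int]] = []
    for start, end in order:
        new = not covered[start - 1 : end].all()
        if new or rng.random() < params.redundancy_keep:
            chosen.append((start, end))
            covered[start - 1 : end] = True
        if covered.mean() >= params.target_coverage:
            break

    peptides = [
        PeptideID(protein, s, e, sequence[s - 1 : e], _assign_charge(e - s + 1))
        for s, e in sorted(chosen)
    ]
    if not peptides:
        raise ValueError("no peptides selected")
    return peptides


# --------------------------------------------------------------------------
# full study
# --------------------------------------------------------------------------

@dataclass
class StudyDataset:
    """A complete simulated study: envelopes plus a ground-truth manifest."""

    envelopes: list[IsotopicEnvelope]
    peptides: list[PeptideID]
    design: StudyDesign
    manifest: dict

    def exchange_envelopes(self) -> list[IsotopicEnvelope]:
        return [e for e in self.envelopes if e.kind == "exchange"]


def generate_study(
    models: dict[str, ExchangeModel],
    peptides: list[PeptideID],
    design: StudyDesign,
    *,
    manifest_extra: dict | None = None,
) -> StudyDataset:
    """Simulate every envelope of a factorial HDX study.

    Emits one exchange envelope per peptide x state x time point x
    replicate, plus per-replicate t0 (undeuterated) and fully-deuterated
    controls, and a manifest recording the ground truth needed by recovery
    tests (design, per-peptide maximum exchangeable amides, state labels).
    """
    if not models:
        raise ValueError("no exchange models supplied")
    if set(design.states) != set(models):
        raise ValueError(
            f"design states {design.states} inconsistent with models {tuple(models)}"
        )
    if design.noisy and design.seed is None:
        raise ValueError("a seed is mandatory when noise is enabled")
    rng = np.random.default_rng(design.seed)

    envelopes: list[IsotopicEnvelope] = []
    for state in design.states:
        model = models[state]
        for peptide in peptides:
            for rep in range(1, design.replicates + 1):
                envelopes.append(
                    simulate_envelope(model, peptide, 0.0, design, rng, rep, kind="t0")
                )
                envelopes.append(
                    simulate_envelope(model, peptide, 0.0, design, rng, rep, kind="fd")
                )
                for t in design.time_points:
                    envelopes.append(
                        simulate_envelope(model, peptide, t, design, rng, rep)
                    )

    from .peptides import max_exchangeable  # local import to keep module API tight

    manifest = {
        "states": list(design.states),
        "time_points_s": list(design.time_points),
        "replicates": design.replicates,
        "f_D": design.f_D,
        "recovery": design.recovery,
        "intensity_sigma": design.intensity_sigma,
        "mz_jitter_sd": design.mz_jitter_sd,
        "seed": design.seed,
        "n_peptides": len(peptides),
        "n_exchange_envelopes": len(peptides)
        * len(design.states)
        * len(design.time_points)
        * design.replicates,
        "peptides": {
            p.label: {
                "protein": p.protein,
                "start": p.start,
                "end": p.end,
                "charge": p.charge,
                "n_exch": max_exchangeable(p.sequence),
            }
            for p in peptides
        },
    }
    manifest.update(manifest_extra or {})
    return StudyDataset(envelopes, list(peptides), design, manifest)
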