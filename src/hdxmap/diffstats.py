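"""Differential HDX statistics.

State-vs-state comparison per peptide: one-way ANOVA across states on
replicate percent uptake at each time point, Tukey honest-significant-
difference pairwise p-values, the mean uptake difference across all time
points, and a three-way perturbation call (protected / deprotected /
unchanged) gated on both effect size and significance.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import f_oneway, tukey_hsd

from .peptides import PeptideID

__all__ = [
    "DifferentialRecord",
    "compare_states",
    "classify_perturbation",
    "DEFAULT_ALPHA",
    "DEFAULT_DELTA_MIN",
]

#: significance threshold; matches the single-star convention P < 0.04
DEFAULT_ALPHA = 0.04
#: minimum absolute mean uptake difference (%) to call a perturbation;
#: chosen to retain the smallest protections worth reporting (~3 %)
DEFAULT_DELTA_MIN = 3.0


@dataclass
class DifferentialRecord:
    """Per-peptide comparison of two states (B relative to A)."""

    peptide: PeptideID
    state_a: str
    state_b: str
    times: tuple[float, ...]
    delta_d: tuple[float, ...]  # per-time-point mean D%(B) - D%(A)
    p_values: tuple[float | None, ...]  # Tukey-adjusted, per time point
    anova_p: tuple[float | None, ...]
    perturbation: str = "unchanged"

    @property
    def mean_delta_d(self) -> float:
        """Unweighted mean of the per-time-point differences."""
        return float(np.mean(self.delta_d))

    @property
    def min_p(self) -> float | None:
        ps = [p for p in self.p_values if p is not None and not np.isnan(p)]
        return min(ps) if ps else None


#: numerical guard on the effect-size threshold (percent units).  Effects a
#: few 1e-4 % from the boundary are indistinguishable given floating-point
#: round-off in centroiding; the guard makes the boundary call reproducible.
BOUNDARY_TOL = 1e-3


def classify_perturbation(
    mean_delta_d: float,
    min_p: float | None,
    delta_min: float = DEFAULT_DELTA_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> str:
    """Three-way perturbation call gated on effect size AND significance.

    ``protected`` when the mean uptake difference is at most ``-delta_min``
    (inclusive, with a ~1e-3 % round-off guard) and some time point is
    significant; ``deprotected`` symmetrically for increases; otherwise
    ``unchanged``.  A large but insignificant shift stays ``unchanged``.
    """
    if min_p is None or np.isnan(min_p) or min_p >= alpha:
        return "unchanged"
    if mean_delta_d <= -delta_min + BOUNDARY_TOL:
        return "protected"
    if mean_delta_d >= delta_min - BOUNDARY_TOL:
        return "deprotected"
    return "unchanged"


def compare_states(
    peptide: PeptideID,
    replicate_uptake: dict[str, dict[float, list[float]]],
    states: tuple[str, ...] | None = None,
    *,
    delta_min: float = DEFAULT_DELTA_MIN,
    alpha: float = DEFAULT_ALPHA,
) -> list[DifferentialRecord]:
    """Compare >= 2 states of one peptide, returning one record per pair.

    ``replicate_uptake`` maps state -> time point -> per-replicate percent
    uptake.  All states must share the same time grid.  At each time point a
    one-way ANOVA is run across all states, followed by Tukey HSD pairwise
    p-values; with a single replicate in any cell the difference is still
    reported but its p-value is missing.
    """
    states = tuple(states or replicate_uptake)
    if len(states) < 2:
        raise ValueError("need at least two states to compare")
    missing = [s for s in states if s not in replicate_uptake]
    if missing:
        raise ValueError(f"no uptake data for states {missing}")

    grids = [tuple(sorted(replicate_uptake[s])) for s in states]
    if len(set(grids)) != 1:
        raise ValueError(f"states measured on different time grids: {sorted(set(grids))}")
    times = grids[0]

    # per time point: means for every state, Tukey p for every pair
    means = {s: [float(np.mean(replicate_uptake[s][t])) for t in times] for s in states}
    pair_p: dict[tuple[str, str], list[float | None]] = {
        pair: [] for pair in itertools.combinations(states, 2)
    }
    anova_p: list[float | None] = []
    for ti, t in enumerate(times):
        groups = [np.asarray(replicate_uptake[s][t], dtype=float) for s in states]
        if any(g.size < 2 for g in groups):
            anova_p.append(None)
            for pair in pair_p:
                pair_p[pair].append(None)
            continue
        # zero within-group variance (e.g. noiseless simulations) gives
        # inf/0-over-0 statistics; the NaN-aware min_p handles the fallout
        with np.errstate(divide="ignore", invalid="ignore"):
            anova_p.append(float(f_oneway(*groups).pvalue))
            res = tukey_hsd(*groups)
        for (a, b) in pair_p:
            ia, ib = states.index(a), states.index(b)
            pair_p[(a, b)].append(float(res.pvalue[ia, ib]))

    records = []
    for (a, b), ps in pair_p.items():
        delta = tuple(means[b][i] - means[a][i] for i in range(len(times)))
        rec = DifferentialRecord(
            peptide, a, b, times, delta, tuple(ps), tuple(anova_p)
        )
        rec.perturbation = classify_perturbation(
            rec.mean_delta_d, rec.min_p, delta_min, alpha
        )
        records.append(rec)
    return records


def flip(record: DifferentialRecord) -> DifferentialRecord:
    """The same comparison seen from the other direction (A and B swapped)."""
    flipped = replace(
        record,
        state_a=record.state_b,
        state_b=record.state_a,
        delta_d=tuple(-d for d in record.delta_d),
    )
    swap = {"protected": "deprotected", "deprotected": "protected"}
    flipped.perturbation = swap.get(record.perturbation, record.perturbation)
    return flipped
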