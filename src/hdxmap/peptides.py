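"""Peptide identity and backbone-amide bookkeeping.

Coordinates are 1-based and inclusive throughout the package, matching the
field's peptide naming convention (e.g. ``Y103-114`` is the peptide starting
with Tyr at residue 103 and ending at residue 114).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import STANDARD_AA

__all__ = ["PeptideID", "exchangeable_mask", "max_exchangeable"]


@dataclass(frozen=True)
class PeptideID:
    """One identified peptic peptide.

    Parameters
    ----------
    protein
        Identifier of the parent protein.
    start, end
        1-based inclusive residue coordinates on the parent protein.
    sequence
        Amino-acid sequence; its length must equal ``end - start + 1``.
    charge
        Charge state the peptide is observed at (single charge per peptide).
    """

    protein: str
    start: int
    end: int
    sequence: str
    charge: int = 2

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid peptide span {self.start}-{self.end} (1-based, inclusive)"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match span "
                f"{self.start}-{self.end}"
            )
        if self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")
        bad = set(self.sequence) - set(STANDARD_AA)
        if bad:
            raise ValueError(f"non-standard residue symbols {sorted(bad)!r}")

    @property
    def label(self) -> str:
        """Field-style peptide name, e.g. ``'Y103-114'``."""
        return f"{self.sequence[0]}{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return len(self.sequence)

    def key(self) -> tuple[str, int, int, int]:
        """Identity tuple used for duplicate detection."""
        return (self.protein, self.start, self.end, self.charge)


def exchangeable_mask(sequence: str, n_term_skip: int = 1) -> np.ndarray:
    """Boolean mask of residues carrying an exchange-competent backbone amide.

    The first ``n_term_skip`` residues are excluded (their amide deuterons
    back-exchange too fast to be retained through quench and chromatography;
    the conventional choice is 1, some pipelines use 2) and prolines are
    excluded everywhere because they have no backbone N-H.
    """
    if n_term_skip < 1:
        raise ValueError("n_term_skip must be >= 1 (the N-terminus never counts)")
    mask = np.array([aa != "P" for aa in sequence], dtype=bool)
    mask[: min(n_term_skip, len(mask))] = False
    return mask


def max_exchangeable(sequence: str, n_term_skip: int = 1) -> int:
    """Maximum number of retainable backbone-amide deuterons (N_exch).

    This is the denominator of every percent-uptake figure:
    ``L - n_term_skip - #(prolines at positions > n_term_skip)``.

    >>> max_exchangeable("YGGFL")
    4
    >>> max_exchangeable("APGF")
    2
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    return int(exchangeable_mask(sequence, n_term_skip).sum())
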