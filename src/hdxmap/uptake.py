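"""Deuterium-uptake quantification.

Turns envelope centroids into corrected absolute and percent deuterium
uptake, aggregates replicates, and fits multi-exponential uptake time
courses.  Percent uptake is normalised to 100 % D2O content and corrected
for the estimated average deuterium recovery, i.e.

    D% = 100 * (centroid_t - centroid_0) / (N_exch * m_DH * f_D * recovery)

where ``m_DH`` is the deuterium-protium mass difference.  When a
fully-deuterated control is available the empirical normalisation
``100 * (c_t - c_0) / (c_FD - c_0)`` is recorded alongside.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import DH_MASS_DIFF
from .peptides import PeptideID, max_exchangeable

__all__ = [
    "UptakeValue",
    "UptakeRecord",
    "UptakeFit",
    "max_exchangeable",
    "compute_uptake",
    "compute_uptake_fd",
    "aggregate_replicates",
    "fit_uptake_curve",
]

#: values above this many percent are flagged (noise can exceed the
#: theoretical maximum; flagged, never clipped, to avoid biasing differences)
OVERSHOOT_FLAG_PERCENT = 110.0


@dataclass(frozen=True)
class UptakeValue:
    """Uptake of a single peptide x state x time x replicate measurement."""

    d_abs: float  # Da, centroid shift vs the undeuterated baseline
    d_percent: float  # % of theoretical maximum
    qc_flags: tuple[str, ...] = ()


@dataclass
class UptakeRecord:
    """Replicate-aggregated uptake for one peptide x state x time point."""

    peptide: PeptideID
    state: str
    time_s: float
    n_rep: int
    d_abs: float
    d_percent: float
    sd: float | None  # % across replicates; None when n_rep == 1
    d_percent_fd: float | None = None
    qc_flags: tuple[str, ...] = ()


def compute_uptake(
    centroid_t: float,
    centroid_0: float,
    n_exch: int,
    f_D: float = 0.80,
    recovery: float = 0.70,
) -> UptakeValue:
    """Theory-normalised uptake from two centroid masses.

    >>> v = compute_uptake(1000 + 2.8 * 1.00628, 1000.0, 10, 0.8, 0.7)
    >>> round(v.d_percent, 6)
    50.0
    """
    if n_exch < 1:
        raise ValueError("peptide has no exchangeable amides (N_exch = 0)")
    if not 0 < f_D <= 1 or not 0 < recovery <= 1:
        raise ValueError("f_D and recovery must be in (0, 1]")
    d_abs = centroid_t - centroid_0
    d_percent = 100.0 * d_abs / (n_exch * DH_MASS_DIFF * f_D * recovery)
    flags = ("overshoot",) if d_percent > OVERSHOOT_FLAG_PERCENT else ()
    return UptakeValue(float(d_abs), float(d_percent), flags)


def compute_uptake_fd(centroid_t: float, centroid_0: float, centroid_fd: float) -> float:
    """Uptake normalised to a fully-deuterated control (empirical 100 %)."""
    if centroid_fd <= centroid_0:
        raise ValueError("FD control centroid must exceed the undeuterated centroid")
    return float(100.0 * (centroid_t - centroid_0) / (centroid_fd - centroid_0))


def aggregate_replicates(
    peptide: PeptideID,
    state: str,
    time_s: float,
    values: list[UptakeValue],
    fd_percents: list[float] | None = None,
) -> UptakeRecord:
    """Mean and sample standard deviation across replicate measurements.

    With a single replicate the spread is reported as missing (``None``),
    never as zero.
    """
    if not values:
        raise ValueError("no replicate values to aggregate")
    d_abs = float(np.mean([v.d_abs for v in values]))
    percents = np.array([v.d_percent for v in values])
    sd = float(np.std(percents, ddof=1)) if len(values) > 1 else None
    flags = tuple(sorted({f for v in values for f in v.qc_flags}))
    fd = float(np.mean(fd_percents)) if fd_percents else None
    return UptakeRecord(
        peptide, state, time_s, len(values), d_abs, float(percents.mean()), sd, fd, flags
    )


# --------------------------------------------------------------------------
# kinetic fits
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UptakeFit:
    """Sum-of-exponentials fit D%(t) = sum_i A_i (1 - exp(-k_i t))."""

    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]  # s^-1, same order as amplitudes
    aicc: float
    converged: bool

    @property
    def plateau(self) -> float:
        return float(sum(self.amplitudes))


def _multi_exp(t, *params):
    n = len(params) // 2
    a = np.asarray(params[:n])
    k = np.asarray(params[n:])
    return (a[None, :] * -np.expm1(-np.outer(t, k))).sum(axis=1)


def _aicc(n_obs: int, rss: float, n_par: int) -> float:
    if n_obs <= n_par + 1:
        return math.inf
    aic = n_obs * math.log(max(rss, 1e-12) / n_obs) + 2 * n_par
    return aic + 2 * n_par * (n_par + 1) / (n_obs - n_par - 1)


def fit_uptake_curve(
    times: np.ndarray,
    d_percent: np.ndarray,
    max_components: int = 2,
) -> UptakeFit:
    """Least-squares exponential fit of an uptake time course.

    Fits one- and (when enough points) two-component models with
    non-negative amplitudes and picks the model with the lower small-sample
    corrected information criterion (AICc).  A flat-zero series returns a
    zero-amplitude fit; non-convergence is flagged, not raised.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(d_percent, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points to fit an uptake curve")
    if np.allclose(y, 0.0, atol=1e-9):
        return UptakeFit((0.0,), (1.0 / t.max(),), -math.inf, True)

    plateau = max(float(y.max()), 1e-6)
    best: UptakeFit | None = None
    for n_comp in range(1, max_components + 1):
        n_par = 2 * n_comp
        if t.size <= n_par:
            continue
        # spread initial rates across the observed time window
        k0 = np.geomspace(1.0 / t.max(), 1.0 / t.min(), n_comp)
        p0 = np.concatenate([np.full(n_comp, plateau / n_comp), k0])
        bounds = (
            np.concatenate([np.zeros(n_comp), np.full(n_comp, 1e-8)]),
            np.concatenate([np.full(n_comp, 200.0), np.full(n_comp, 1e3)]),
        )
        try:
            popt, _ = curve_fit(_multi_exp, t, y, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(((y - _multi_exp(t, *popt)) ** 2).sum())
        fit = UptakeFit(
            tuple(float(a) for a in popt[:n_comp]),
            tuple(float(k) for k in popt[n_comp:]),
            _aicc(t.size, rss, n_par),
            True,
        )
        if best is None or fit.aicc < best.aicc:
            best = fit
    if best is None:
        return UptakeFit((), (), math.inf, False)
    return best
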