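import numpy as np
import pytest

from hdxmap import (
    DH_MASS_DIFF,
    PROTON_MASS,
    IsotopicEnvelope,
    PeptideID,
    centroid_mass,
    classify_exchange_regime,
    deconvolve_deuteration,
    deuteration_distribution,
    fit_deuteron_mixture,
    max_exchangeable,
    natural_isotope_distribution,
    simulate_envelope,
)
from hdxmap.synthetic import StudyDesign, build_exchange_model


# --------------------------------------------------------------------------
# natural isotope distribution
# --------------------------------------------------------------------------

# average-abundance isotope tables used by the naive oracle below
_ORACLE_ISOTOPES = {
    "C": [(0, 0.9893), (1, 0.0107)],
    "H": [(0, 0.999885), (1, 0.000115)],
    "N": [(0, 0.99636), (1, 0.00364)],
    "O": [(0, 0.99757), (1, 0.00038), (2, 0.00205)],
    "S": [(0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)],
}
# elemental composition of GASTC including one water (counted by hand from
# residue formulas: G C2H3NO, A C3H5NO, S C3H5NO2, T C4H7NO2, C C3H5NOS)
_GASTC_COMPOSITION = {"C": 15, "H": 27, "N": 5, "O": 8, "S": 1}


def _oracle_profile(composition: dict[str, int]) -> np.ndarray:
    """Atom-by-atom convolution, no exponentiation tricks."""
    dist = np.array([1.0])
    for element, count in composition.items():
        shifts = _ORACLE_ISOTOPES[element]
        single = np.zeros(max(s for s, _ in shifts) + 1)
        for s, a in shifts:
            single[s] = a
        single /= single.sum()
        for _ in range(count):
            dist = np.convolve(dist, single)
    return dist


def test_isotope_profile_matches_atomwise_convolution_oracle():
    profile = natural_isotope_distribution("GASTC")
    oracle = _oracle_profile(_GASTC_COMPOSITION)
    n = profile.probs.size
    assert np.abs(profile.probs - oracle[:n]).max() < 1e-6


def test_isotope_profile_normalised_and_monoisotopic_dominant():
    profile = natural_isotope_distribution("YGGFLYGGFL")
    assert profile.probs.sum() == pytest.approx(1.0, abs=1e-3)
    assert profile.probs.argmax() == 0  # short peptide: monoisotopic peak tallest
    assert np.all(profile.probs >= 0)


def test_isotope_profile_rejects_unknown_symbol():
    with pytest.raises(ValueError):
        natural_isotope_distribution("AXZ1")


# --------------------------------------------------------------------------
# centroiding
# --------------------------------------------------------------------------

def _envelope(mz, intensity, charge=1):
    pep = PeptideID("p", 1, 5, "YGGFL", charge)
    return IsotopicEnvelope(pep, "apo", 60.0, 1, np.asarray(mz), np.asarray(intensity))


def test_centroid_single_peak_removes_proton():
    env = _envelope([500.0], [1.0], charge=1)
    assert centroid_mass(env) == pytest.approx(498.99272, abs=1e-5)


def test_centroid_two_equal_peaks_is_midpoint():
    mz = [(1000.0 + PROTON_MASS), (1002.0 + PROTON_MASS)]
    env = _envelope(mz, [5.0, 5.0], charge=1)
    assert centroid_mass(env) == pytest.approx(1001.0, abs=1e-9)


def test_envelope_rejects_all_zero_intensities():
    with pytest.raises(ValueError):
        _envelope([500.0, 501.0], [0.0, 0.0])


def test_simulated_centroid_matches_model_expectation(toy_model, toy_peptide, noiseless_design):
    """Centroid shift of a simulated envelope equals mean deuteration x m(D-H)."""
    t = 300.0
    env_t = simulate_envelope(toy_model, toy_peptide, t, noiseless_design)
    env_0 = simulate_envelope(toy_model, toy_peptide, 0.0, noiseless_design)
    dist = deuteration_distribution(
        toy_model, toy_peptide, t, noiseless_design.f_D, noiseless_design.recovery
    )
    expected_shift = float((np.arange(dist.size) * dist).sum()) * DH_MASS_DIFF
    measured = centroid_mass(env_t) - centroid_mass(env_0)
    assert measured == pytest.approx(expected_shift, abs=5e-3)


# --------------------------------------------------------------------------
# deconvolution
# --------------------------------------------------------------------------

def test_deconvolve_natural_envelope_is_point_mass_at_zero(toy_model, toy_peptide, noiseless_design):
    env = simulate_envelope(toy_model, toy_peptide, 0.0, noiseless_design)
    profile = natural_isotope_distribution(toy_peptide.sequence)
    dist, residual = deconvolve_deuteration(env, profile, max_exchangeable(toy_peptide.sequence))
    assert dist[0] == pytest.approx(1.0, abs=1e-6)
    assert residual < 1e-6


def test_deconvolution_round_trip_recovers_generating_distribution(
    toy_model, toy_peptide, noiseless_design
):
    t = 300.0
    env = simulate_envelope(toy_model, toy_peptide, t, noiseless_design)
    profile = natural_isotope_distribution(toy_peptide.sequence)
    truth = deuteration_distribution(
        toy_model, toy_peptide, t, noiseless_design.f_D, noiseless_design.recovery
    )
    recovered, _ = deconvolve_deuteration(env, profile, max_exchangeable(toy_peptide.sequence))
    assert np.abs(recovered - truth).sum() < 0.02


def test_deconvolution_rejects_impossible_mass_shift():
    pep = PeptideID("p", 1, 5, "YGGFL", 1)
    profile = natural_isotope_distribution("YGGFL")
    # place the envelope 12 Da above monoisotopic: > 4 exchangeable amides
    mz = profile.monoisotopic_mass + 12.0 + PROTON_MASS
    env = IsotopicEnvelope(pep, "apo", 60.0, 1, np.array([mz]), np.array([1.0]))
    with pytest.raises(ValueError):
        deconvolve_deuteration(env, profile, n_exch=4)


# --------------------------------------------------------------------------
# mixture fitting
# --------------------------------------------------------------------------

def _binomial(n, p):
    from scipy.stats import binom

    return binom.pmf(np.arange(n + 1), n, p)


def test_mixture_weights_sum_to_one_and_means_ordered():
    dist = 0.5 * np.pad(_binomial(6, 0.3), (0, 8)) + 0.5 * np.pad(_binomial(6, 0.9), (8, 0))
    fit = fit_deuteron_mixture(dist, 2, np.random.default_rng(0))
    assert sum(fit.weights) == pytest.approx(1.0, abs=1e-9)
    assert fit.means[0] <= fit.means[1]


def test_em_loglik_non_decreasing():
    dist = 0.6 * np.pad(_binomial(8, 0.2), (0, 10)) + 0.4 * np.pad(_binomial(8, 0.8), (10, 0))
    _, trace = fit_deuteron_mixture(
        dist, 2, np.random.default_rng(1), return_trace=True
    )
    diffs = np.diff(trace)
    assert np.all(diffs > -1e-7)


def test_degenerate_distribution_yields_none():
    point = np.zeros(10)
    point[0] = 1.0
    assert fit_deuteron_mixture(point, 2, np.random.default_rng(0)) is None


# --------------------------------------------------------------------------
# regime classification
# --------------------------------------------------------------------------

def test_unimodal_series_is_ex2():
    series = {t: _binomial(15, p) for t, p in [(10, 0.1), (60, 0.3), (300, 0.5), (900, 0.7)]}
    call = classify_exchange_regime(series, rng=np.random.default_rng(2))
    assert call.regime == "EX2"
    assert call.qualifying_times == ()


def test_constructed_bimodal_series_is_ex1():
    lo = np.pad(_binomial(4, 0.3), (0, 12))
    hi = np.pad(_binomial(4, 0.3), (5, 7))  # modes ~5 Da apart, 50/50
    series = {10: lo, 900: 0.5 * lo + 0.5 * hi}
    call = classify_exchange_regime(series, rng=np.random.default_rng(2))
    assert call.regime == "EX1"
    assert 900 in call.qualifying_times


def test_degenerate_series_is_ambiguous_not_crash():
    point = np.zeros(8)
    point[0] = 1.0
    call = classify_exchange_regime({10: point, 60: point}, rng=np.random.default_rng(2))
    assert call.regime == "ambiguous"


def test_latch_like_fixture_bimodal_only_at_late_times():
    """Cooperative segment opening at 4e-4 /s: the heavy mode crosses the
    detection gates only at 900 s and 3600 s of the standard time course."""
    seq = "YADLLKNAGIEWAQSK" * 2
    model = build_exchange_model(
        seq,
        {"intervals": [(1, len(seq), 1e5)], "ex1": [(1, 14, 4.0e-4)]},
        "bound",
        base_protection=1e5,
    )
    pep = PeptideID("p", 1, 16, seq[:16], 2)
    design = StudyDesign(states=("bound",), intensity_sigma=0.0)
    series = {}
    for t in design.time_points:
        dist = deuteration_distribution(model, pep, t, design.f_D, design.recovery)
        series[t] = dist
    call = classify_exchange_regime(series, rng=np.random.default_rng(4))
    assert call.regime == "EX1"
    assert call.qualifying_times == (900.0, 3600.0)
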