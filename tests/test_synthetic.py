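import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdxmap import (
    DH_MASS_DIFF,
    CleavageParams,
    PeptideID,
    StudyDesign,
    build_exchange_model,
    centroid_mass,
    d2o_fraction,
    deuteration_distribution,
    generate_peptide_map,
    generate_study,
    max_exchangeable,
    residue_exchange_prob,
    sequence_coverage,
    simulate_envelope,
)
from hdxmap.peptides import exchangeable_mask
from hdxmap.studies import synthetic_protein_sequence
from hdxmap.synthetic import fd_deuteration_distribution


# --------------------------------------------------------------------------
# exchange model construction
# --------------------------------------------------------------------------

def test_no_protection_spec_gives_uniform_default():
    model = build_exchange_model("ACDEFGHIKL", {}, "apo", base_protection=100.0)
    assert np.all(model.protection == 100.0)
    assert np.all(model.k_int == 1.0)


def test_states_differ_only_in_marked_interval():
    seq = synthetic_protein_sequence(200, seed=7)
    apo = build_exchange_model(seq, {"intervals": [(103, 114, 5000.0)]}, "apo")
    bound = build_exchange_model(seq, {"intervals": [(103, 114, 400.0)]}, "bound")
    diff = np.flatnonzero(apo.protection != bound.protection) + 1
    assert diff.min() == 103 and diff.max() == 114
    assert np.array_equal(apo.protection[:102], bound.protection[:102])


def test_interval_beyond_sequence_rejected():
    with pytest.raises(ValueError):
        build_exchange_model("ACDEF", {"intervals": [(2, 9, 100.0)]}, "apo")


def test_protection_below_one_rejected():
    with pytest.raises(ValueError):
        build_exchange_model("ACDEF", {"intervals": [(1, 3, 0.5)]}, "apo")


# --------------------------------------------------------------------------
# per-residue exchange probability
# --------------------------------------------------------------------------

def test_exchange_prob_boundary_values(toy_model):
    assert residue_exchange_prob(toy_model, 5, 0.0, 0.8) == 0.0
    assert residue_exchange_prob(toy_model, 5, 1e12, 0.8) == pytest.approx(0.8)
    with pytest.raises(ValueError):
        residue_exchange_prob(toy_model, 5, -1.0, 0.8)


def test_exchange_prob_half_life():
    # observed rate ln2/60 /s: at t = 60 s exactly half the asymptote
    model = build_exchange_model(
        "AAAAAA", {}, "apo", base_k_int=np.log(2) / 60.0, base_protection=1.0
    )
    assert residue_exchange_prob(model, 3, 60.0, 0.8) == pytest.approx(0.4, abs=1e-12)


def test_proline_and_n_terminus_never_exchange():
    model = build_exchange_model("APGFK", {}, "apo")
    assert residue_exchange_prob(model, 1, 1e9, 0.8) == 0.0  # N-terminus
    assert residue_exchange_prob(model, 2, 1e9, 0.8) == 0.0  # proline


# --------------------------------------------------------------------------
# deuteration distribution vs exhaustive enumeration
# --------------------------------------------------------------------------

def _enumerate_distribution(probs: np.ndarray) -> np.ndarray:
    """Brute force over all 2^N exchange outcomes."""
    n = probs.size
    dist = np.zeros(n + 1)
    for outcome in itertools.product([0, 1], repeat=n):
        p = 1.0
        for o, q in zip(outcome, probs):
            p *= q if o else (1.0 - q)
        dist[sum(outcome)] += p
    return dist


def test_ex2_distribution_equals_exhaustive_enumeration(toy_sequence):
    model = build_exchange_model(
        toy_sequence, {"intervals": [(12, 18, 900.0)]}, "apo", base_protection=250.0
    )
    pep = PeptideID("toy", 10, 20, toy_sequence[9:20], 2)
    t, f_D, rec = 300.0, 0.8, 0.7
    # amides retained: protein-level mask restricted to the span, minus the
    # peptide's own fast-exchanging N-terminal residue
    mask = exchangeable_mask(toy_sequence)[9:20] & exchangeable_mask(toy_sequence[9:20])
    residues = np.flatnonzero(mask) + 10
    probs = np.array(
        [residue_exchange_prob(model, r, t, f_D) * rec for r in residues]
    )
    assert probs.size <= 10
    oracle = _enumerate_distribution(probs)
    dist = deuteration_distribution(model, pep, t, f_D, rec)
    assert np.abs(dist - oracle).sum() < 1e-9


def test_back_exchange_thinning_commutes_with_exchange(toy_model, toy_peptide):
    """Applying recovery r equals binomial thinning of the r=1 distribution."""
    from scipy.stats import binom

    t, f_D, r = 300.0, 0.8, 0.7
    full = deuteration_distribution(toy_model, toy_peptide, t, f_D, 1.0)
    thinned = np.zeros(full.size)
    for n, pn in enumerate(full):
        thinned[: n + 1] += pn * binom.pmf(np.arange(n + 1), n, r)
    direct = deuteration_distribution(toy_model, toy_peptide, t, f_D, r)
    assert np.abs(direct - thinned).sum() < 1e-12


# --------------------------------------------------------------------------
# envelope simulation
# --------------------------------------------------------------------------

def test_t0_envelope_equals_natural_isotope_distribution(
    toy_model, toy_peptide, noiseless_design
):
    from hdxmap import natural_isotope_distribution

    env = simulate_envelope(toy_model, toy_peptide, 0.0, noiseless_design)
    profile = natural_isotope_distribution(toy_peptide.sequence)
    assert env.intensity.size == profile.probs.size
    assert np.allclose(env.intensity, profile.probs)


def test_ex1_envelope_heavy_mode_weight_tracks_opened_fraction():
    seq = "YADLLKNAGIEWAQSKYADL"
    k_op = np.log(2) / 900.0  # half the molecules opened at t = 900 s
    model = build_exchange_model(
        seq,
        {"intervals": [(1, 20, 1e6)], "ex1": [(1, 12, k_op)]},
        "bound",
        base_protection=1e6,
    )
    pep = PeptideID("p", 1, 14, seq[:14], 2)
    dist = deuteration_distribution(model, pep, 900.0, 0.8, 0.7)
    # closed population stays near zero deuterons; the heavy mode carries the
    # opened fraction (here one half-life of the opening process)
    assert dist[3:].sum() == pytest.approx(0.5, abs=0.02)
    # two resolvable modes with a valley between them
    assert dist[:2].max() > dist[2:5].min() < dist[5:].max()


def test_saturation_centroid_shift(noiseless_design, toy_sequence):
    """recovery = 1, t -> inf: centroid shift = N_exch * f_D * m(D-H)."""
    design = StudyDesign(states=("apo",), intensity_sigma=0.0, recovery=1.0)
    model = build_exchange_model(toy_sequence, {}, "apo", base_protection=1.0)
    pep = PeptideID("toy", 5, 24, toy_sequence[4:24], 2)
    env_inf = simulate_envelope(model, pep, 1e9, design)
    env_0 = simulate_envelope(model, pep, 0.0, design)
    n_exch = max_exchangeable(pep.sequence)
    shift = centroid_mass(env_inf) - centroid_mass(env_0)
    assert shift == pytest.approx(n_exch * design.f_D * DH_MASS_DIFF, abs=1e-3)


def test_noise_requires_rng(toy_model, toy_peptide):
    design = StudyDesign(states=("apo",), intensity_sigma=0.05, seed=1)
    with pytest.raises(ValueError):
        simulate_envelope(toy_model, toy_peptide, 60.0, design, rng=None)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    t1=st.floats(min_value=0.0, max_value=5000.0),
    dt=st.floats(min_value=0.1, max_value=5000.0),
    p_base=st.floats(min_value=1.0, max_value=1e5),
)
def test_mean_deuteration_monotone_and_conserved(t1, dt, p_base, toy_sequence):
    """Conservation and monotonicity of the simulated deuteration distribution."""
    model = build_exchange_model(toy_sequence, {}, "apo", base_protection=p_base)
    pep = PeptideID("toy", 3, 17, toy_sequence[2:17], 2)
    d1 = deuteration_distribution(model, pep, t1, 0.8, 0.7)
    d2 = deuteration_distribution(model, pep, t1 + dt, 0.8, 0.7)
    assert d1.sum() == pytest.approx(1.0, abs=1e-9)
    assert d2.sum() == pytest.approx(1.0, abs=1e-9)
    mean1 = (np.arange(d1.size) * d1).sum()
    mean2 = (np.arange(d2.size) * d2).sum()
    assert mean2 >= mean1 - 1e-12


# --------------------------------------------------------------------------
# pepsin map generator
# --------------------------------------------------------------------------

def test_peptide_map_hits_target_coverage():
    seq = synthetic_protein_sequence(925, seed=5)
    peps = generate_peptide_map(
        seq, CleavageParams(target_coverage=0.89), np.random.default_rng(3)
    )
    coverage, _ = sequence_coverage(peps, 925)
    assert abs(coverage - 0.89) <= 0.03
    assert all(5 <= p.length <= 25 for p in peps)


def test_peptide_map_deterministic_under_seed():
    seq = synthetic_protein_sequence(300, seed=9)
    a = generate_peptide_map(seq, None, np.random.default_rng(42))
    b = generate_peptide_map(seq, None, np.random.default_rng(42))
    assert a == b


def test_peptide_map_rejects_short_sequence():
    with pytest.raises(ValueError):
        generate_peptide_map("ACD", None, np.random.default_rng(0))


# --------------------------------------------------------------------------
# full study generation
# --------------------------------------------------------------------------

def test_study_envelope_counting():
    seq = synthetic_protein_sequence(600, seed=11)
    models = {
        s: build_exchange_model(seq, {}, s, base_protection=300.0)
        for s in ("apo", "bound")
    }
    peps = [
        PeptideID("p", i * 12 + 1, i * 12 + 10, seq[i * 12 : i * 12 + 10], 2)
        for i in range(50)
    ]
    design = StudyDesign(states=("apo", "bound"), intensity_sigma=0.0)
    study = generate_study(models, peps, design)
    exchange = study.exchange_envelopes()
    assert len(exchange) == 2 * 6 * 3 * 50  # 1800
    controls = [e for e in study.envelopes if e.kind != "exchange"]
    assert len(controls) == 2 * 3 * 50 * 2  # t0 + FD per state x replicate x peptide
    assert study.manifest["n_exchange_envelopes"] == 1800


def test_study_rejects_inconsistent_states():
    seq = synthetic_protein_sequence(60, seed=2)
    models = {"apo": build_exchange_model(seq, {}, "apo")}
    peps = [PeptideID("p", 1, 10, seq[:10], 2)]
    design = StudyDesign(states=("apo", "bound"), intensity_sigma=0.0)
    with pytest.raises(ValueError):
        generate_study(models, peps, design)


def test_zero_replicates_rejected():
    with pytest.raises(ValueError):
        StudyDesign(replicates=0)


def test_noise_without_seed_rejected():
    seq = synthetic_protein_sequence(60, seed=2)
    models = {"apo": build_exchange_model(seq, {}, "apo")}
    peps = [PeptideID("p", 1, 10, seq[:10], 2)]
    design = StudyDesign(states=("apo",), intensity_sigma=0.05, seed=None)
    with pytest.raises(ValueError):
        generate_study(models, peps, design)


def test_d2o_mixing_arithmetic():
    assert d2o_fraction(4, 16, buffer_purity=1.0) == pytest.approx(0.80)
    with pytest.raises(ValueError):
        d2o_fraction(4, 0)
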