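"""Shared fixtures: small exchange models and cached synthetic studies."""
from __future__ import annotations

import numpy as np
import pytest

from hdxmap import (
    PeptideID,
    StudyDesign,
    build_exchange_model,
)
from hdxmap.io import PipelineConfig
from hdxmap.studies import build_fixture_study, rigi_card2_fixture, synthetic_protein_sequence


@pytest.fixture(scope="session")
def toy_sequence() -> str:
    return synthetic_protein_sequence(60, seed=101)


@pytest.fixture()
def toy_model(toy_sequence):
    return build_exchange_model(
        toy_sequence, {"intervals": [(10, 25, 800.0)]}, "apo", base_protection=300.0
    )


@pytest.fixture()
def toy_peptide(toy_sequence):
    return PeptideID("toy", 8, 22, toy_sequence[7:22], 2)


@pytest.fixture()
def noiseless_design():
    return StudyDesign(states=("apo",), intensity_sigma=0.0)


@pytest.fixture(scope="session")
def rigi_study():
    """The bundled CARD2-like study, simulated once per session (seed 3)."""
    fixture = rigi_card2_fixture()
    config = PipelineConfig(fixture="rigi_card2", seed=3)
    states = (fixture.state_apo, fixture.state_bound)
    study = build_fixture_study(fixture, config.design(states))
    return fixture, config, study
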