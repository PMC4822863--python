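"""Shared fixtures.

The heavy session fixtures train desk-scale models once and share them
across tests: a tone-trained 29-category model for vector-strength and
ISIH structure, and a vowel-trained model (finer learning-rate scaling,
which vowel timbre needs for synaptic structure to emerge from the
spontaneous background) for the pitch-ranking experiment.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pitchstdp import pipeline, plasticity, stimuli

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from pitchstdp.periphery import build_cochlear_map, spatiotemporal_map


@pytest.fixture(scope="session")
def cmap():
    return build_cochlear_map()


@pytest.fixture(scope="session")
def ladder():
    return list(stimuli.semitone_ladder())


@pytest.fixture(scope="session")
def tone110():
    return stimuli.synth_pure_tone(110.0)


@pytest.fixture(scope="session")
def stm_tone110(tone110, cmap):
    return spatiotemporal_map(tone110, cmap)


@pytest.fixture(scope="session")
def trained_110():
    """Single pitch neuron trained on its own 110 Hz tone (eta x100, T/100)."""
    sched = plasticity.single_type_schedule("tone", [110.0], n_presentations=100, seed=2024)
    return plasticity.train(sched, eta_scale=100.0)


@pytest.fixture(scope="session")
def tone_model29(ladder):
    """All 29 pitch neurons trained on pure tones (eta x100, T/100)."""
    sched = plasticity.single_type_schedule("tone", ladder, n_presentations=100, seed=77)
    return plasticity.train(sched, eta_scale=100.0)


@pytest.fixture(scope="session")
def vowel_model29(ladder):
    """All 29 pitch neurons trained on /a/ and /i/ vowels (eta x10, T/10)."""
    sched = plasticity.single_type_schedule("vowel", ladder, n_presentations=1000, seed=21)
    return plasticity.train(sched, eta_scale=10.0)


@pytest.fixture(scope="session")
def vowel_isih_pools(vowel_model29, ladder):
    original = pipeline.isih_pool(vowel_model29.model, ladder, filtered=False, n_reps=10, seed=33)
    filtered = pipeline.isih_pool(vowel_model29.model, ladder, filtered=True, n_reps=10, seed=33)
    return original, filtered


@pytest.fixture(scope="session")
def untrained_model29(ladder, cmap):
    return plasticity.TrainedModel.untrained(ladder, cmap)
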