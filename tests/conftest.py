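"""Shared fixtures: calibrated synthetic HMMs and generator defaults.

HMM calibration is Monte-Carlo and moderately expensive, so the calibrated
models are session-scoped.
"""

from __future__ import annotations

import pytest

from its1kit.annotate import AnnotationConfig
from its1kit.helixwise import MotifModel
from its1kit.phmm import build_phmm, calibrate_evalue
from its1kit.simulate import default_training_alignments


@pytest.fixture(scope="session")
def training_alignments():
    return default_training_alignments()


@pytest.fixture(scope="session")
def flank_hmms(training_alignments):
    h18 = build_phmm(training_alignments["flank18S"], name="hmm18S")
    calibrate_evalue(h18, decoy_count=300, decoy_length=100, seed=21)
    h58 = build_phmm(training_alignments["flank58S"], name="hmm58S")
    calibrate_evalue(h58, decoy_count=300, decoy_length=100, seed=22)
    return h18, h58


@pytest.fixture(scope="session")
def motif_models(training_alignments):
    models = []
    for i, name in enumerate(("motifI", "motifII")):
        hmm = build_phmm(training_alignments[name], name=name)
        calibrate_evalue(hmm, decoy_count=300, decoy_length=120, seed=11 + i)
        models.append(MotifModel(name, hmm))
    return models


@pytest.fixture(scope="session")
def annotation_config():
    return AnnotationConfig()
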