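"""Shared fixtures: montages, template maps, and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from microstates import (SynthConfig, generate_study, get_montage,
                         make_template_maps)


@pytest.fixture(scope="session")
def montage30():
    return get_montage(30)


@pytest.fixture(scope="session")
def montage8():
    return get_montage(8)


@pytest.fixture(scope="session")
def templates30(montage30):
    return make_template_maps(montage30, seed=1)


@pytest.fixture(scope="session")
def small_study():
    """A desk-scale study (4 subjects × 2 sessions, 8 channels, 20 s)."""
    cfg = SynthConfig(n_subjects=4, n_sessions=2, n_channels=8,
                      record_length_s=20.0, seed=7)
    return generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
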