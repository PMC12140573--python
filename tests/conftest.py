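"""Shared fixtures: small synthetic datasets reused across test modules.

Heavy artifacts (raw-signal bundles, large tables) are session-scoped so
each is generated once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from oscportraits.elements import CATEGORIES, ElementIndex
from oscportraits.synth import SynthConfig, generate_portraits, generate_signals


@pytest.fixture(scope="session")
def small_table():
    """3 subjects x 2 categories x 40 trials, default generator settings."""
    cfg = SynthConfig(
        n_subjects=3, trials_per_category={"NR-Hit": 40, "NR-Miss": 40}, seed=42
    )
    table, truth = generate_portraits(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def dissociation_table():
    """Two Hit categories differing in manifold orientation and a small,
    spread-out mean offset: element marginals overlap heavily while the
    full portrait separates."""
    cfg = SynthConfig(
        n_subjects=6,
        trials_per_category={"NR-Hit": 150, "RS-Hit": 150},
        seed=11,
    )
    table, _ = generate_portraits(cfg)
    return cfg, table


@pytest.fixture(scope="session")
def coupling_signals():
    """Raw signals with one injected cross-epoch anticoupling.

    A single latent loads IC1 Pre-alpha positively and IC1 During-alpha
    negatively; everything else is noise.  Used by the surrogate tests:
    IAAFT must destroy this epoch-differential coordination.
    """
    B = np.zeros((48, 1))
    i_pre = ElementIndex("IC1", "Pre", "alpha").column
    i_dur = ElementIndex("IC1", "During", "alpha").column
    B[i_pre, 0] = 0.9
    B[i_dur, 0] = -0.9
    zeros = {c: np.zeros(48) for c in CATEGORIES}
    cfg = SynthConfig(
        n_subjects=2,
        trials_per_category={"NR-Hit": 60},
        n_latent=1,
        backbone=B,
        category_perturbation=0.0,
        subject_intercept_sd=0.0,
        error_loadings=zeros,
        duration_readout=np.zeros(48),
        couple_labels=False,
        seed=5,
    )
    signals = generate_signals(cfg)
    return cfg, signals, (i_pre, i_dur)


@pytest.fixture(scope="session")
def extraction_signals():
    """200 trials of default-structure signals for extraction fidelity."""
    cfg = SynthConfig(
        n_subjects=2, trials_per_category={"NR-Hit": 50, "NR-Miss": 50}, seed=3
    )
    return cfg, generate_signals(cfg)
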