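"""Shared fixtures: generated subjects and a trained CAE-FC model.

Expensive fixtures are session-scoped; everything is generated
programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from hdlatent.caefc import train_caefc
from hdlatent.containers import SubjectProfile, TissuePatternSpec
from hdlatent.deformation import build_two_channel
from hdlatent.roi import sample_random_rois
from hdlatent.synthetic import DEFAULT_PATTERNS, generate_subject

PATTERN_NAMES = list(DEFAULT_PATTERNS)


@pytest.fixture(scope="session")
def mixed_subject():
    """One subject with all four default patterns (50/20/20/10)."""
    profile = SubjectProfile(
        "mix0", "A",
        {"normal": 0.5, "hyperlucent": 0.2, "low_j": 0.2, "hypoinflated": 0.1},
    )
    return profile, generate_subject(profile, seed=7)


@pytest.fixture(scope="session")
def four_class_patches():
    """200 labeled patches, 50 per pattern, each cut from a
    single-pattern subject so the texture classes are separable."""
    patches, labels = [], []
    for k, name in enumerate(PATTERN_NAMES):
        profile = SubjectProfile(f"P{k}", "A", {name: 1.0})
        scan = generate_subject(profile, seed=10 + k)
        vol = build_two_channel(scan)
        ps = sample_random_rois(vol, 50, seed=20 + k, label_grid=scan.pattern_label)
        patches += ps
        labels += [k] * len(ps)
    return patches, np.asarray(labels)


@pytest.fixture(scope="session")
def trained_model(four_class_patches):
    patches, _ = four_class_patches
    return train_caefc(patches, 4, epochs=20, seed=0)


@pytest.fixture(scope="session")
def uniform_lung_volume():
    """All-lung two-channel phantom for sampler geometry tests."""
    from hdlatent.containers import TwoChannelVolume

    shape = (40, 40, 40)
    return TwoChannelVolume(
        density=np.full(shape, 0.1),
        jacobian=np.ones(shape),
        lung_mask=np.ones(shape, dtype=bool),
        spacing=(1.0, 1.0, 1.0),
        subject_id="phantom",
    )


@pytest.fixture(scope="session")
def contraction_patterns():
    """Single pattern with uniform global contraction J = 0.216."""
    return {
        "uniform": TissuePatternSpec("uniform", mean_hu=-870.0, sd_hu=20.0,
                                     mean_j=0.216, sd_j=0.0)
    }
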