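"""Shared fixtures.

Heavy artefacts (a trained classifier, one fully analyzed synthetic core)
are session-scoped: the suite exercises them from many angles but builds
them once.
"""
from __future__ import annotations

import numpy as np
import pytest

from ishquant.classification import train_classifier
from ishquant.detection import detect_signals
from ishquant.raster import compute_tissue_mask
from ishquant.synthetic import (
    generate_point_set,
    generate_training_set,
    render_core,
    spec_for_prototype,
)


@pytest.fixture(scope="session")
def training_set():
    return generate_training_set(crops_per_class=80, seed=0)


@pytest.fixture(scope="session")
def classifier(training_set):
    return train_classifier(training_set, seed=0)


@pytest.fixture(scope="session")
def core_run(classifier):
    """One NON_DELETION core pushed through detect + classify."""
    from ishquant.classification import classify_signals

    spec = spec_for_prototype("NON_DELETION", seed=1)
    truth = generate_point_set(spec)
    image = render_core(truth)
    mask = compute_tissue_mask(image)
    detected = detect_signals(image, mask)
    labeled = classify_signals(classifier, image, detected)
    return {
        "spec": spec,
        "truth": truth,
        "image": image,
        "mask": mask,
        "detected": detected,
        "labeled": labeled,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
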