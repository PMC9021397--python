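import dataclasses

import numpy as np
import pytest

from nmrfp import synthetic as syn


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (106 patients, 26 deceased-like)."""
    return syn.generate_cohort(syn.SimConfig(seed=42))


@pytest.fixture(scope="session")
def strong_peaks():
    """Peak library with all class effects pushed to ratio 2 (or 1/2)."""
    def push(e):
        if e < 1:
            return 0.5
        if e > 1:
            return 2.0
        return 1.0
    return tuple(dataclasses.replace(p, class_effect=push(p.class_effect))
                 for p in syn.DEFAULT_PEAKS)


@pytest.fixture(scope="session")
def separable_blobs():
    """Two well-separated Gaussian clusters in 12-D with +-1 labels."""
    rng = np.random.default_rng(7)
    n_per = 30
    X = np.vstack([rng.normal(0.0, 1.0, size=(n_per, 12)),
                   rng.normal(6.0, 1.0, size=(n_per, 12))])
    y = np.array([-1.0] * n_per + [1.0] * n_per)
    return X, y
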