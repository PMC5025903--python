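import numpy as np
import pytest

import synergait as sg

# factorization settings used throughout the suite: strong enough for the
# 8 x 2000 synthetic envelope matrices, small enough to keep the suite fast
FAST_NMF = {"n_restarts": 5, "max_iter": 300, "tol": 1e-5}


@pytest.fixture(scope="session")
def template():
    return sg.make_canonical_template()


@pytest.fixture(scope="session")
def cohort(template):
    """13-subject healthy cohort at the default study conditions."""
    return sg.make_healthy_cohort(template, config=sg.SynthConfig(seed=42))


@pytest.fixture(scope="session")
def built(template, cohort):
    """Group template + normative thresholds built from the cohort."""
    tmpl, thresholds, subject_sets = sg.run_template_build(
        cohort, dict(FAST_NMF), seed=1
    )
    return tmpl, thresholds, subject_sets


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
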