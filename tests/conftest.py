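import numpy as np
import pytest

import ethoseq as eq


@pytest.fixture(scope="session")
def demo_model_3():
    """Well-separated 3-state AR(1) model in 3 dimensions."""
    return eq.build_demo_model(K=3, P=3)


@pytest.fixture(scope="session")
def demo_model_5():
    """The 5-state, 5-dimensional base model used for recovery studies."""
    return eq.build_demo_model(K=5, P=5)


@pytest.fixture(scope="session")
def short_session(demo_model_3):
    """One 2-minute session with acquisition gaps, plus its ground truth."""
    return eq.simulate_arhmm_session(
        demo_model_3, minutes=2, fps=30, gap_spec=eq.GapSpec(), seed=7
    )


@pytest.fixture(scope="session")
def fitted_3state(demo_model_3, short_session):
    """A single EM fit on the short session (shared across tests)."""
    sess, _gt = short_session
    pca = eq.fit_pca([sess], n_components=3)
    scores = pca.transform(sess.features)
    fit = eq.fit_arhmm([scores], [sess.valid_mask], K=3, L=1, seed=0, max_iter=100)
    return sess, scores, fit
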