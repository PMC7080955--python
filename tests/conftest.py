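import numpy as np
import pytest
from hypothesis import settings

import matplotlib

matplotlib.use("Agg")

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from flowtoj import (
    StudyConfig,
    fit_lmm,
    generate_study,
    prepare_model_table,
    score_table,
    screen_estimates,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study with staircase trials (8 participants)."""
    cfg = StudyConfig(seed=77, n_participants=8, dropout_rate=0.0)
    return generate_study(cfg)


@pytest.fixture(scope="session")
def default_study_estimates():
    """Default-sized study, estimate-level outputs (no trial simulation)."""
    study = generate_study(StudyConfig(seed=202), simulate_trials=False)
    est = study.true_estimates()
    scores = score_table(study.questionnaire)
    return study, est, scores


def grid_logistic_mle(soa, y):
    """Independent brute-force maximizer of the Bernoulli logistic likelihood.

    Coarse exhaustive lattice followed by a fine lattice around the coarse
    argmax; resolution 1e-4 (intercept) x 1e-6 (slope).
    """
    soa = np.asarray(soa, float)
    y = np.asarray(y, float)

    def best(b0s, b1s):
        eta = b0s[:, None, None] + b1s[None, :, None] * soa[None, None, :]
        ll = (y * eta - np.logaddexp(0, eta)).sum(axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        return b0s[i], b1s[j]

    b0, b1 = best(np.arange(-2.0, 2.0, 1e-2), np.arange(1e-4, 0.1, 2.5e-4))
    return best(np.arange(b0 - 2e-2, b0 + 2e-2, 1e-4),
                np.arange(max(b1 - 5e-4, 1e-6), b1 + 5e-4, 1e-6))


def model_tables(study, estimates, scores):
    jnd = prepare_model_table(estimates, scores, "JND", study.latent)
    pss = prepare_model_table(estimates, scores, "PSS_distance", study.latent)
    return jnd, pss


@pytest.fixture(scope="session")
def null_simulation():
    """Interaction estimates and p-values under the generator null.

    gamma_jnd = 0 with 500 replicate studies at the default design; used both
    for type-I-error calibration and for p-value uniformity.
    """
    estimates, pvalues = [], []
    for r in range(500):
        cfg = StudyConfig(seed=60_000 + r, gamma_jnd=0.0, gamma_pss=0.0)
        study = generate_study(cfg, simulate_trials=False)
        est = study.true_estimates()
        scores = score_table(study.questionnaire)
        screened, _ = screen_estimates(est)
        jnd_tab = prepare_model_table(screened, scores, "JND", study.latent)
        res = fit_lmm(jnd_tab, kind="jnd")
        estimates.append(res.params["prepost:flow_c"])
        pvalues.append(res.pvalues["prepost:flow_c"])
    return np.asarray(estimates), np.asarray(pvalues)
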