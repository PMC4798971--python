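"""Likelihood construction and the two fitting stages (fast checks).

The full stochastic parameter-recovery experiments live in the acceptance
suite; here the likelihoods are validated algebraically and against
noise-free expected counts, where recovery must be essentially exact.
"""

import numpy as np
import pytest

from racemind import (BehavioralCounts, ConfidenceCriterion, FitConfig,
                      FitResult, RaceParams, RevisionParams,
                      counts_from_trials, fit_revision, nll_initial,
                      nll_revision, predict_initial)
from racemind.fitting import _RevisionPredictor

COARSE = dict(dt=0.01, n_loser=61)
UNSIGNED = np.array([0.0, 0.032, 0.064, 0.128, 0.256, 0.512])


@pytest.fixture(scope="module")
def s1_counts(s1_session):
    return counts_from_trials(s1_session)


@pytest.fixture(scope="module")
def carried_truth(s1_params, s1_crit):
    return FitResult(params={"kappa": s1_params.kappa,
                             "bound": s1_params.bound,
                             "tnd_mean": s1_params.tnd_mean,
                             "theta": s1_crit.theta},
                     nll=0.0, starts=[],
                     fixed={"corr": s1_params.corr, "tnd_sd": 0.06},
                     success=True)


def test_counts_tabulation(s1_session, s1_counts):
    assert s1_counts.counts4.sum() == len(s1_session)
    assert np.array_equal(s1_counts.counts16.sum(axis=2), s1_counts.counts4)
    assert np.all(s1_counts.sem_rt > 0)


def test_counts_validation():
    with pytest.raises(ValueError):
        BehavioralCounts(np.array([0.1]), np.array([[1, -1, 0, 0]]),
                         np.array([0.5]), np.array([0.01]))
    with pytest.raises(ValueError, match="s.e.m."):
        BehavioralCounts(np.array([0.1]), np.array([[1, 1, 0, 0]]),
                         np.array([0.5]), np.array([0.0]))


def test_doubling_counts_doubles_multinomial_part(s1_params, s1_crit,
                                                  s1_counts):
    cfg = FitConfig(**COARSE)
    nll1 = nll_initial(s1_params, s1_crit, s1_counts, cfg)
    doubled = BehavioralCounts(s1_counts.coherences, 2 * s1_counts.counts4,
                               s1_counts.mean_rt, s1_counts.sem_rt)
    nll2 = nll_initial(s1_params, s1_crit, doubled, cfg)
    _, mean_rt = predict_initial(s1_params, s1_crit, s1_counts.coherences,
                                 cfg)
    rt_part = 0.5 * np.sum(((s1_counts.mean_rt - mean_rt)
                            / s1_counts.sem_rt) ** 2)
    assert nll2 - nll1 == pytest.approx(nll1 - rt_part, rel=1e-9)


def test_nll_minimized_at_generating_point_on_expected_data(s1_params,
                                                            s1_crit):
    """Noise-free data at the model's own proportions: the generating
    parameters beat local perturbations of every parameter."""
    cfg = FitConfig(**COARSE)
    probs, mean_rt = predict_initial(s1_params, s1_crit, UNSIGNED, cfg)
    n = 1500
    data = BehavioralCounts(UNSIGNED, probs * n, mean_rt,
                            np.full(len(UNSIGNED), 0.005))
    base = nll_initial(s1_params, s1_crit, data, cfg)
    for name, delta in [("kappa", 0.7), ("bound", 0.04),
                        ("tnd_mean", 0.02), ("theta", 0.06)]:
        for sign in (-1, 1):
            kw = dict(kappa=s1_params.kappa, bound=s1_params.bound,
                      tnd_mean=s1_params.tnd_mean)
            theta = s1_crit.theta
            if name == "theta":
                theta += sign * delta
            else:
                kw[name] += sign * delta
            p = RaceParams(corr=s1_params.corr, tnd_sd=0.06, **kw)
            assert nll_initial(p, ConfidenceCriterion(theta), data, cfg) > base


def test_theta_profile_increases_on_session_data(s1_params, s1_crit,
                                                 s1_counts):
    cfg = FitConfig(**COARSE)
    base = nll_initial(s1_params, s1_crit, s1_counts, cfg)
    for theta in (0.7, 1.1):
        assert nll_initial(s1_params, ConfidenceCriterion(theta), s1_counts,
                           cfg) > base


def test_rt_shift_moves_only_nondecision_time(s1_params, s1_crit, s1_counts):
    """Shifting all observed mean RTs by +100 ms is explained by mu_tnd
    alone: the shifted-tnd model attains the unshifted model's likelihood."""
    cfg = FitConfig(**COARSE)
    shifted = BehavioralCounts(s1_counts.coherences, s1_counts.counts4,
                               s1_counts.mean_rt + 0.1, s1_counts.sem_rt)
    p_shift = RaceParams(kappa=s1_params.kappa, bound=s1_params.bound,
                         corr=s1_params.corr,
                         tnd_mean=s1_params.tnd_mean + 0.1, tnd_sd=0.06)
    nll_ref = nll_initial(s1_params, s1_crit, s1_counts, cfg)
    nll_shift = nll_initial(p_shift, s1_crit, shifted, cfg)
    assert nll_shift == pytest.approx(nll_ref, abs=1e-6)


def test_revision_guards(s1_counts, carried_truth):
    cfg = FitConfig(**COARSE)
    assert np.isinf(nll_revision(RevisionParams(t_pip=0.9), carried_truth,
                                 s1_counts, cfg))  # above mu_tnd
    assert np.isinf(nll_revision(RevisionParams(t_pip=0.2, d1=3.0),
                                 carried_truth, s1_counts, cfg))  # bad zones
    no16 = BehavioralCounts(s1_counts.coherences, s1_counts.counts4,
                            s1_counts.mean_rt, s1_counts.sem_rt)
    with pytest.raises(ValueError, match="counts16"):
        nll_revision(RevisionParams(0.2), carried_truth, no16, cfg)


def test_revision_recovery_exact_on_expected_counts(s1_params, s1_crit,
                                                    carried_truth):
    """Stage 2 on noise-free expected counts recovers the generating
    post-initiation parameters to optimizer precision, and never touches
    the carried stage-1 estimates."""
    cfg = FitConfig(n_starts=2, seed=7, maxfev=500, **COARSE)
    predictor = _RevisionPredictor(s1_params, s1_crit, UNSIGNED, cfg)
    truth = RevisionParams(t_pip=0.3, d1=0.2, d2=0.1, d3=-0.2)
    p16 = predictor.probs16(truth)
    counts16 = p16 * 1536.0
    data = BehavioralCounts(UNSIGNED, counts16.sum(axis=2),
                            np.full(6, 0.8), np.full(6, 0.01), counts16)
    res = fit_revision(data, carried_truth, cfg)
    assert res.params["t_pip"] == pytest.approx(0.3, abs=0.005)
    assert res.params["d1"] == pytest.approx(0.2, abs=0.02)
    assert res.params["d2"] == pytest.approx(0.1, abs=0.02)
    assert res.params["d3"] == pytest.approx(-0.2, abs=0.03)
    for k in ("kappa", "bound", "tnd_mean", "theta"):
        assert res.params[k] == carried_truth.params[k]
    # the best reported cost is never worse than any start's initial cost
    assert all(res.nll <= s["nll0"] + 1e-9 for s in res.starts)


def test_degenerate_no_change_data_drives_tpip_down(s1_params, s1_crit,
                                                    s1_counts,
                                                    carried_truth):
    """Final categories forced equal to initial ones: a no-change solution
    (t_pip ~ 0) has lower cost than the generating change-producing one."""
    cfg = FitConfig(**COARSE)
    diag16 = np.zeros_like(s1_counts.counts16)
    for i in range(diag16.shape[0]):
        np.fill_diagonal(diag16[i], s1_counts.counts4[i])
    data = BehavioralCounts(s1_counts.coherences, s1_counts.counts4,
                            s1_counts.mean_rt, s1_counts.sem_rt, diag16)
    predictor = _RevisionPredictor(s1_params, s1_crit, data.coherences, cfg)
    nll_nochange = nll_revision(RevisionParams(t_pip=1e-4), carried_truth,
                                data, cfg, predictor=predictor)
    nll_generating = nll_revision(RevisionParams(0.395, 0.77, 0.24, -0.36),
                                  carried_truth, data, cfg,
                                  predictor=predictor)
    assert nll_nochange < nll_generating
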