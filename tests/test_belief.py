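"""Belief map, confidence criterion and initial-outcome predictions."""

import numpy as np
import pytest

from racemind import (ConfidenceCriterion, RaceParams,
                      alternative_confidence_rule, absorption_flux,
                      build_belief_map, initial_outcome_probs,
                      optimal_criterion, probability_equivalent)


def test_logodds_zero_at_zero_balance(s1_belief_map):
    t = np.array([0.1, 0.5, 2.0])
    assert np.allclose(s1_belief_map.log_odds(t, np.zeros(3)), 0.0)


def test_logodds_antisymmetric_and_monotone(s1_belief_map):
    t = 0.4
    d = np.linspace(-3, 3, 101)
    lo = s1_belief_map.log_odds(np.full_like(d, t), d)
    assert np.allclose(lo + lo[::-1], 0.0, atol=1e-10)
    assert np.all(np.diff(lo) > 0)


def test_logodds_grid_monotone_in_balance(s1_belief_map):
    interior = s1_belief_map.logodds[1:]  # t = 0 row is flat in t only
    assert np.all(np.diff(interior, axis=1) > 0)


def test_short_time_large_balance_gives_strong_belief(s1_params):
    bmap = build_belief_map(s1_params, [-0.256, 0.256])
    assert bmap.log_odds(0.05, 2.0) > 5.0


def test_zero_only_coherence_set_is_uninformative(s1_params):
    bmap = build_belief_map(s1_params, [0.0])
    t = np.full(5, 0.3)
    assert np.allclose(bmap.log_odds(t, np.linspace(-2, 2, 5)), 0.0)


def test_asymmetric_coherence_set_rejected(s1_params):
    with pytest.raises(ValueError, match="symmetric"):
        build_belief_map(s1_params, [0.0, 0.1])


def test_interp_matches_exact_and_clamps(s1_belief_map):
    v = s1_belief_map.interp_log_odds(0.33, 0.4)
    assert v == pytest.approx(s1_belief_map.log_odds(0.33, 0.4), abs=1e-3)
    with pytest.warns(RuntimeWarning, match="clamping"):
        s1_belief_map.interp_log_odds(0.33, 1e4)


def test_belief_map_roundtrip(tmp_path, s1_params):
    bmap = build_belief_map(s1_params, [-0.128, 0.0, 0.128],
                            time_grid=np.linspace(0, 2, 21),
                            balance_grid=np.linspace(-3, 3, 31))
    path = tmp_path / "map.tsv"
    bmap.to_delimited(path)
    from racemind import BeliefMap
    back = BeliefMap.from_delimited(path)
    assert np.allclose(back.logodds, bmap.logodds)
    assert np.allclose(back.prior, bmap.prior)
    assert back.params.kappa == bmap.params.kappa


def test_probability_equivalent_values():
    assert probability_equivalent(0.89) == pytest.approx(0.71, abs=0.005)
    assert probability_equivalent(1.26) == pytest.approx(0.78, abs=0.005)
    assert probability_equivalent(0.0) == 0.5
    with pytest.raises(ValueError):
        probability_equivalent(np.inf)


def test_optimal_criterion_cases():
    # the experimental payoffs: +2/-3 high risk vs +1/-1 low risk
    assert optimal_criterion([[2, -3], [1, -1]]) == pytest.approx(0.69, abs=0.005)
    # +3/-3 vs +1/-1 crosses at indifference (belief one half)
    assert optimal_criterion([[3, -3], [1, -1]]) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError, match="degenerate"):
        optimal_criterion([[1, -1], [1, -1]])


def test_initial_outcome_probs_basics(s1_params, s1_crit, s1_belief_map):
    sol = absorption_flux(s1_params, 0.0)
    pred0 = initial_outcome_probs(s1_params, s1_crit, s1_belief_map, 0.0,
                                  solution=sol)
    assert pred0.probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert pred0.probs[0] + pred0.probs[1] == pytest.approx(0.5, abs=1e-12)
    assert pred0.mean_rt == pytest.approx(
        pred0.mean_decision_time + s1_params.tnd_mean)


def test_criterion_limits(s1_params, s1_belief_map):
    sol = absorption_flux(s1_params, 0.128)
    hi = initial_outcome_probs(s1_params, ConfidenceCriterion(50.0),
                               s1_belief_map, 0.128, solution=sol)
    lo = initial_outcome_probs(s1_params, ConfidenceCriterion(1e-9),
                               s1_belief_map, 0.128, solution=sol)
    assert hi.probs[0] + hi.probs[2] == pytest.approx(0.0, abs=1e-9)
    assert lo.probs[0] + lo.probs[2] == pytest.approx(1.0, abs=1e-6)


def test_high_confidence_saturates_at_strong_motion(s1_params, s1_crit,
                                                    s1_belief_map):
    pred = initial_outcome_probs(s1_params, s1_crit, s1_belief_map, 0.512)
    p_high_correct = pred.probs[0] / (pred.probs[0] + pred.probs[1])
    assert p_high_correct > 0.9


def test_confidence_accuracy_coupling(s1_params, s1_crit, s1_belief_map):
    """P(correct | high) >= P(correct | low), and errors grow more confident
    with motion strength."""
    p_high_err = []
    for c in (0.032, 0.064, 0.128, 0.256):
        pred = initial_outcome_probs(s1_params, s1_crit, s1_belief_map, c)
        ch, cl, eh, el = pred.probs
        assert ch / (ch + eh) >= cl / (cl + el)
        p_high_err.append(eh / (eh + el))
    assert np.all(np.diff(p_high_err) > 0)


def test_outside_map_coherence_refused(s1_params, s1_crit, s1_belief_map):
    with pytest.raises(ValueError, match="refus"):
        initial_outcome_probs(s1_params, s1_crit, s1_belief_map, 0.3)


def test_alternative_rules_limits(s1_params):
    sol = absorption_flux(s1_params, 0.128)
    bal = alternative_confidence_rule("balance-only", 0.0, s1_params, 0.128,
                                      solution=sol)
    assert bal.probs[0] + bal.probs[2] == pytest.approx(1.0, abs=1e-9)
    tim = alternative_confidence_rule("time-only", 1e6, s1_params, 0.128,
                                      solution=sol)
    assert tim.probs[0] + tim.probs[2] == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError, match="unknown"):
        alternative_confidence_rule("both", 0.0, s1_params, 0.128, solution=sol)


def test_main_model_beats_time_only_rule(s1_params, s1_crit, s1_belief_map,
                                         s1_session):
    """On data from the full model, a decision-time-only confidence rule has
    a worse likelihood than the log-odds rule even at its best threshold."""
    from racemind.fitting import counts_from_trials
    data = counts_from_trials(s1_session)
    sols = {c: absorption_flux(s1_params, c) for c in data.coherences}

    def category_nll(pred_fn):
        nll = 0.0
        for i, c in enumerate(data.coherences):
            pred = pred_fn(c)
            nll -= np.sum(data.counts4[i] * np.log(np.clip(pred.probs,
                                                           1e-10, None)))
        return nll

    nll_main = category_nll(lambda c: initial_outcome_probs(
        s1_params, s1_crit, s1_belief_map, c, solution=sols[c]))
    nll_time = min(category_nll(lambda c: alternative_confidence_rule(
        "time-only", thr, s1_params, c, solution=sols[c]))
        for thr in (0.2, 0.3, 0.4, 0.6, 0.9))
    assert nll_main < nll_time
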