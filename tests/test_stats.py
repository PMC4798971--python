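"""Screening, change detection, logistic and odds-ratio analyses, points."""

import numpy as np
import pandas as pd
import pytest

from racemind import (classify_trajectories, detect_change, exclude_trials,
                      logistic_choice_with_confidence, logistic_confidence,
                      odds_ratio_analysis, points_accounting,
                      synthesize_trajectories)
from racemind.stats import _odds_ratio


def test_exclude_trials_boundary_cases():
    table = pd.DataFrame({"rt": [0.10, 0.149, 0.150, 0.80]})
    out = exclude_trials(table)
    assert len(out) == 2  # the rule is strictly "less than 150 ms"
    assert out.attrs["n_excluded_rt"] == 2
    assert 0.150 in out.rt.values
    empty = exclude_trials(pd.DataFrame({"rt": []}))
    assert len(empty) == 0
    slow = pd.DataFrame({"rt": [0.3, 0.5]})
    assert exclude_trials(slow).rt.tolist() == [0.3, 0.5]


def _path(points, n=500):
    pts = np.asarray(points, float)
    s = np.linspace(0, 1, n)
    seg = np.linspace(0, 1, len(pts))
    return pd.DataFrame({"t": s,
                         "x": np.interp(s, seg, pts[:, 0]),
                         "y": np.interp(s, seg, pts[:, 1])})


def test_detect_change_straight_reach():
    c = detect_change(_path([(0, 0), (8.5, 8.5)]))
    assert not c.change_of_decision and not c.change_of_confidence
    assert c.final_choice == 1 and c.final_conf == "high"
    assert c.initial_choice == 1 and c.initial_conf == "high"


def test_detect_change_excursion_area():
    # a 0.2 cm^2-scale excursion to the right before reaching the left target
    c = detect_change(_path([(0, 0), (1.2, 1.0), (1.2, 2.0), (0, 3.0),
                             (-8.5, 8.5)]))
    assert c.area_vertical > 0.1
    assert c.change_of_decision
    assert c.initial_choice == 1 and c.final_choice == -1


def test_detect_change_small_excursion_ignored():
    c = detect_change(_path([(0, 0), (0.1, 0.8), (-8.5, 8.5)]))
    assert c.area_vertical < 0.1
    assert not c.change_of_decision


def test_detect_change_layout_b_confidence():
    c = detect_change(_path([(0, 0), (8.5, 8.5)]), layout="B")
    assert c.final_conf == "low"


def test_detect_change_requires_movement():
    still = pd.DataFrame({"t": [0, 1], "x": [0.0, 0.2], "y": [0.0, 0.1]})
    with pytest.raises(ValueError, match="home"):
        detect_change(still)


def test_change_of_both_fixture_roundtrip(s1_session):
    both = s1_session[(s1_session.init_choice != s1_session.final_choice)
                      & (s1_session.init_conf != s1_session.final_conf)]
    sub = both.head(25)
    assert len(sub) > 0
    # re-plan only after the hand has cleared the home region, so the
    # excursion toward the first target is guaranteed to be measurable
    traj = synthesize_trajectories(sub.reset_index(drop=True), seed=3,
                                   replan_range=(0.35, 0.8))
    cls = classify_trajectories(traj,
                                layouts=sub.reset_index(drop=True).layout)
    assert cls.change_of_decision.all()
    assert cls.change_of_confidence.all()


def test_detector_recovers_planted_targets(s1_session):
    sub = s1_session.head(400).reset_index(drop=True)
    traj = synthesize_trajectories(sub, seed=13)
    cls = classify_trajectories(traj, layouts=sub.layout)
    ok = ((cls.initial_choice.values == sub.init_choice.values)
          & (cls.final_choice.values == sub.final_choice.values)
          & (cls.initial_conf.values == sub.init_conf.values)
          & (cls.final_conf.values == sub.final_conf.values))
    assert ok.mean() >= 0.99


def test_logistic_confidence_recovery():
    rng = np.random.default_rng(0)
    n = 10000
    c = rng.choice([0.0, 0.032, 0.064, 0.128, 0.256, 0.512], n)
    b0, b1 = -0.5, 8.0
    p = 1.0 / (1.0 + np.exp(-b0 - b1 * c))
    conf = np.where(rng.random(n) < p, "high", "low")
    trials = pd.DataFrame({"coherence": c, "init_conf": conf})
    f0, f1, sep = logistic_confidence(trials)
    assert not sep
    assert f0 == pytest.approx(b0, abs=0.15)
    assert f1 == pytest.approx(b1, abs=0.6)
    shuffled = trials.assign(init_conf=rng.permutation(conf))
    _, f1s, _ = logistic_confidence(shuffled)
    assert abs(f1s) < 0.5


def test_logistic_confidence_needs_both_levels():
    trials = pd.DataFrame({"coherence": [0.1] * 5, "init_conf": ["high"] * 5})
    with pytest.raises(ValueError):
        logistic_confidence(trials)


def _race_like_trials(rng, n=8000, b=(0.0, 8.0, 0.0, 4.0)):
    c = rng.choice([-0.256, -0.128, -0.064, 0.0, 0.064, 0.128, 0.256], n)
    high = rng.random(n) < 0.6
    logit = b[0] + b[1] * c + b[2] * high + b[3] * high * c
    right = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame({"coherence": c,
                         "init_choice": np.where(right, 1, -1),
                         "init_conf": np.where(high, "high", "low")})


def test_choice_logistic_interaction_and_symmetry():
    rng = np.random.default_rng(1)
    trials = _race_like_trials(rng)
    coefs, p, sep = logistic_choice_with_confidence(trials)
    assert coefs[3] > 0 and p < 0.01
    flipped = trials.assign(coherence=-trials.coherence,
                            init_choice=-trials.init_choice)
    coefs_f, _, _ = logistic_choice_with_confidence(flipped)
    assert abs(coefs_f[1]) == pytest.approx(abs(coefs[1]), rel=1e-6)


def test_choice_logistic_reduces_without_confidence_split():
    rng = np.random.default_rng(2)
    trials = _race_like_trials(rng, b=(0.2, 6.0, 0.0, 0.0))
    trials["init_conf"] = "high"  # indicator identically one
    coefs, p, sep = logistic_choice_with_confidence(trials)
    assert coefs[2] == 0.0 and coefs[3] == 0.0
    assert coefs[1] == pytest.approx(6.0, rel=0.2)


def test_odds_ratio_arithmetic_and_invariance():
    high = np.repeat([True, False, True, False], [90, 10, 50, 50])
    correct = np.repeat([True, True, False, False], [90, 10, 50, 50])
    assert _odds_ratio(high, correct) == pytest.approx(9.0)
    scaled = _odds_ratio(np.repeat(high, 3), np.repeat(correct, 3))
    assert scaled == pytest.approx(9.0)
    # an empty cell leaves the ratio undefined
    assert np.isnan(_odds_ratio(high[:100], correct[:100]))


def test_odds_ratio_identity_without_confidence_changes(s1_session):
    frozen = s1_session.assign(final_conf=s1_session.init_conf)
    res = odds_ratio_analysis(frozen, n_boot=50, seed=0)
    assert np.allclose(res.table.or_final, res.table.or_initial)


def test_bootstrap_cis_contain_point_and_shrink(s1_session):
    res = odds_ratio_analysis(s1_session, n_boot=200, seed=1)
    t = res.table
    assert ((t.or_initial_lo <= t.or_initial)
            & (t.or_initial <= t.or_initial_hi)).all()
    half = odds_ratio_analysis(s1_session.sample(frac=0.25, random_state=0),
                               n_boot=200, seed=1)
    joint = t.merge(half.table, on="coherence", suffixes=("", "_half"))
    w_full = (joint.or_initial_hi - joint.or_initial_lo)
    w_half = (joint.or_initial_hi_half - joint.or_initial_lo_half)
    assert (w_half > w_full).mean() > 0.6


def test_points_accounting_payoffs_and_benefit():
    trials = pd.DataFrame({
        "direction": [1, 1, 1, 1],
        "init_choice": [1, 1, -1, 1],
        "init_conf": ["high", "low", "high", "high"],
        "final_choice": [1, 1, -1, 1],
        "final_conf": ["high", "low", "low", "high"],
        "init_correct": [True, True, False, True],
        "final_correct": [True, True, False, True],
    })
    pts, benefit = points_accounting(trials)
    assert pts.tolist() == [2.0, 1.0, -1.0, 2.0]
    # the single change trial: high-risk error (-3) downgraded to -1
    assert benefit == pytest.approx(2.0)
    no_change = trials.iloc[[0, 1]]
    _, b2 = points_accounting(no_change)
    assert np.isnan(b2)
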