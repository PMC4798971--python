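"""Motion-energy filtering, psychophysical kernels, non-decision recovery."""

import numpy as np
import pandas as pd
import pytest

from racemind import (MotionFilterConfig, RaceParams, energy_residuals,
                      filter_impulse_response, fit_nondecision_from_kernel,
                      generate_dot_movie, kernel_model, motion_energy,
                      psychophysical_kernels, simulate_trials_from_movies)


@pytest.fixture(scope="module")
def impulse():
    return filter_impulse_response()


def test_energy_sign_convention():
    right = motion_energy(generate_dot_movie(1.0, 1, 60, seed=3))
    left = motion_energy(generate_dot_movie(1.0, -1, 60, seed=3))
    assert right.energy[8:].mean() > 0
    assert left.energy[8:].mean() < 0


def test_mirror_antisymmetry():
    mv = generate_dot_movie(0.256, 1, 45, seed=12)
    tr = motion_energy(mv)
    mir = motion_energy(mv.mirrored())
    assert np.max(np.abs(tr.energy + mir.energy)) < 1e-9 * max(
        1.0, np.max(np.abs(tr.energy)))


def test_mirrored_pair_cancels_net_energy():
    """Double-pass construction: a movie plus its mirror has no net bias."""
    sums = []
    for s in range(20):
        mv = generate_dot_movie(0.064, 1, 45, seed=s)
        sums.append(motion_energy(mv).energy + motion_energy(mv.mirrored()).energy)
    assert np.max(np.abs(np.mean(sums, axis=0))) < 1e-9


def test_zero_coherence_energy_centers_on_zero():
    means = [motion_energy(generate_dot_movie(0.0, 1, 45, seed=s)).energy.mean()
             for s in range(80)]
    sem = np.std(means) / np.sqrt(len(means))
    assert abs(np.mean(means)) < 3.0 * sem + 1e-12


def test_empty_movie_rejected():
    class _Empty:
        frames = []
        aperture = 5.0
        frame_rate = 75.0
    with pytest.raises(ValueError, match="empty"):
        motion_energy(_Empty())


def test_impulse_response_shape(impulse):
    peak = impulse.time[np.argmax(impulse.energy)]
    assert 0.02 < peak < 0.15  # delayed, band-pass response
    assert impulse.energy[-1] == pytest.approx(0.0, abs=1e-6)


class _Trace:
    def __init__(self, e):
        self.energy = np.asarray(e, dtype=float)
        self.time = np.arange(len(self.energy)) / 75.0

    def __len__(self):
        return len(self.energy)


def _toy_traces_and_trials(T=30, seed=0):
    rng = np.random.default_rng(seed)
    cohs = ([0.032] * 8 + [-0.032] * 8 + [0.0] * 4
            + [0.064] * 2      # singleton-ish weak cell: warned, excluded
            + [0.512] * 3)     # strong motion: filtered out
    trials = pd.DataFrame({
        "coherence": cohs,
        "direction": [1 if c >= 0 else -1 for c in cohs],
    })
    traces = [_Trace(10.0 * c + rng.standard_normal(T))
              for c in trials.coherence]
    return traces, trials


def test_residuals_center_each_condition_and_filter_strong_motion():
    traces, trials = _toy_traces_and_trials()
    with pytest.warns(RuntimeWarning, match="fewer than"):
        resid, kept = energy_residuals(traces, trials, min_trials=3)
    kept_trials = trials.loc[kept]
    assert (kept_trials.coherence.abs() <= 0.064).all()
    assert 0.064 not in kept_trials.coherence.values  # excluded small cell
    kept_list = list(kept)
    for (c, d), grp in kept_trials.groupby(["coherence", "direction"]):
        rows = [kept_list.index(i) for i in grp.index]
        cell = resid[rows]
        assert np.allclose(np.nanmean(cell, axis=0), 0.0, atol=1e-9)
        raw = np.array([traces[i].energy for i in grp.index])
        assert np.nanvar(cell) <= np.nanvar(raw) + 1e-12


def test_kernels_null_under_shuffled_labels():
    rng = np.random.default_rng(1)
    n, T = 400, 30
    resid = rng.standard_normal((n, T))
    trials = pd.DataFrame({
        "init_choice": rng.choice([-1, 1], n),
        "init_conf": rng.choice(["high", "low"], n),
        "final_choice": rng.choice([-1, 1], n),
        "final_conf": rng.choice(["high", "low"], n),
    })
    out = psychophysical_kernels(resid, trials, grouping="choice")
    assert np.abs(out["mean"]).max() < 4.0 / np.sqrt(n // 2)


def test_kernel_group_and_alignment_validation():
    resid = np.zeros((5, 4))
    trials = pd.DataFrame({"init_choice": [1] * 5,
                           "init_conf": ["high"] * 5,
                           "final_choice": [1] * 5,
                           "final_conf": ["high"] * 5})
    with pytest.raises(ValueError, match="grouping"):
        psychophysical_kernels(resid, trials, grouping="nope")
    with pytest.raises(ValueError, match="alignment"):
        psychophysical_kernels(resid, trials, alignment="nope")
    with pytest.warns(RuntimeWarning, match="omitted"):
        out = psychophysical_kernels(resid, trials, grouping="choice",
                                     min_trials=3)
    assert set(out.group) == {"right"}


def test_nondecision_recovery_from_synthetic_kernel(impulse):
    rng = np.random.default_rng(0)
    t = np.arange(-0.8, 1e-9, 1.0 / 75.0)
    clean = kernel_model(t, 1.0, 0.40, 0.06, impulse)
    fit = fit_nondecision_from_kernel(t, clean
                                      + 0.01 * rng.standard_normal(len(t)),
                                      impulse)
    assert fit.success
    assert fit.mu_tnd == pytest.approx(0.40, rel=0.10)
    assert fit.sigma_tnd == pytest.approx(0.06, rel=0.25)


def test_zero_variability_kernel_is_filter_smoothed_step(impulse):
    t = np.arange(-0.8, 1e-9, 1.0 / 75.0)
    clean = kernel_model(t, 1.0, 0.40, 1e-9, impulse)
    fit = fit_nondecision_from_kernel(t, clean, impulse)
    assert fit.sigma_tnd < 0.02
    # the rise width is set by the impulse response alone
    step = kernel_model(t, 1.0, 0.40, 1e-9, impulse)
    assert np.allclose(fit.fitted, step, atol=0.05)


def test_flat_kernel_flagged_nonidentifiable(impulse):
    rng = np.random.default_rng(3)
    t = np.arange(-0.8, 1e-9, 1.0 / 75.0)
    fit = fit_nondecision_from_kernel(t, 0.01 * rng.standard_normal(len(t)),
                                      impulse)
    assert not fit.success


def test_closed_loop_kernel_shape(s1_params, s1_crit, s1_belief_map):
    """Trials whose reports are driven by each movie's own energy: the
    choice-conditioned kernel is positive early and decays to nothing by
    movement onset (late evidence arrives after the decision)."""
    movies = []
    for s in range(240):
        c = [0.032, 0.064][s % 2]
        d = 1 if (s // 2) % 2 == 0 else -1
        movies.append(generate_dot_movie(c, d, 75, seed=100 + s))
    trials = simulate_trials_from_movies(movies, s1_params, crit=s1_crit,
                                         bmap=s1_belief_map, gain=4.0,
                                         seed=5)
    # the stimulus is extinguished at movement onset: energy defined to RT
    traces = []
    for m, rt in zip(movies, trials.rt):
        full = motion_energy(m)
        n_shown = max(int(rt * 75.0), 5)
        traces.append(_Trace(full.energy[:n_shown]))
    resid, kept = energy_residuals(traces, trials)
    kt = trials.loc[kept].reset_index(drop=True)
    # orient residuals toward the choice and pool for power
    signed = resid * kt.init_choice.to_numpy()[:, None]
    pooled = pd.DataFrame({"init_choice": np.ones(len(kt), dtype=int),
                           "init_conf": kt.init_conf,
                           "final_choice": np.ones(len(kt), dtype=int),
                           "final_conf": kt.init_conf})
    onset = psychophysical_kernels(signed, pooled, grouping="choice",
                                   alignment="onset")
    early = onset[(onset.time > 0.05) & (onset.time < 0.45)]["mean"]
    assert early.mean() > 0
    # movement-aligned: the kernel has vanished by movement onset
    mov = psychophysical_kernels(signed, pooled, grouping="choice",
                                 alignment="movement")
    late = mov[mov.time > -0.08]
    earlier = mov[(mov.time > -0.6) & (mov.time < -0.45)]
    assert late["mean"].mean() < earlier["mean"].mean()
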