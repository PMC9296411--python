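"""2-down-1-up staircase: psychometric observer, rule soundness, reversal
bookkeeping, threshold estimation, compliance screening."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from prosodim.staircase import (ObserverModel, StaircaseConfig, StaircaseTrack,
                                TARGET_P, convergence_point, estimate_threshold,
                                flag_noncompliance, log_transform,
                                observer_p_correct, run_staircase)


# ---------------------------------------------------------------- observer

def test_guess_rate_at_zero_excursion():
    obs = ObserverModel(alpha=1.0, beta=3.0, lapse=0.05)
    assert observer_p_correct(obs, 0.0) == pytest.approx(1 / 3)


def test_upper_asymptote():
    obs = ObserverModel(alpha=1.0, beta=3.0, lapse=0.05)
    assert observer_p_correct(obs, 100.0) == pytest.approx(1 - 0.05)


def test_convergence_point_closed_form_matches_root():
    obs = ObserverModel(alpha=1.0, beta=3.0, lapse=0.0)
    x = convergence_point(obs)
    root = brentq(lambda v: observer_p_correct(obs, v) - TARGET_P, 1e-6, 100.0)
    assert x == pytest.approx(root, rel=1e-9)
    assert observer_p_correct(obs, x) == pytest.approx(TARGET_P)


def test_convergence_point_scale_equivariance():
    a = convergence_point(ObserverModel(alpha=0.5, beta=3.0))
    b = convergence_point(ObserverModel(alpha=1.5, beta=3.0))
    assert b == pytest.approx(3.0 * a, rel=1e-12)


def test_unreachable_target_raises():
    with pytest.raises(ValueError):
        convergence_point(ObserverModel(alpha=1.0, beta=3.0, lapse=0.3738))


# ---------------------------------------------------------------- rule logic

def test_always_correct_descends_every_second_trial():
    track = run_staircase(ObserverModel(alpha=1.0), responses=[True] * 12)
    assert np.allclose(track.excursions, [6, 6, 5, 5, 4, 4, 3, 3, 2, 2, 1, 1])
    assert len(track.reversal_indices) == 0


def test_always_wrong_ascends_every_trial():
    track = run_staircase(ObserverModel(alpha=1.0), responses=[False] * 8)
    assert np.allclose(track.excursions, [6, 7, 8, 9, 10, 11, 12, 13])
    assert len(track.reversal_indices) == 0


def _reference_staircase(responses, start=6.0, schedule=((4, 1.0), (8, 0.1), (10 ** 9, 0.02)),
                         floor=0.02):
    """Independent hand-coded re-implementation of the rule for tracing."""
    x = start
    streak = 0
    last_dir = 0
    n_rev = 0
    levels, rev_idx = [], []
    for i, ok in enumerate(responses):
        levels.append(x)
        step = next(s for lim, s in schedule if n_rev < lim)
        d = 0
        if ok:
            streak += 1
            if streak == 2:
                streak = 0
                nx = max(floor, x - step)
                if nx < x:
                    d = -1
        else:
            streak = 0
            nx = x + step
            d = +1
        if d:
            if last_dir and d != last_dir:
                rev_idx.append(i)
                n_rev += 1
            last_dir = d
            x = nx
    return levels, rev_idx


def test_hand_traced_sequence_matches_reference():
    """A patterned C,C,W,... response stream drives the implementation and an
    independently coded trace of the rule to identical tracks."""
    pattern = ([True, True, False] * 20)[:60]
    track = run_staircase(ObserverModel(alpha=1.0), responses=pattern)
    levels, rev_idx = _reference_staircase(pattern[: track.n_trials])
    assert np.allclose(track.excursions, levels)
    assert track.reversal_indices.tolist() == rev_idx[: len(track.reversal_indices)]


def test_random_track_obeys_rule_and_schedule():
    """Every excursion change is +-(active step) (or a floor clamp); step
    sizes follow the 1 / 0.1 / 0.02 schedule keyed to reversal count."""
    cfg = StaircaseConfig()
    obs = ObserverModel(alpha=0.8, beta=3.0, lapse=0.02)
    for seed in range(5):
        tr = run_staircase(obs, cfg, seed=seed)
        assert tr.completed
        assert len(tr.reversal_indices) == cfg.total_reversals
        assert np.all(tr.excursions >= cfg.floor_excursion)
        rev = set(tr.reversal_indices.tolist())
        n_rev_before = 0
        for i in range(tr.n_trials):
            expected_step = cfg.step_for(n_rev_before)
            assert tr.steps[i] == expected_step
            if i + 1 < tr.n_trials:
                change = tr.excursions[i + 1] - tr.excursions[i]
                at_floor = tr.excursions[i + 1] == cfg.floor_excursion
                assert (change == 0.0
                        or abs(abs(change) - expected_step) < 1e-12
                        or (change < 0 and at_floor))
            if i in rev:
                n_rev_before += 1


def test_step_schedule_stages():
    cfg = StaircaseConfig()
    assert cfg.step_for(0) == 1.0
    assert cfg.step_for(3) == 1.0
    assert cfg.step_for(4) == 0.1
    assert cfg.step_for(7) == 0.1
    assert cfg.step_for(8) == 0.02
    assert cfg.step_for(13) == 0.02


def test_convergence_to_analytic_point():
    """Mean estimate over seeded runs sits near the 70.71%-correct point."""
    obs = ObserverModel(alpha=1.0, beta=3.0, lapse=0.01)
    cp = convergence_point(obs)
    rng = np.random.default_rng(0)
    ests = [run_staircase(obs, seed=int(rng.integers(2 ** 31 - 1))).threshold_estimate
            for _ in range(200)]
    assert np.mean(ests) == pytest.approx(cp, rel=0.25)


# ---------------------------------------------------------------- estimator

def _track_from(levels, rev_idx):
    levels = np.asarray(levels, dtype=float)
    return StaircaseTrack(excursions=levels,
                          correct=np.ones(len(levels), dtype=bool),
                          steps=np.full(len(levels), 0.1),
                          reversal_indices=np.asarray(rev_idx, dtype=int),
                          threshold_estimate=math.nan, log_threshold=math.nan,
                          completed=True)


def test_estimate_is_mean_of_last_six_reversals():
    levels = [6, 5, 4, 3, 2, 1, 0.4, 0.6, 0.4, 0.6, 0.4, 0.6]
    track = _track_from(levels, [6, 7, 8, 9, 10, 11])
    assert estimate_threshold(track) == pytest.approx(0.5)
    track2 = _track_from([1] * 8 + [0.5] * 6, list(range(8, 14)))
    assert estimate_threshold(track2) == pytest.approx(0.5)


def test_estimate_matches_recomputation_from_log():
    tr = run_staircase(ObserverModel(alpha=0.5), seed=77)
    manual = np.mean([tr.excursions[i] for i in tr.reversal_indices[-6:]])
    assert tr.threshold_estimate == pytest.approx(manual)
    assert tr.log_threshold == pytest.approx(np.log10(manual))


def test_estimate_requires_six_reversals():
    track = _track_from([6, 5, 4], [1, 2])
    with pytest.raises(ValueError):
        estimate_threshold(track)


# ---------------------------------------------------------------- compliance

def test_stable_track_not_flagged():
    levels = [6, 5, 4, 3, 2, 1] + [0.5, 0.6] * 6
    track = _track_from(levels, list(range(6, 18, 2)))
    flagged, diag = flag_noncompliance(track)
    assert not flagged
    assert not diag["rule_a"] and not diag["rule_b"]


def test_late_jump_triggers_rule_b():
    levels = [6, 5, 4, 3, 2, 1] + [0.5, 0.6, 0.5, 4.0, 0.5, 0.6] + [0.5] * 4
    track = _track_from(levels, [6, 7, 8, 9, 10, 11])
    flagged, diag = flag_noncompliance(track)
    assert flagged and diag["rule_b"]


def test_high_lapse_observers_flagged_more_often():
    cfg = StaircaseConfig()
    rng = np.random.default_rng(1)
    rates = []
    for lapse in (0.0, 0.3):
        obs = ObserverModel(alpha=0.5, beta=3.0, lapse=lapse)
        n_flagged = 0
        for _ in range(200):
            tr = run_staircase(obs, cfg, seed=int(rng.integers(2 ** 31 - 1)))
            n_flagged += flag_noncompliance(tr)[0]
        rates.append(n_flagged / 200)
    assert rates[1] > rates[0]


# ---------------------------------------------------------------- transform

def test_log_transform_values():
    out = log_transform([1.0, 0.1, 6.0])
    assert out == pytest.approx([0.0, -1.0, 0.7781512503836436])


def test_log_transform_rejects_nonpositive():
    with pytest.raises(ValueError):
        log_transform([1.0, 0.0])
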