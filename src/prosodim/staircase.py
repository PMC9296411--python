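"""2-down-1-up adaptive staircase for pitch-direction thresholds.

The track starts at a 6-semitone glide excursion, decreases the excursion
after two consecutive correct odd-one-out responses and increases it after
every error.  The step size follows a three-stage schedule (1 st initially,
0.1 st once four reversals have occurred, 0.02 st once eight have) and the
run terminates after 14 reversals; the threshold is the mean excursion at
the last six reversal trials.  A transformed up-down rule of this kind
converges on the stimulus level where the psychometric function passes
through 2^(-1/2) ~ 70.71% correct.

Simulated listeners are Weibull 3AFC observers:
``p(x) = 1/3 + (2/3 - lapse) * (1 - exp(-(x/alpha)^beta))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StaircaseConfig",
    "ObserverModel",
    "StaircaseTrack",
    "observer_p_correct",
    "convergence_point",
    "run_staircase",
    "estimate_threshold",
    "flag_noncompliance",
    "log_transform",
    "TARGET_P",
]

#: convergence target of a 2-down-1-up rule
TARGET_P = 2.0 ** -0.5
GUESS_3AFC = 1.0 / 3.0


@dataclass(frozen=True)
class StaircaseConfig:
    start_excursion: float = 6.0
    step_schedule: tuple[float, ...] = (1.0, 0.1, 0.02)
    step_reversals: tuple[int, ...] = (4, 8)  # reversal counts at which steps shrink
    total_reversals: int = 14
    estimator_reversals: int = 6
    floor_excursion: float = 0.02
    max_trials: int = 1000

    def __post_init__(self) -> None:
        if any(a <= b for a, b in zip(self.step_schedule[1:], self.step_schedule[2:])) \
                or self.step_schedule[0] <= self.step_schedule[1]:
            raise ValueError("step_schedule must be strictly decreasing")
        if len(self.step_schedule) != len(self.step_reversals) + 1:
            raise ValueError("need one step per schedule stage")
        if self.estimator_reversals > self.total_reversals:
            raise ValueError("estimator_reversals must be <= total_reversals")
        if self.floor_excursion <= 0:
            raise ValueError("floor_excursion must be positive")

    def step_for(self, reversals_so_far: int) -> float:
        """Step size active for a change occurring after ``reversals_so_far``
        reversals have completed."""
        stage = sum(reversals_so_far >= r for r in self.step_reversals)
        return self.step_schedule[stage]


@dataclass(frozen=True)
class ObserverModel:
    """Weibull psychometric observer for the 3AFC odd-one-out task."""

    alpha: float
    beta: float = 3.0
    lapse: float = 0.0
    guess: float = GUESS_3AFC

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not 0.0 <= self.lapse < 1.0 - self.guess:
            raise ValueError("lapse must lie in [0, 1 - guess)")


@dataclass
class StaircaseTrack:
    """Full per-trial record of one adaptive run."""

    excursions: np.ndarray            # stimulus level presented at each trial
    correct: np.ndarray               # response correctness per trial
    steps: np.ndarray                 # step size active at each trial's change
    reversal_indices: np.ndarray      # trial indices where direction flipped
    threshold_estimate: float
    log_threshold: float              # log10 semitones
    completed: bool                   # reached total_reversals before max_trials
    compliance_flag: bool = False
    compliance_diagnostics: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.excursions)

    def reversal_excursions(self) -> np.ndarray:
        return self.excursions[self.reversal_indices]


def observer_p_correct(obs: ObserverModel, excursion_st: float) -> float:
    """Probability of a correct odd-one-out response at a given excursion."""
    if excursion_st < 0:
        raise ValueError("excursion must be >= 0")
    x = excursion_st
    return obs.guess + (1.0 - obs.guess - obs.lapse) * (1.0 - math.exp(-((x / obs.alpha) ** obs.beta)))


def convergence_point(obs: ObserverModel, target_p: float = TARGET_P) -> float:
    """Excursion where the observer's psychometric function crosses the
    2-down-1-up convergence probability (70.71% correct by default).

    Closed-form inversion of the Weibull form; raises if the observer's
    upper asymptote ``1 - lapse`` lies below the target.
    """
    span = 1.0 - obs.guess - obs.lapse
    frac = (target_p - obs.guess) / span
    if frac >= 1.0:
        raise ValueError(
            f"target p={target_p:.4f} unreachable: asymptote {obs.guess + span:.4f}")
    if frac <= 0.0:
        raise ValueError("target below guess rate")
    return obs.alpha * (-math.log(1.0 - frac)) ** (1.0 / obs.beta)


def run_staircase(
    obs: ObserverModel,
    config: StaircaseConfig | None = None,
    seed: int = 0,
    responses: "list[bool] | None" = None,
) -> StaircaseTrack:
    """Run one 2-down-1-up track against a simulated observer.

    Responses are Bernoulli draws from ``observer_p_correct`` under ``seed``;
    alternatively an explicit boolean ``responses`` sequence can be supplied
    (for hand-traced verification), in which case the observer is ignored.

    Rule details (transformed up-down conventions): the correct-pair counter
    resets both after a decrease and after any error; a reversal is a trial
    whose excursion change direction differs from the previous change; the
    change completing the Nth scheduled reversal still uses the old step and
    the new step applies from the first change after it.  Excursions never
    fall below ``floor_excursion``.  If ``max_trials`` is exhausted first,
    the track is marked incomplete and the estimate uses the reversals
    available.
    """
    config = config or StaircaseConfig()
    rng = np.random.default_rng(seed)
    x = config.start_excursion
    consecutive_correct = 0
    last_direction = 0  # -1 down, +1 up, 0 no change yet
    excursions, corrects, steps = [], [], []
    reversal_indices: list[int] = []
    trial = 0
    while len(reversal_indices) < config.total_reversals and trial < config.max_trials:
        if responses is not None:
            if trial >= len(responses):
                break
            correct = bool(responses[trial])
        else:
            correct = rng.random() < observer_p_correct(obs, x)
        step = config.step_for(len(reversal_indices))
        excursions.append(x)
        corrects.append(correct)
        steps.append(step)
        direction = 0
        if correct:
            consecutive_correct += 1
            if consecutive_correct == 2:
                consecutive_correct = 0
                new_x = max(config.floor_excursion, x - step)
                if new_x < x:
                    direction = -1
        else:
            consecutive_correct = 0
            new_x = x + step
            direction = +1
        if direction != 0:
            if last_direction != 0 and direction != last_direction:
                reversal_indices.append(trial)
            last_direction = direction
            x = new_x
        trial += 1

    excursions_a = np.asarray(excursions)
    track = StaircaseTrack(
        excursions=excursions_a,
        correct=np.asarray(corrects, dtype=bool),
        steps=np.asarray(steps),
        reversal_indices=np.asarray(reversal_indices, dtype=int),
        threshold_estimate=math.nan,
        log_threshold=math.nan,
        completed=len(reversal_indices) >= config.total_reversals,
    )
    n_est = min(config.estimator_reversals, len(reversal_indices))
    if n_est >= 1:
        track.threshold_estimate = estimate_threshold(track, n_reversals=n_est)
        track.log_threshold = math.log10(track.threshold_estimate)
    return track


def estimate_threshold(track: StaircaseTrack, n_reversals: int = 6) -> float:
    """Mean excursion at the last ``n_reversals`` reversal trials."""
    if len(track.reversal_indices) < n_reversals:
        raise ValueError(
            f"track has {len(track.reversal_indices)} reversals, need {n_reversals}")
    idx = track.reversal_indices[-n_reversals:]
    return float(np.mean(track.excursions[idx]))


def flag_noncompliance(
    track: StaircaseTrack,
    cv_max: float = 0.5,
    late_fraction: float = 0.5,
    start_excursion: float = 6.0,
    n_reversals: int = 6,
) -> tuple[bool, dict]:
    """Heuristic screen for inattentive ("non-compliant") tracks.

    A surrogate for the visual track inspection used with human listeners.
    Flags when (a) the coefficient of variation of the last ``n_reversals``
    reversal excursions exceeds ``cv_max``, or (b) any excursion from the
    first of those reversals onward exceeds ``late_fraction`` of the
    starting excursion (a late jump back toward the start signals an
    attention lapse).  Returns the flag and which rule(s) fired.
    """
    if len(track.reversal_indices) < n_reversals:
        diag = {"rule_a": False, "rule_b": False, "incomplete": True}
        return True, diag
    idx = track.reversal_indices[-n_reversals:]
    rev_exc = track.excursions[idx]
    mean = float(np.mean(rev_exc))
    cv = float(np.std(rev_exc) / mean) if mean > 0 else math.inf
    late = track.excursions[idx[0]:]
    late_max = float(np.max(late))
    rule_a = cv > cv_max
    rule_b = late_max > late_fraction * start_excursion
    diag = {"rule_a": rule_a, "rule_b": rule_b, "cv": cv, "late_max": late_max,
            "incomplete": not track.completed}
    return bool(rule_a or rule_b or not track.completed), diag


def log_transform(thresholds) -> np.ndarray:
    """Base-10 log of thresholds (the scale used for parametric analysis)."""
    arr = np.asarray(thresholds, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("thresholds must be positive")
    return np.log10(arr)
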