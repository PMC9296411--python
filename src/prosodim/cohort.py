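"""Synthetic participant cohorts with the dependence structure the
downstream analyses assume.

Each simulated listener carries two latent quantities: a log2 pitch-glide
threshold (semitones) with group x age cell means, and an intonation
sensitivity on the d' scale used for the identification/discrimination/
imitation tasks.  The two are coupled by a Gaussian copula applied to the
threshold's *population-wide* quantile (its CDF under the equal-weight
mixture of cell-level normals), so the pooled-cohort Kendall tau between
threshold and sensitivity equals ``tau_target`` exactly — for a Gaussian
copula tau = (2/pi) * arcsin(r), hence r = sin(pi * tau / 2) — even in the
presence of group x age threshold effects.  (Coupling only the within-cell
variation would dilute the pooled tau, because between-cell threshold
differences would then be independent of sensitivity.)  A side effect is
that cells with worse thresholds also tend to have lower sensitivity,
which is the age-effect direction the analyses expect.  Kendall tau is
invariant to the monotone marginal transforms, so the calibration survives
the log / d' scalings.

Trial-level behaviour is an equal-variance signal-detection model with a
fixed criterion (0 by default — no response bias) mixed with a small
per-participant lapse rate of random responding.  This generator is a
stand-in for human choice behaviour, not a claim about it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .acoustics import GlideMeasurement, classify_sentence_type
from .stimuli import TrialList, UtteranceSpec

__all__ = [
    "GROUPS",
    "AGE_COHORTS",
    "CohortConfig",
    "Participant",
    "ResponseRecord",
    "generate_cohort",
    "simulate_perception_responses",
    "simulate_imitation",
    "imitation_sign_match_probability",
    "participants_to_frame",
    "responses_to_frame",
]

GROUPS = ("ASD", "control")
AGE_COHORTS = ("child", "adolescent", "adult")

#: default cell means of log2 threshold (semitones): children worse than
#: adolescents/adults, and ASD children worse than control children — the
#: effect directions the analyses are expected to recover.
DEFAULT_THRESHOLD_MEANS = {
    ("ASD", "child"): 1.0,        # 2.0 st
    ("control", "child"): 0.0,    # 1.0 st
    ("ASD", "adolescent"): -1.0,  # 0.5 st
    ("control", "adolescent"): -1.0,
    ("ASD", "adult"): -1.2,       # ~0.44 st
    ("control", "adult"): -1.3,   # ~0.41 st
}


@dataclass
class CohortConfig:
    """Generator settings for one synthetic cohort.

    ``group_age_threshold_means`` holds the mean log2-semitone threshold per
    (group, age) cell; ``tau_target`` is the target Kendall correlation
    (negative: better thresholds go with better intonation sensitivity)
    between log threshold and latent d'; ``music_advantage`` is the mean d'
    increment of the music condition over speech.
    """

    n_per_cell: int = 7
    group_age_threshold_means: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLD_MEANS))
    threshold_sd: float = 0.8
    tau_target: float = -0.4
    d_mean: float = 2.0
    d_sd: float = 0.8
    music_advantage: float = 0.3
    criterion: float = 0.0
    lapse_range: tuple[float, float] = (0.0, 0.04)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")
        if not -1.0 < self.tau_target < 1.0:
            raise ValueError(f"tau_target must lie in (-1, 1), got {self.tau_target}")
        if self.music_advantage < 0:
            raise ValueError("music_advantage must be >= 0")
        lo, hi = self.lapse_range
        if not (0.0 <= lo <= hi <= 0.1):
            raise ValueError("lapse_range must lie within [0, 0.1]")
        for cell in _cells():
            if cell not in self.group_age_threshold_means:
                raise ValueError(f"missing threshold mean for cell {cell}")


@dataclass
class Participant:
    id: str
    group: Literal["ASD", "control"]
    age_cohort: Literal["child", "adolescent", "adult"]
    latent_log_threshold: float          # log2 semitones
    latent_intonation_d: float           # d' scale
    condition_offsets: dict[str, float]  # {"speech": 0, "music": advantage}
    lapse: float

    @property
    def threshold_st(self) -> float:
        """Latent threshold on the semitone scale."""
        return 2.0 ** self.latent_log_threshold


@dataclass(frozen=True)
class ResponseRecord:
    participant_id: str
    task: Literal["discrimination", "identification", "imitation"]
    condition: Literal["speech", "music", "n/a"]
    trial_index: int
    truth: str
    response: str
    correct: bool


def _cells():
    return [(g, a) for g in GROUPS for a in AGE_COHORTS]


def generate_cohort(config: CohortConfig) -> list[Participant]:
    """Draw ``n_per_cell`` participants per group x age cell.

    Latent log thresholds are normal within each cell around the cell mean.
    Latent d' is generated from the threshold's population-wide quantile
    through a Gaussian copula with correlation
    ``r = sin(pi * tau_target / 2)``, so the pooled-cohort Kendall tau
    between the two latents equals ``tau_target``.  Deterministic under a
    fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    r = math.sin(math.pi * config.tau_target / 2.0)
    cell_means = np.array([config.group_age_threshold_means[c] for c in _cells()])
    participants: list[Participant] = []
    idx = 0
    for (group, age), mean in zip(_cells(), cell_means):
        for _ in range(config.n_per_cell):
            log_thr = mean + config.threshold_sd * rng.standard_normal()
            # population quantile of the threshold under the equal-weight
            # mixture of cell normals -> standard-normal copula coordinate
            u = float(np.mean(ndtr((log_thr - cell_means) / config.threshold_sd)))
            z_thr = float(ndtri(np.clip(u, 1e-12, 1.0 - 1e-12)))
            z_d = r * z_thr + math.sqrt(1.0 - r * r) * rng.standard_normal()
            participants.append(Participant(
                id=f"P{idx:03d}",
                group=group,
                age_cohort=age,
                latent_log_threshold=log_thr,
                latent_intonation_d=config.d_mean + config.d_sd * z_d,
                condition_offsets={"speech": 0.0, "music": config.music_advantage,
                                   "n/a": 0.0},
                lapse=float(rng.uniform(*config.lapse_range)),
            ))
            idx += 1
    return participants


_SIGNAL_LABEL = {"discrimination": "different", "identification": "question",
                 "imitation": "question"}
_NOISE_LABEL = {"discrimination": "same", "identification": "statement",
                "imitation": "statement"}


def simulate_perception_responses(
    p: Participant,
    trials: TrialList,
    seed: int,
    criterion: float = 0.0,
) -> list[ResponseRecord]:
    """Trial-level binary responses from the equal-variance SDT generator.

    Sensitivity is ``d = latent_intonation_d + condition_offsets[condition]``.
    Signal trials (truth = "different" / "question") draw evidence from
    N(d, 1), noise trials from N(0, 1); the decision cut sits at
    ``d/2 + criterion`` so ``criterion = 0`` is unbiased.  With probability
    ``lapse`` the response is instead uniformly random.
    """
    if trials.task not in ("discrimination", "identification"):
        raise ValueError(f"unsupported task {trials.task!r}")
    try:
        offset = p.condition_offsets[trials.condition]
    except KeyError:
        raise ValueError(f"unknown condition {trials.condition!r}") from None
    d = p.latent_intonation_d + offset
    signal = _SIGNAL_LABEL[trials.task]
    noise = _NOISE_LABEL[trials.task]
    rng = np.random.default_rng(seed)
    records = []
    for i, trial in enumerate(trials.trials):
        if rng.random() < p.lapse:
            response = signal if rng.random() < 0.5 else noise
        else:
            mean = d if trial.truth == signal else 0.0
            evidence = mean + rng.standard_normal()
            response = signal if evidence > d / 2.0 + criterion else noise
        records.append(ResponseRecord(
            participant_id=p.id, task=trials.task, condition=trials.condition,
            trial_index=i, truth=trial.truth, response=response,
            correct=response == trial.truth,
        ))
    return records


def imitation_sign_match_probability(d: float) -> float:
    """Closed-form probability that an imitation's glide sign matches the model.

    The imitation generator treats reproduction of the terminal contour as a
    2AFC decision driven by the same latent sensitivity as identification:
    P(match) = Phi(d / sqrt(2)), i.e. chance at d = 0 and saturating for
    large d.
    """
    return float(ndtr(d / math.sqrt(2.0)))


def simulate_imitation(
    p: Participant,
    spec: UtteranceSpec,
    seed: int,
    magnitude_sigma: float = 0.3,
) -> GlideMeasurement:
    """Simulate one imitation as a signed final-word glide.

    The glide's sign matches the model's with probability
    ``Phi(d / sqrt(2))`` where ``d = latent_intonation_d``; its magnitude is
    log-normal around the model magnitude with log-SD ``magnitude_sigma``.
    """
    if spec.final_glide_hz == 0:
        raise ValueError("model glide must be nonzero (ambiguous model)")
    rng = np.random.default_rng(seed)
    p_match = imitation_sign_match_probability(p.latent_intonation_d)
    sign = math.copysign(1.0, spec.final_glide_hz)
    if rng.random() >= p_match:
        sign = -sign
    magnitude = abs(spec.final_glide_hz) * math.exp(magnitude_sigma * rng.standard_normal())
    glide = sign * magnitude
    stem_dur = spec.stem_syllables * spec.syllable_duration
    interval = (stem_dur, stem_dur + spec.syllable_duration)
    return GlideMeasurement(
        glide_hz=glide, interval=interval, n_voiced_frames=-1,
        label=classify_sentence_type(glide),
        diagnostic="simulated imitation",
    )


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def participants_to_frame(participants: list[Participant]) -> pd.DataFrame:
    """One row per participant; columns documented in the package docs."""
    return pd.DataFrame({
        "participant_id": [p.id for p in participants],
        "group": [p.group for p in participants],
        "age_cohort": [p.age_cohort for p in participants],
        "latent_log2_threshold_st": [p.latent_log_threshold for p in participants],
        "latent_threshold_st": [p.threshold_st for p in participants],
        "latent_intonation_d": [p.latent_intonation_d for p in participants],
        "music_offset_d": [p.condition_offsets["music"] for p in participants],
        "lapse": [p.lapse for p in participants],
    })


def responses_to_frame(records: list[ResponseRecord]) -> pd.DataFrame:
    """One row per trial."""
    return pd.DataFrame({
        "participant_id": [r.participant_id for r in records],
        "task": [r.task for r in records],
        "condition": [r.condition for r in records],
        "trial_index": [r.trial_index for r in records],
        "truth": [r.truth for r in records],
        "response": [r.response for r in records],
        "correct": [r.correct for r in records],
    })
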