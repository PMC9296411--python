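"""Signal-detection scoring of perception and production responses.

Hit coding follows the study convention: in same/different discrimination,
correct responses to "different" trials are hits; in identification and
imitation, correct responses to "question" trials are hits.  Sensitivity is
d' with the log-linear correction (add 0.5 to each count and 1 to each
total before the inverse-normal transform), which keeps d' finite for
perfect and empty cells.  Per-individual chance performance is assessed
with an exact binomial tail test against the guessing rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy.special import ndtri
from scipy.stats import binom

from .cohort import ResponseRecord

__all__ = [
    "DetectionCounts",
    "DPrimeResult",
    "ChanceAssessment",
    "code_responses",
    "dprime_loglinear",
    "proportions_by_response_type",
    "binomial_chance_probability",
]

SIGNAL_LABEL = {"discrimination": "different", "identification": "question",
                "imitation": "question"}


@dataclass(frozen=True)
class DetectionCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self) -> None:
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def n_correct(self) -> int:
        return self.hits + self.correct_rejections

    @property
    def n_trials(self) -> int:
        return self.n_signal + self.n_noise


@dataclass(frozen=True)
class DPrimeResult:
    d_prime: float
    criterion_c: float
    hit_rate_adj: float
    fa_rate_adj: float


@dataclass(frozen=True)
class ChanceAssessment:
    n_correct: int
    n_trials: int
    p_chance: float
    tail_probability: float
    classification: Literal["chance", "above_chance"]


def code_responses(records: Iterable[ResponseRecord], task: str) -> DetectionCounts:
    """Contingency counts for one participant/task/condition record set."""
    if task not in SIGNAL_LABEL:
        raise ValueError(f"unknown task {task!r}")
    signal = SIGNAL_LABEL[task]
    h = m = fa = cr = 0
    for rec in records:
        if rec.task != task:
            raise ValueError(f"record task {rec.task!r} does not match {task!r}")
        said_signal = rec.response == signal
        if rec.truth == signal:
            h += said_signal
            m += not said_signal
        else:
            fa += said_signal
            cr += not said_signal
    return DetectionCounts(hits=h, misses=m, false_alarms=fa, correct_rejections=cr)


def dprime_loglinear(counts: DetectionCounts) -> DPrimeResult:
    """d' and criterion c with the log-linear correction.

    H = (hits + 0.5) / (n_signal + 1), F = (FA + 0.5) / (n_noise + 1);
    d' = z(H) - z(F), c = -(z(H) + z(F)) / 2.  The adjusted rates lie
    strictly inside (0, 1), so d' is finite for any integer counts.
    """
    if counts.n_signal < 1 or counts.n_noise < 1:
        raise ValueError("need at least one signal and one noise trial")
    h = (counts.hits + 0.5) / (counts.n_signal + 1)
    f = (counts.false_alarms + 0.5) / (counts.n_noise + 1)
    zh, zf = float(ndtri(h)), float(ndtri(f))
    return DPrimeResult(d_prime=zh - zf, criterion_c=-(zh + zf) / 2.0,
                        hit_rate_adj=h, fa_rate_adj=f)


def proportions_by_response_type(
    records: Iterable[ResponseRecord], task: str
) -> dict[str, float]:
    """Per-truth-category accuracy (the response-bias analysis input).

    Returns accuracy keyed by truth label (e.g. same/different or
    statement/question); categories with no trials are reported as NaN.
    """
    if task not in SIGNAL_LABEL:
        raise ValueError(f"unknown task {task!r}")
    totals: dict[str, int] = {}
    correct: dict[str, int] = {}
    for rec in records:
        if rec.task != task:
            raise ValueError(f"record task {rec.task!r} does not match {task!r}")
        totals[rec.truth] = totals.get(rec.truth, 0) + 1
        correct[rec.truth] = correct.get(rec.truth, 0) + rec.correct
    expected = {"discrimination": ("same", "different")}.get(task, ("statement", "question"))
    out: dict[str, float] = {}
    for label in expected:
        out[label] = correct[label] / totals[label] if totals.get(label) else float("nan")
    return out


def binomial_chance_probability(
    n_correct: int,
    n_trials: int,
    p_chance: float = 0.5,
    two_sided: bool = False,
    alpha: float = 0.05,
) -> ChanceAssessment:
    """Exact binomial assessment of whether accuracy exceeds guessing.

    The default test is the one-sided upper tail P(X >= n_correct) for
    X ~ Binomial(n_trials, p_chance): tail probabilities above ``alpha``
    are classified as consistent with chance.  A two-sided variant doubles
    the smaller tail (capped at 1).
    """
    if not 0 < p_chance < 1:
        raise ValueError("p_chance must lie in (0, 1)")
    if not 0 <= n_correct <= n_trials:
        raise ValueError("need 0 <= n_correct <= n_trials")
    upper = float(binom.sf(n_correct - 1, n_trials, p_chance))
    if two_sided:
        lower = float(binom.cdf(n_correct, n_trials, p_chance))
        tail = min(1.0, 2.0 * min(upper, lower))
    else:
        tail = upper
    cls = "chance" if tail > alpha else "above_chance"
    return ChanceAssessment(n_correct=n_correct, n_trials=n_trials,
                            p_chance=p_chance, tail_probability=tail,
                            classification=cls)
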