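"""Acoustic scoring: autocorrelation F0 tracking, signed final-word glide
measurement, statement/question classification, and imitation scoring.

The glide statistic is the quantity the study design turns on: the signed
F0 change (Hz) over the final word, negative for a terminal fall
(statement-like) and positive for a terminal rise (question-like).  It is
operationalised here as the OLS slope of frame-wise F0 on time over the
voiced frames of the final-word interval, multiplied by the interval
duration — robust to isolated frame errors, and equal to last-minus-first
F0 for a perfectly linear glide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .stimuli import AudioBuffer, F0Contour, UtteranceSpec

__all__ = [
    "F0ExtractionParams",
    "GlideMeasurement",
    "extract_f0",
    "measure_final_glide",
    "classify_sentence_type",
    "score_imitation",
    "read_interval_annotations",
]

#: dead zone (Hz) inside which a glide is too small to carry a label
DEFAULT_EPSILON_HZ = 1.0


@dataclass(frozen=True)
class F0ExtractionParams:
    """Frame-wise autocorrelation pitch-tracker settings.

    ``frame_length_s`` must cover at least two periods of the lowest search
    frequency ``fmin``; ``voicing_threshold`` is the minimum normalized
    autocorrelation peak for a frame to count as voiced.
    """

    frame_length_s: float = 0.04
    hop_s: float = 0.01
    fmin: float = 75.0
    fmax: float = 600.0
    voicing_threshold: float = 0.5
    silence_rms: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.fmin < self.fmax):
            raise ValueError("need 0 < fmin < fmax")
        if self.frame_length_s < 2.0 / self.fmin:
            raise ValueError("frame_length_s must be >= 2 periods of fmin")
        if self.hop_s <= 0:
            raise ValueError("hop_s must be positive")


@dataclass
class GlideMeasurement:
    """Signed final-word glide with its classification.

    ``label`` follows the sign rule with a dead zone: question iff
    ``glide_hz`` > +epsilon, statement iff < -epsilon, else ambiguous.
    """

    glide_hz: float
    interval: tuple[float, float]
    n_voiced_frames: int
    label: Literal["statement", "question", "ambiguous"]
    diagnostic: str = ""


def extract_f0(audio: AudioBuffer, params: F0ExtractionParams | None = None) -> F0Contour:
    """Frame-wise autocorrelation F0 estimate.

    Each frame's normalized autocorrelation is searched over the lag band
    corresponding to [fmin, fmax]; the winning peak is refined by parabolic
    interpolation.  Frames whose RMS falls below ``silence_rms`` or whose
    peak falls below ``voicing_threshold`` are marked unvoiced (f0 = 0).
    The biased autocorrelation estimator is used, which naturally penalises
    sub-octave (double-period) candidates.
    """
    params = params or F0ExtractionParams()
    if len(audio.samples) == 0:
        raise ValueError("empty audio")
    sr = audio.sample_rate
    if params.fmax >= sr / 2:
        raise ValueError(f"sample rate {sr} too low for fmax {params.fmax}")
    frame = int(round(params.frame_length_s * sr))
    hop = max(1, int(round(params.hop_s * sr)))
    lag_min = max(2, int(math.floor(sr / params.fmax)))
    lag_max = int(math.ceil(sr / params.fmin))
    if lag_max >= frame:
        raise ValueError("frame too short for fmin at this sample rate")

    x = audio.samples
    times, f0s = [], []
    for start in range(0, len(x) - frame + 1, hop):
        w = x[start:start + frame]
        t_center = (start + frame / 2) / sr
        times.append(t_center)
        if np.sqrt(np.mean(w * w)) < params.silence_rms:
            f0s.append(0.0)
            continue
        w = w - w.mean()
        # biased autocorrelation via FFT
        nfft = 1 << int(np.ceil(np.log2(2 * frame)))
        spec = np.fft.rfft(w, nfft)
        ac = np.fft.irfft(spec * np.conj(spec))[: lag_max + 2]
        if ac[0] <= 0:
            f0s.append(0.0)
            continue
        ac = ac / ac[0]
        seg = ac[lag_min: lag_max + 1]
        k = int(np.argmax(seg)) + lag_min
        if ac[k] < params.voicing_threshold:
            f0s.append(0.0)
            continue
        # parabolic interpolation around the peak
        if 1 <= k < len(ac) - 1:
            y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f0 = sr / (k + delta)
        f0s.append(f0 if params.fmin <= f0 <= params.fmax else 0.0)
    return F0Contour(times=np.asarray(times), f0=np.asarray(f0s))


def measure_final_glide(
    contour: F0Contour,
    interval: tuple[float, float] | None = None,
    epsilon_hz: float = DEFAULT_EPSILON_HZ,
    min_voiced_frames: int = 3,
    edge_margin_s: float = 0.02,
) -> GlideMeasurement:
    """Signed glide over the final word: OLS slope of F0 on time x duration.

    ``interval`` overrides the contour's own ``final_word_interval`` (used
    when the interval comes from an external annotation file).  Frames whose
    centres fall within ``edge_margin_s`` of the interval edges are dropped:
    their analysis windows straddle the boundary and mix stem F0 into the
    final-word regression.  Fewer than ``min_voiced_frames`` voiced frames
    yields an ambiguous measurement with a diagnostic rather than an
    exception.
    """
    iv = interval if interval is not None else contour.final_word_interval
    if iv is None:
        raise ValueError("no final-word interval available")
    start, end = iv
    if end <= start:
        raise ValueError("interval must have positive duration")
    margin = min(edge_margin_s, 0.25 * (end - start))
    mask = (contour.times >= start + margin) & (contour.times <= end - margin) \
        & contour.voiced_mask()
    n_voiced = int(mask.sum())
    if n_voiced < min_voiced_frames:
        return GlideMeasurement(
            glide_hz=0.0, interval=(start, end), n_voiced_frames=n_voiced,
            label="ambiguous",
            diagnostic=f"only {n_voiced} voiced frames in final-word interval",
        )
    t = contour.times[mask]
    f = contour.f0[mask]
    slope = float(np.polyfit(t, f, 1)[0])
    glide = slope * (end - start)
    return GlideMeasurement(
        glide_hz=glide, interval=(start, end), n_voiced_frames=n_voiced,
        label=classify_sentence_type(glide, epsilon_hz=epsilon_hz),
    )


def classify_sentence_type(
    glide: "GlideMeasurement | float",
    epsilon_hz: float = DEFAULT_EPSILON_HZ,
) -> Literal["statement", "question", "ambiguous"]:
    """Sign rule: rise => question, fall => statement, |glide| <= eps => ambiguous."""
    g = glide.glide_hz if isinstance(glide, GlideMeasurement) else float(glide)
    if g > epsilon_hz:
        return "question"
    if g < -epsilon_hz:
        return "statement"
    return "ambiguous"


def read_interval_annotations(path, label: str = "final_word") -> dict:
    """Read a final-word annotation CSV for external audio.

    Expected columns: ``file, start_s, end_s, label``.  Returns a mapping
    from file name to ``(start, end)`` for rows carrying ``label`` — the
    interval handed to :func:`measure_final_glide`.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"file", "start_s", "end_s", "label"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation CSV needs columns {sorted(required)}")
    sel = df[df["label"] == label]
    return {row.file: (float(row.start_s), float(row.end_s))
            for row in sel.itertuples()}


def score_imitation(model: UtteranceSpec, imitation: GlideMeasurement) -> bool:
    """An imitation is correct iff its glide shares the model's sign.

    Magnitude is irrelevant: a -12 Hz fall correctly imitates a -40 Hz
    statement model.  Ambiguous imitations (within the dead zone or with too
    few voiced frames) are scored incorrect.
    """
    if model.final_glide_hz == 0:
        raise ValueError("model glide must be nonzero")
    if imitation.label == "ambiguous":
        return False
    model_label = "statement" if model.final_glide_hz < 0 else "question"
    return imitation.label == model_label
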