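"""Stimulus construction: pitch glides, pseudo-utterance F0 contours,
musical analogues, additive-synthesis rendering, and trial lists.

All pitch material is specified as an :class:`F0Contour` — a sampled
fundamental-frequency trajectory with syllable and final-word intervals —
which is the shared currency between synthesis and acoustic analysis.
Glides for the threshold task are log-linear in frequency and geometrically
centred, so that upward and downward glides are mirror images on a
log-frequency axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "F0Contour",
    "UtteranceSpec",
    "AudioBuffer",
    "Trial",
    "TrialList",
    "make_glide_contour",
    "make_triplet",
    "make_utterance_contour",
    "render_speech_proxy",
    "render_musical_analogue",
    "normalize_peak",
    "build_discrimination_trials",
    "build_identification_trials",
    "write_wav",
    "read_wav",
    "DEFAULT_SAMPLE_RATE",
]

DEFAULT_SAMPLE_RATE = 22_050
#: odd-harmonic multipliers used for the musical analogues: the fundamental
#: plus its seven odd harmonics (overtones 3f, 5f, ..., 15f).
ODD_HARMONICS = (1, 3, 5, 7, 9, 11, 13, 15)
SPEECH_HARMONICS = 15


@dataclass
class F0Contour:
    """Time-stamped F0 trajectory with interval annotations.

    ``f0`` entries of 0 mark unvoiced samples.  ``syllable_intervals`` are
    ordered, non-overlapping ``(start, end)`` pairs in seconds;
    ``final_word_interval`` (when set) delimits the glide-carrying final word.
    """

    times: np.ndarray
    f0: np.ndarray
    syllable_intervals: list[tuple[float, float]] = field(default_factory=list)
    final_word_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.f0.shape:
            raise ValueError("times and f0 must be 1-D arrays of equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.f0 < 0):
            raise ValueError("f0 must be non-negative (0 marks unvoiced)")
        ends = [iv[1] for iv in self.syllable_intervals]
        starts = [iv[0] for iv in self.syllable_intervals]
        if any(e <= s for s, e in self.syllable_intervals):
            raise ValueError("syllable intervals must have positive duration")
        if any(s2 < e1 - 1e-12 for e1, s2 in zip(ends, starts[1:])):
            raise ValueError("syllable intervals must be ordered, non-overlapping")
        if self.final_word_interval is not None and len(self.times):
            s, e = self.final_word_interval
            if s < self.times[0] - 1e-9 or e > self.times[-1] + 1e-9:
                raise ValueError("final_word_interval outside contour time span")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def voiced_mask(self) -> np.ndarray:
        return self.f0 > 0


@dataclass(frozen=True)
class UtteranceSpec:
    """Parametric description of one pseudo-utterance.

    A statement carries a falling final glide (``final_glide_hz`` < 0), a
    question a rising one (> 0); pair members sharing ``pair_id`` share the
    identical stem (cross-splice construction).
    """

    sentence_type: Literal["statement", "question"]
    final_glide_hz: float
    pair_id: str
    stem_syllables: int = 4
    stem_start_f0: float = 220.0
    declination: float = -16.0
    syllable_duration: float = 0.25

    def __post_init__(self) -> None:
        if self.sentence_type not in ("statement", "question"):
            raise ValueError(f"unknown sentence_type {self.sentence_type!r}")
        expected_sign = -1.0 if self.sentence_type == "statement" else 1.0
        if self.final_glide_hz * expected_sign <= 0:
            raise ValueError(
                "final_glide_hz must be negative for statements and positive "
                f"for questions; got {self.final_glide_hz} for {self.sentence_type}"
            )
        if self.declination > 0:
            raise ValueError("declination must be <= 0 Hz/s")
        if self.stem_syllables < 1 or self.syllable_duration <= 0:
            raise ValueError("invalid stem geometry")


@dataclass
class AudioBuffer:
    """Mono audio samples in [-1, 1] at a fixed sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D (mono)")
        if np.max(np.abs(self.samples), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("samples must lie in [-1, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def peak(self) -> float:
        return float(np.max(np.abs(self.samples), initial=0.0))


@dataclass(frozen=True)
class Trial:
    """One trial descriptor: stimulus references plus the truth label."""

    stimuli: tuple[UtteranceSpec, ...]
    truth: str
    pair_id: str


@dataclass
class TrialList:
    task: Literal["discrimination", "identification"]
    condition: Literal["speech", "music", "n/a"]
    trials: list[Trial]
    isi_ms: int = 750
    iti_ms: int = 2000

    def __len__(self) -> int:
        return len(self.trials)

    def truth_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.trials:
            out[t.truth] = out.get(t.truth, 0) + 1
        return out


# ---------------------------------------------------------------------------
# contour construction
# ---------------------------------------------------------------------------

def make_glide_contour(
    center_hz: float,
    excursion_st: float,
    direction: Literal["up", "down"],
    duration_s: float,
    n_points: int = 121,
    log_linear: bool = True,
) -> F0Contour:
    """Single gliding tone, geometrically centred on ``center_hz``.

    The glide spans ``excursion_st`` semitones end-to-end, so the endpoints
    are ``center * 2**(-e/24)`` and ``center * 2**(+e/24)`` (order set by
    ``direction``).  With ``log_linear`` the trajectory is linear in
    log-frequency (the default); otherwise linear in Hz between the same
    endpoints.
    """
    if center_hz <= 0:
        raise ValueError("center_hz must be positive")
    if excursion_st < 0:
        raise ValueError("excursion_st must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    sign = 1.0 if direction == "up" else -1.0
    t = np.linspace(0.0, duration_s, n_points)
    half = sign * excursion_st / 24.0  # semitones -> octave fraction of half-span
    if log_linear:
        f0 = center_hz * 2.0 ** np.linspace(-half, half, n_points)
    else:
        f0 = np.linspace(center_hz * 2.0 ** -half, center_hz * 2.0 ** half, n_points)
    return F0Contour(times=t, f0=f0, syllable_intervals=[(0.0, duration_s)],
                     final_word_interval=(0.0, duration_s))


def make_triplet(
    target_direction: Literal["up", "down"],
    excursion_st: float,
    rng: np.random.Generator,
    center_hz: float = 500.0,
    duration_s: float = 0.6,
) -> tuple[list[F0Contour], int]:
    """Odd-one-out triplet for the pitch-direction task.

    Returns three glide contours of identical centre, excursion and duration:
    the target glide moves in ``target_direction`` while the two distractors
    move the opposite way.  The target's position (0-based ``odd_index``) is
    uniform over the three slots under ``rng``.
    """
    if excursion_st < 0:
        raise ValueError("excursion_st must be >= 0")
    other = "down" if target_direction == "up" else "up"
    odd_index = int(rng.integers(3))
    contours = []
    for i in range(3):
        d = target_direction if i == odd_index else other
        contours.append(make_glide_contour(center_hz, excursion_st, d, duration_s))
    return contours, odd_index


def make_utterance_contour(spec: UtteranceSpec, hop_s: float = 0.005) -> F0Contour:
    """F0 contour of a pseudo-utterance: declining stem + final-word glide.

    The stem follows a linear declination from ``stem_start_f0``; the final
    word is one syllable carrying a linear (in Hz) glide of
    ``final_glide_hz`` starting from the stem's final F0.  Statement and
    question members of a pair are sample-identical over the stem.
    """
    stem_dur = spec.stem_syllables * spec.syllable_duration
    total = stem_dur + spec.syllable_duration
    n = int(round(total / hop_s)) + 1
    t = np.linspace(0.0, total, n)
    f0 = np.empty_like(t)
    stem_mask = t <= stem_dur + 1e-12
    f0[stem_mask] = spec.stem_start_f0 + spec.declination * t[stem_mask]
    f_end = spec.stem_start_f0 + spec.declination * stem_dur
    tf = t[~stem_mask]
    f0[~stem_mask] = f_end + spec.final_glide_hz * (tf - stem_dur) / spec.syllable_duration
    if np.any(f0 <= 0):
        raise ValueError("contour would cross 0 Hz; adjust declination/glide")
    syllables = [
        (i * spec.syllable_duration, (i + 1) * spec.syllable_duration)
        for i in range(spec.stem_syllables + 1)
    ]
    return F0Contour(times=t, f0=f0, syllable_intervals=syllables,
                     final_word_interval=(stem_dur, total))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _raised_cosine_envelope(n: int, sr: int, ramp_s: float) -> np.ndarray:
    """Unit envelope with raised-cosine onset/offset ramps."""
    env = np.ones(n)
    ramp = min(int(round(ramp_s * sr)), n // 2)
    if ramp > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = r
        env[-ramp:] = r[::-1]
    return env


def _interval_slice(interval: tuple[float, float], sr: int, n_total: int):
    a = max(0, int(round(interval[0] * sr)))
    b = min(n_total, int(round(interval[1] * sr)))
    return a, b


def _check_nyquist(max_f0: float, max_harmonic: int, sample_rate: int) -> None:
    if max_f0 * max_harmonic >= sample_rate / 2:
        raise ValueError(
            f"highest component {max_f0 * max_harmonic:.0f} Hz violates Nyquist "
            f"at sample rate {sample_rate}"
        )


def render_speech_proxy(
    contour: F0Contour,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    ramp_s: float = 0.015,
    peak: float = 0.9,
) -> AudioBuffer:
    """Render a harmonic-rich 'speech proxy' from an F0 contour.

    Additive synthesis with harmonics 1..15 at amplitudes 1/n and a
    raised-cosine amplitude envelope per syllable (silence outside syllable
    intervals).  Phase is accumulated from the instantaneous F0, so the
    waveform is phase-continuous through F0 changes.  Gain is a fixed
    worst-case bound (``peak / sum(1/n)``) rather than a per-signal peak
    scaling, so stimuli sharing a stem stay sample-identical over the stem.
    Only the pitch trajectory is meaningful; the timbre is a fixed
    synthetic stand-in.
    """
    voiced = contour.voiced_mask()
    if not np.any(voiced):
        raise ValueError("contour has no voiced samples")
    _check_nyquist(float(contour.f0.max()), SPEECH_HARMONICS, sample_rate)

    t0, t1 = contour.times[0], contour.times[-1]
    n = int(round((t1 - t0) * sample_rate)) + 1
    ts = t0 + np.arange(n) / sample_rate
    f0 = np.interp(ts, contour.times[voiced], contour.f0[voiced])
    phase = 2.0 * np.pi * np.cumsum(f0) / sample_rate
    x = np.zeros(n)
    for h in range(1, SPEECH_HARMONICS + 1):
        x += np.sin(h * phase) / h
    env = np.zeros(n)
    for iv in contour.syllable_intervals:
        a, b = _interval_slice((iv[0] - t0, iv[1] - t0), sample_rate, n)
        if b > a:
            env[a:b] = np.maximum(env[a:b],
                                  _raised_cosine_envelope(b - a, sample_rate, ramp_s))
    x *= env * (peak / sum(1.0 / h for h in range(1, SPEECH_HARMONICS + 1)))
    return AudioBuffer(samples=x, sample_rate=sample_rate)


def render_musical_analogue(
    contour: F0Contour,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    ramp_s: float = 0.015,
    peak: float = 0.9,
) -> AudioBuffer:
    """Render the musical analogue of an utterance contour.

    One discrete gliding complex tone per syllable interval, built from the
    fundamental and its seven odd harmonics (components at F0·{1,3,...,15},
    amplitudes 1/n) — exactly eight spectral components, no even harmonics.
    Pitch and timing match the source contour; verbal timbre is removed.
    """
    voiced = contour.voiced_mask()
    if not np.any(voiced):
        raise ValueError("contour has no voiced samples")
    _check_nyquist(float(contour.f0.max()), ODD_HARMONICS[-1], sample_rate)

    t0, t1 = contour.times[0], contour.times[-1]
    n = int(round((t1 - t0) * sample_rate)) + 1
    ts = t0 + np.arange(n) / sample_rate
    f0 = np.interp(ts, contour.times[voiced], contour.f0[voiced])
    x = np.zeros(n)
    for iv in contour.syllable_intervals:
        a, b = _interval_slice((iv[0] - t0, iv[1] - t0), sample_rate, n)
        if b <= a:
            continue
        phase = 2.0 * np.pi * np.cumsum(f0[a:b]) / sample_rate
        tone = np.zeros(b - a)
        for h in ODD_HARMONICS:
            tone += np.sin(h * phase) / h
        x[a:b] += tone * _raised_cosine_envelope(b - a, sample_rate, ramp_s)
    x *= peak / sum(1.0 / h for h in ODD_HARMONICS)
    return AudioBuffer(samples=x, sample_rate=sample_rate)


def normalize_peak(audio: AudioBuffer, reference: AudioBuffer) -> AudioBuffer:
    """Scale ``audio`` so its peak amplitude matches the reference's."""
    ref_peak = reference.peak()
    if ref_peak == 0:
        raise ValueError("silent reference")
    in_peak = audio.peak()
    if in_peak == 0:
        raise ValueError("silent input cannot be peak-normalized")
    return AudioBuffer(samples=audio.samples * (ref_peak / in_peak),
                       sample_rate=audio.sample_rate)


# ---------------------------------------------------------------------------
# trial lists
# ---------------------------------------------------------------------------

def build_discrimination_trials(
    pairs: Sequence[tuple[UtteranceSpec, UtteranceSpec]],
    condition: Literal["speech", "music"],
    rng: np.random.Generator,
    strict_balance: bool = True,
) -> TrialList:
    """Same/different discrimination block: 2 trials per pair.

    Each statement-question pair contributes one "different" trial (the two
    members) and one "same" trial (one member repeated).  Which member is
    repeated is balanced across pairs — half statement-same, half
    question-same — to avoid confounding response type with sentence type.
    Trial order is shuffled under ``rng``.
    """
    if condition not in ("speech", "music"):
        raise ValueError(f"unknown condition {condition!r}")
    n = len(pairs)
    if strict_balance and n % 2 != 0:
        raise ValueError("odd pair count cannot balance statement-same/question-same")
    for stmt, ques in pairs:
        if stmt.sentence_type != "statement" or ques.sentence_type != "question":
            raise ValueError("each pair must be (statement, question)")
        if stmt.pair_id != ques.pair_id:
            raise ValueError("pair members must share pair_id")
    # which pairs repeat their statement on the "same" trial
    same_member = np.array(["statement"] * (n // 2) + ["question"] * (n - n // 2))
    rng.shuffle(same_member)
    trials: list[Trial] = []
    for (stmt, ques), member in zip(pairs, same_member):
        order = (stmt, ques) if rng.integers(2) == 0 else (ques, stmt)
        trials.append(Trial(stimuli=order, truth="different", pair_id=stmt.pair_id))
        rep = stmt if member == "statement" else ques
        trials.append(Trial(stimuli=(rep, rep), truth="same", pair_id=stmt.pair_id))
    perm = rng.permutation(len(trials))
    trials = [trials[i] for i in perm]
    return TrialList(task="discrimination", condition=condition, trials=trials)


def build_identification_trials(
    pairs: Sequence[tuple[UtteranceSpec, UtteranceSpec]],
    rng: np.random.Generator,
) -> TrialList:
    """Statement/question identification block: every member once, shuffled."""
    trials: list[Trial] = []
    for stmt, ques in pairs:
        trials.append(Trial(stimuli=(stmt,), truth="statement", pair_id=stmt.pair_id))
        trials.append(Trial(stimuli=(ques,), truth="question", pair_id=ques.pair_id))
    perm = rng.permutation(len(trials))
    trials = [trials[i] for i in perm]
    return TrialList(task="identification", condition="speech", trials=trials)


def default_utterance_pairs(
    n_pairs: int = 18,
    rng: np.random.Generator | None = None,
    glide_range_hz: tuple[float, float] = (30.0, 80.0),
) -> list[tuple[UtteranceSpec, UtteranceSpec]]:
    """Construct a default statement-question pair set.

    Glide magnitudes are drawn per pair from ``glide_range_hz``; stem length
    varies over 3-5 syllables.  Pair members share the identical stem.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pairs = []
    for i in range(n_pairs):
        mag = float(rng.uniform(*glide_range_hz))
        n_syl = int(rng.integers(3, 6))
        common = dict(pair_id=f"pair{i:02d}", stem_syllables=n_syl,
                      stem_start_f0=220.0, declination=-16.0)
        stmt = UtteranceSpec(sentence_type="statement", final_glide_hz=-mag, **common)
        ques = UtteranceSpec(sentence_type="question", final_glide_hz=+mag, **common)
        pairs.append((stmt, ques))
    return pairs


def pairs_to_manifest(
    pairs: Sequence[tuple[UtteranceSpec, UtteranceSpec]],
    path_for=None,
) -> pd.DataFrame:
    """Stimulus manifest table: one row per pair member.

    ``path_for(spec)`` may supply an audio file path per stimulus (empty
    string otherwise).  The manifest carries everything the acoustic
    scoring needs: pair identity, sentence type, signed glide, and the
    final-word interval.
    """
    rows = []
    for stmt, ques in pairs:
        for spec in (stmt, ques):
            stem_dur = spec.stem_syllables * spec.syllable_duration
            rows.append({
                "pair_id": spec.pair_id,
                "sentence_type": spec.sentence_type,
                "final_glide_hz": spec.final_glide_hz,
                "final_word_start_s": stem_dur,
                "final_word_end_s": stem_dur + spec.syllable_duration,
                "path": path_for(spec) if path_for is not None else "",
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# WAV I/O
# ---------------------------------------------------------------------------

def write_wav(audio: AudioBuffer, path, subtype: str = "float32") -> None:
    """Write an AudioBuffer as WAV (``float32`` or ``pcm16``)."""
    if subtype == "float32":
        wavfile.write(path, audio.sample_rate, audio.samples.astype(np.float32))
    elif subtype == "pcm16":
        q = np.clip(np.round(audio.samples * 32767.0), -32768, 32767).astype(np.int16)
        wavfile.write(path, audio.sample_rate, q)
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def read_wav(path) -> AudioBuffer:
    """Read a WAV file into an AudioBuffer (int formats rescaled to [-1, 1])."""
    try:
        sr, data = wavfile.read(path)
    except ValueError as exc:
        raise IOError(f"could not read WAV file {path}: {exc}") from exc
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = np.clip(data.astype(float), -1.0, 1.0)
    return AudioBuffer(samples=samples, sample_rate=int(sr))
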