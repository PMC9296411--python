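"""Stimulus synthesis: glide geometry, utterance contours, rendering
spectra, amplitude normalization, trial lists, WAV I/O."""

import numpy as np
import pytest
from scipy.stats import chisquare

from prosodim.stimuli import (AudioBuffer, F0Contour, UtteranceSpec,
                              build_discrimination_trials,
                              build_identification_trials,
                              default_utterance_pairs, make_glide_contour,
                              make_triplet, make_utterance_contour,
                              normalize_peak, read_wav,
                              render_musical_analogue, render_speech_proxy,
                              write_wav)


# ---------------------------------------------------------------- contours

def test_zero_excursion_glide_is_constant():
    c = make_glide_contour(500.0, 0.0, "up", 0.6)
    assert np.allclose(c.f0, 500.0)
    assert c.times[-1] == pytest.approx(0.6)


def test_glide_endpoints_geometrically_centred():
    # six-semitone glide spans 500 * 2^(+-3/12)
    c = make_glide_contour(500.0, 6.0, "up", 0.6)
    assert c.f0[0] == pytest.approx(500 * 2 ** (-3 / 12), rel=1e-9)
    assert c.f0[-1] == pytest.approx(500 * 2 ** (3 / 12), rel=1e-9)
    # geometric centring: the log-midpoint is the centre frequency
    assert np.sqrt(c.f0[0] * c.f0[-1]) == pytest.approx(500.0, rel=1e-9)


def test_down_glide_mirrors_up_glide():
    up = make_glide_contour(500.0, 6.0, "up", 0.6)
    down = make_glide_contour(500.0, 6.0, "down", 0.6)
    assert np.allclose(up.f0, down.f0[::-1])


def test_triplet_structure_and_odd_index_uniformity(rng):
    counts = np.zeros(3)
    for _ in range(3000):
        contours, odd = make_triplet("up", 6.0, rng)
        counts[odd] += 1
    assert chisquare(counts).pvalue > 0.01
    contours, odd = make_triplet("up", 6.0, rng)
    assert all(c.duration == pytest.approx(0.6) for c in contours)
    # the odd tone rises, the two distractors fall
    rises = [c.f0[-1] > c.f0[0] for c in contours]
    assert rises[odd] and sum(rises) == 1


def test_degenerate_zero_excursion_triplet(rng):
    contours, odd = make_triplet("up", 0.0, rng)
    assert odd in (0, 1, 2)
    for c in contours[1:]:
        assert np.allclose(c.f0, contours[0].f0)


def test_pair_members_share_identical_stem():
    stmt = UtteranceSpec("statement", -50.0, "p1")
    ques = UtteranceSpec("question", +50.0, "p1")
    cs, cq = make_utterance_contour(stmt), make_utterance_contour(ques)
    stem_end = stmt.stem_syllables * stmt.syllable_duration
    mask = cs.times <= stem_end
    assert np.array_equal(cs.f0[mask], cq.f0[mask])


def test_final_word_glide_endpoint():
    spec = UtteranceSpec("question", +50.0, "p2", stem_start_f0=200.0,
                         declination=0.0)
    c = make_utterance_contour(spec)
    assert c.f0[-1] == pytest.approx(250.0, abs=1e-9)
    assert c.f0[0] == pytest.approx(200.0)


def test_contour_crossing_zero_rejected():
    spec = UtteranceSpec("statement", -300.0, "p3", stem_start_f0=200.0)
    with pytest.raises(ValueError):
        make_utterance_contour(spec)


# ---------------------------------------------------------------- rendering

def _spectrum(audio: AudioBuffer):
    w = audio.samples * np.hanning(len(audio.samples))
    spec = np.abs(np.fft.rfft(w))
    freqs = np.fft.rfftfreq(len(w), 1.0 / audio.sample_rate)
    return freqs, spec


def _level_at(freqs, spec, f, half_width=5.0):
    band = (freqs > f - half_width) & (freqs < f + half_width)
    return spec[band].max()


@pytest.fixture(scope="module")
def flat_contour():
    t = np.linspace(0.0, 1.0, 201)
    return F0Contour(times=t, f0=np.full(201, 200.0),
                     syllable_intervals=[(0.0, 1.0)],
                     final_word_interval=(0.0, 1.0))


def test_speech_proxy_has_full_harmonic_stack(flat_contour):
    audio = render_speech_proxy(flat_contour)
    freqs, spec = _spectrum(audio)
    fund = _level_at(freqs, spec, 200.0)
    for h in range(2, 16):
        # all harmonics present, rolling off roughly as 1/n
        assert _level_at(freqs, spec, 200.0 * h) > fund / (3.0 * h)


def test_speech_proxy_silent_outside_syllables():
    t = np.linspace(0.0, 1.0, 201)
    c = F0Contour(times=t, f0=np.full(201, 200.0),
                  syllable_intervals=[(0.2, 0.5)])
    audio = render_speech_proxy(c)
    sr = audio.sample_rate
    assert np.all(audio.samples[: int(0.19 * sr)] == 0)
    assert np.all(audio.samples[int(0.51 * sr):] == 0)
    assert audio.peak() > 0.1


def test_speech_proxy_nyquist_guard(flat_contour):
    with pytest.raises(ValueError):
        render_speech_proxy(flat_contour, sample_rate=4000)


def test_musical_analogue_has_only_odd_harmonics(flat_contour):
    audio = render_musical_analogue(flat_contour)
    freqs, spec = _spectrum(audio)
    fund = _level_at(freqs, spec, 200.0)
    overtones = 0
    for h in range(2, 16):
        level = _level_at(freqs, spec, 200.0 * h)
        if h % 2 == 1:
            overtones += 1
            assert level > fund / 100.0
        else:
            db_down = 20 * np.log10(fund / level)
            assert db_down >= 40.0
    assert overtones == 7


def test_render_round_trip_recovers_contour():
    from prosodim.acoustics import extract_f0
    c = make_glide_contour(500.0, 6.0, "up", 0.6)
    tracked = extract_f0(render_speech_proxy(c))
    voiced = tracked.voiced_mask()
    # compare to the true instantaneous F0 at the voiced frame centres,
    # excluding onset/offset ramps
    inner = voiced & (tracked.times > 0.05) & (tracked.times < 0.55)
    truth = np.interp(tracked.times[inner], c.times, c.f0)
    assert np.max(np.abs(tracked.f0[inner] - truth)) < 2.0


def test_normalize_peak_matches_reference(flat_contour):
    audio = render_speech_proxy(flat_contour)
    ref = AudioBuffer(samples=audio.samples * 0.5 / audio.peak(),
                      sample_rate=audio.sample_rate)
    out = normalize_peak(audio, ref)
    assert out.peak() == pytest.approx(0.5, rel=1e-6)
    # idempotence
    again = normalize_peak(out, ref)
    assert np.allclose(again.samples, out.samples, rtol=1e-6)
    # scaling preserves spectral shape
    f1, s1 = _spectrum(out)
    f2, s2 = _spectrum(audio)
    assert np.allclose(s1 / s1.max(), s2 / s2.max(), atol=1e-9)


def test_normalize_peak_rejects_silent_reference():
    silent = AudioBuffer(samples=np.zeros(100), sample_rate=22050)
    loud = AudioBuffer(samples=np.ones(100) * 0.5, sample_rate=22050)
    with pytest.raises(ValueError):
        normalize_peak(loud, silent)


# ---------------------------------------------------------------- trial lists

def test_discrimination_block_counts(pair_set, rng):
    tl = build_discrimination_trials(pair_set, "speech", rng)
    assert len(tl) == 36
    counts = tl.truth_counts()
    assert counts == {"same": 18, "different": 18}
    # same trials balanced between statement-same and question-same
    same_types = [t.stimuli[0].sentence_type for t in tl.trials if t.truth == "same"]
    assert same_types.count("statement") == 9
    assert tl.isi_ms == 750 and tl.iti_ms == 2000


def test_single_pair_discrimination(rng):
    pairs = default_utterance_pairs(1, rng)
    tl = build_discrimination_trials(pairs, "music", rng, strict_balance=False)
    assert len(tl) == 2


def test_odd_pair_count_rejected_under_strict_balance(rng):
    pairs = default_utterance_pairs(3, rng)
    with pytest.raises(ValueError):
        build_discrimination_trials(pairs, "speech", rng)


def test_trial_order_deterministic_under_seed(pair_set):
    a = build_discrimination_trials(pair_set, "speech", np.random.default_rng(5))
    b = build_discrimination_trials(pair_set, "speech", np.random.default_rng(5))
    assert [t.pair_id for t in a.trials] == [t.pair_id for t in b.trials]
    assert [t.truth for t in a.trials] == [t.truth for t in b.trials]


def test_identification_block_complete_and_balanced(pair_set, rng):
    tl = build_identification_trials(pair_set, rng)
    assert len(tl) == 36
    assert tl.truth_counts() == {"statement": 18, "question": 18}
    # every pair contributes exactly one statement and one question
    for pid in {t.pair_id for t in tl.trials}:
        labels = sorted(t.truth for t in tl.trials if t.pair_id == pid)
        assert labels == ["question", "statement"]


# ---------------------------------------------------------------- WAV I/O

@pytest.mark.parametrize("subtype,tol", [("float32", 1e-6), ("pcm16", 2 ** -15)])
def test_wav_round_trip(tmp_path, flat_contour, subtype, tol):
    audio = render_speech_proxy(flat_contour)
    path = tmp_path / "tone.wav"
    write_wav(audio, path, subtype=subtype)
    back = read_wav(path)
    assert back.sample_rate == audio.sample_rate
    assert np.max(np.abs(back.samples - audio.samples)) <= tol + 1e-9


def test_read_non_wav_raises(tmp_path):
    path = tmp_path / "notwav.wav"
    path.write_text("this is not audio")
    with pytest.raises(IOError):
        read_wav(path)
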