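"""Stimulus synthesis: ladder arithmetic, tones, vowels, filtering, WAV I/O."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from pitchstdp import stimuli
from pitchstdp.stimuli import (
    VowelSpec,
    Waveform,
    read_wav,
    semitone_ladder,
    set_level,
    synth_pure_tone,
    synth_vowel,
    telephone_filter,
    write_wav,
)


class TestSemitoneLadder:
    @pytest.mark.parametrize(
        "f_low,f_high,expected_len",
        [(98.0, 493.0, 29), (440.0, 440.0, 1), (98.0, 196.0, 13)],
    )
    def test_note_counts(self, f_low, f_high, expected_len):
        assert len(semitone_ladder(f_low, f_high)) == expected_len

    def test_octave_endpoint_exact(self):
        assert semitone_ladder(98.0, 196.0)[-1] == pytest.approx(196.0, abs=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            semitone_ladder(0.0, 493.0)

    @given(
        f_low=st.floats(20.0, 2000.0),
        n_semitones=st.integers(0, 48),
    )
    @settings(max_examples=50, deadline=None)
    def test_constant_log_spacing(self, f_low, n_semitones):
        f_high = f_low * 2.0 ** (n_semitones / 12.0)
        freqs = np.array(list(semitone_ladder(f_low, f_high)))
        assert freqs.size == n_semitones + 1
        if freqs.size > 1:
            ratios = freqs[1:] / freqs[:-1]
            assert np.allclose(ratios, 2.0 ** (1 / 12.0), rtol=1e-9)


class TestPureTone:
    def test_paper_format(self):
        w = synth_pure_tone(110.0)
        assert w.samples.size == 8000
        assert w.rate == 16000
        assert w.samples[0] == pytest.approx(0.0, abs=1e-12)  # zero phase at onset

    def test_spectral_peak_at_frequency(self):
        w = synth_pure_tone(110.0)
        spec = np.abs(np.fft.rfft(w.samples))
        freqs = np.fft.rfftfreq(w.samples.size, 1 / w.rate)
        assert freqs[np.argmax(spec)] == pytest.approx(110.0, abs=freqs[1])

    def test_integer_period_count(self):
        # 110 Hz x 0.5 s = exactly 55 periods: the signal returns to zero phase
        w = synth_pure_tone(110.0)
        up_crossings = np.sum((w.samples[:-1] <= 0) & (w.samples[1:] > 0))
        assert up_crossings == 55

    def test_zero_duration(self):
        assert synth_pure_tone(110.0, duration=0.0).samples.size == 0

    def test_rejects_nyquist(self):
        with pytest.raises(ValueError):
            synth_pure_tone(8000.0)


class TestVowel:
    def test_periodicity_at_f0(self):
        w = stimuli.vowel_a(110.0)
        x = w.samples - w.samples.mean()
        ac = np.correlate(x, x, "full")[x.size - 1 :]
        lag = np.argmax(ac[80:220]) + 80  # search around the 145-sample period
        assert abs(lag - w.rate / 110.0) <= 1.0

    def test_spectral_peaks_at_formants(self):
        w = stimuli.vowel_a(110.0)
        spec = np.abs(np.fft.rfft(w.samples)) ** 2
        freqs = np.fft.rfftfreq(w.samples.size, 1 / w.rate)
        for target in (710.0, 1150.0):
            # local maximum of the envelope of harmonics near the formant:
            # the strongest harmonic within +-150 Hz should be within one
            # harmonic spacing (110 Hz) of the formant center
            window = (freqs > target - 150) & (freqs < target + 150)
            peak = freqs[window][np.argmax(spec[window])]
            assert abs(peak - target) <= 110.0

    def test_no_formants_gives_impulse_train(self):
        w = synth_vowel(VowelSpec(100.0, ()), duration=0.1, rate=16000, level_db_spl=None)
        nonzero = np.flatnonzero(w.samples)
        assert np.array_equal(nonzero, np.round(np.arange(10) * 160).astype(int))

    def test_rejects_formant_at_nyquist(self):
        with pytest.raises(ValueError):
            synth_vowel(VowelSpec(110.0, ((8000.0, 100.0),)))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            VowelSpec(110.0, ((710.0, 40.0), (500.0, 43.0)))  # not increasing
        with pytest.raises(ValueError):
            VowelSpec(-1.0, ())


class TestTelephoneFilter:
    def test_frequency_response_meets_spec(self):
        taps = stimuli.telephone_taps()
        freqs, h = signal.freqz(taps, worN=16384, fs=16000)
        assert 20 * np.log10(np.max(np.abs(h[freqs <= 300]))) <= -80.0
        passband = np.abs(h[freqs >= 350])
        assert 20 * np.log10(passband.max()) <= 1.0
        assert 20 * np.log10(passband.min()) >= -1.0

    def test_stopband_tone_suppressed(self):
        w = synth_pure_tone(110.0)
        y = telephone_filter(w)
        # steady-state portion (away from onset/offset transients)
        sl = slice(2000, 6000)
        atten = np.sqrt(np.mean(y.samples[sl] ** 2)) / np.sqrt(np.mean(w.samples[sl] ** 2))
        assert 20 * np.log10(atten) <= -80.0

    def test_passband_tone_preserved(self):
        w = synth_pure_tone(1000.0)
        y = telephone_filter(w)
        assert abs(20 * np.log10(y.rms / w.rms)) <= 1.0

    def test_zero_in_zero_out(self):
        w = Waveform(np.zeros(8000))
        assert np.array_equal(telephone_filter(w).samples, np.zeros(8000))

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = Waveform(rng.normal(size=4000))
        y = Waveform(rng.normal(size=4000))
        lhs = telephone_filter(Waveform(2.0 * x.samples + 3.0 * y.samples)).samples
        rhs = 2.0 * telephone_filter(x).samples + 3.0 * telephone_filter(y).samples
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_preserves_length(self):
        assert telephone_filter(synth_pure_tone(440.0)).samples.size == 8000

    def test_rejects_other_rates(self):
        with pytest.raises(ValueError):
            telephone_filter(Waveform(np.ones(100), rate=44100))


class TestLevelCalibration:
    def test_target_level_reached(self):
        w = set_level(synth_pure_tone(200.0, level_db_spl=None), 60.0)
        assert w.measured_db_spl() == pytest.approx(60.0, abs=1e-9)

    def test_20_db_is_factor_10_in_rms(self):
        w = synth_pure_tone(200.0, level_db_spl=None)
        assert set_level(w, 80.0).rms / set_level(w, 60.0).rms == pytest.approx(10.0)

    def test_full_scale_convention(self):
        # amplitude-1 sinusoid sits at the 94 dB SPL anchor
        w = Waveform(np.sin(2 * np.pi * 200 * np.arange(8000) / 16000))
        assert w.measured_db_spl() == pytest.approx(94.0, abs=0.01)

    def test_silent_input_rejected(self):
        with pytest.raises(ValueError):
            set_level(Waveform(np.zeros(100)), 60.0)


class TestWavIO:
    def test_round_trip(self, tmp_path):
        w = synth_pure_tone(220.0)
        path = tmp_path / "tone.wav"
        write_wav(w, path)
        back = read_wav(path)
        assert back.rate == 16000
        assert np.max(np.abs(back.samples - w.samples)) <= 2 ** -20

    def test_stereo_reduced_to_first_channel(self, tmp_path):
        from scipy.io import wavfile

        rng = np.random.default_rng(1)
        data = rng.normal(size=(1000, 2)).astype(np.float32)
        path = tmp_path / "stereo.wav"
        wavfile.write(str(path), 16000, data)
        back = read_wav(path)
        assert back.samples.size == 1000
        assert np.allclose(back.samples, data[:, 0], atol=1e-7)

    def test_resampled_to_16k(self, tmp_path):
        from scipy.io import wavfile

        rate_in = 44100
        t = np.arange(int(0.25 * rate_in)) / rate_in
        path = tmp_path / "hi.wav"
        wavfile.write(str(path), rate_in, np.sin(2 * np.pi * 440 * t).astype(np.float32))
        back = read_wav(path)
        assert back.rate == 16000
        assert abs(back.duration - 0.25) <= 1.0 / 16000

    def test_missing_file(self, tmp_path):
        with pytest.raises(IOError):
            read_wav(tmp_path / "nope.wav")


def test_full_stimulus_set_counts_and_format():
    sets = stimuli.paper_stimulus_set()
    assert len(sets["tone"]) == 29
    assert len(sets["vowel"]) == 58
    assert len(sets["telephone_vowel"]) == 58
    for group in sets.values():
        for w in group:
            assert w.samples.size == 8000
            assert w.rate == 16000
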