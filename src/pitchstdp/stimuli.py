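"""Stimulus synthesis and WAV handling.

All built-in stimuli follow one convention: mono, 16 kHz, 0.5 s, calibrated
to 60 dB SPL under the full-scale convention below.  The stimulus set
consists of pure tones on an equal-tempered semitone ladder spanning
G2-B4 (98-493 Hz, 29 notes), two cascade-formant vowels (/a/ and /i/),
and "telephone" variants of the vowels produced by a sharp high-pass
filter that removes the fundamental-frequency region (< 300 Hz).
"""
from __future__ import annotations

import dataclasses
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.io import wavfile

PAPER_RATE = 16_000
"""Sampling rate (samples/s) shared by every built-in stimulus."""

PAPER_DURATION = 0.5
"""Duration (s) of every built-in stimulus."""

PAPER_LEVEL_DB_SPL = 60.0
"""Calibrated loudness of every built-in stimulus."""

FULL_SCALE_SINE_DB_SPL = 94.0
# Pressure reference: a full-scale (amplitude 1.0) sinusoid is defined to be
# 94 dB SPL, i.e. digital 1.0 corresponds to ~1 Pa RMS/sqrt(2).  The absolute
# anchor is arbitrary -- downstream spike-rate calibration absorbs it -- but
# it is fixed here so that "60 dB SPL" is a single well-defined amplitude.
_RMS_REF = (1.0 / np.sqrt(2.0)) * 10.0 ** (-FULL_SCALE_SINE_DB_SPL / 20.0)

LADDER_LOW_HZ = 98.0
LADDER_HIGH_HZ = 493.0

#: (center Hz, bandwidth Hz) of the first three formants.
VOWEL_A_FORMANTS = ((710.0, 40.0), (1150.0, 43.0), (2700.0, 105.0))
VOWEL_I_FORMANTS = ((230.0, 68.0), (2000.0, 63.0), (3000.0, 129.0))


@dataclasses.dataclass
class Waveform:
    """A sampled pressure signal with rate and level metadata."""

    samples: np.ndarray
    rate: int = PAPER_RATE
    level_db_spl: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("Waveform samples must be finite")
        if self.rate <= 0:
            raise ValueError("Sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def rms(self) -> float:
        if self.samples.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))

    def measured_db_spl(self) -> float:
        """Level implied by the RMS under the full-scale convention."""
        rms = self.rms
        if rms == 0.0:
            raise ValueError("silent waveform has no defined level")
        return 20.0 * np.log10(rms / _RMS_REF)


@dataclasses.dataclass(frozen=True)
class VowelSpec:
    """Fundamental frequency plus cascade formant resonators."""

    f0: float
    formants: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        centers = [c for c, _ in self.formants]
        if any(b <= 0 for _, b in self.formants):
            raise ValueError("formant bandwidths must be positive")
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("formant centers must be strictly increasing")


@dataclasses.dataclass(frozen=True)
class PitchLadder:
    """Ascending, equal-tempered list of fundamental frequencies."""

    frequencies: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.frequencies)

    def __iter__(self):
        return iter(self.frequencies)

    def __getitem__(self, i):
        return self.frequencies[i]


def semitone_ladder(f_low: float = LADDER_LOW_HZ, f_high: float = LADDER_HIGH_HZ) -> PitchLadder:
    """Equal-tempered ladder from ``f_low`` up, one semitone per step.

    The number of steps is ``round(12*log2(f_high/f_low))`` so a nominal
    range of [98, 493] Hz yields the 29 notes G2-B4 even though
    98*2^(28/12) = 493.88 Hz slightly exceeds the nominal upper edge.
    """
    if f_low <= 0 or f_high <= 0:
        raise ValueError("frequencies must be positive")
    if f_high < f_low:
        raise ValueError("f_high must be >= f_low")
    n_steps = int(round(12.0 * np.log2(f_high / f_low)))
    freqs = tuple(float(f_low * 2.0 ** (k / 12.0)) for k in range(n_steps + 1))
    return PitchLadder(freqs)


def set_level(w: Waveform, target_db_spl: float) -> Waveform:
    """Rescale so the RMS corresponds to ``target_db_spl``."""
    rms = w.rms
    if rms == 0.0:
        raise ValueError("cannot calibrate a silent waveform")
    target_rms = _RMS_REF * 10.0 ** (target_db_spl / 20.0)
    return Waveform(
        samples=w.samples * (target_rms / rms),
        rate=w.rate,
        level_db_spl=target_db_spl,
        label=w.label,
    )


def synth_pure_tone(
    freq: float,
    duration: float = PAPER_DURATION,
    rate: int = PAPER_RATE,
    level_db_spl: float | None = PAPER_LEVEL_DB_SPL,
) -> Waveform:
    """Zero-phase sinusoid ``sin(2*pi*freq*t)``, level-calibrated."""
    if freq <= 0:
        raise ValueError("frequency must be positive")
    if freq >= rate / 2:
        raise ValueError(f"frequency {freq} Hz is at or above Nyquist ({rate / 2} Hz)")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    w = Waveform(np.sin(2.0 * np.pi * freq * t), rate=rate, label=f"tone_{freq:g}Hz")
    if level_db_spl is not None and n > 0:
        w = set_level(w, level_db_spl)
    return w


def _resonator_coefficients(center: float, bandwidth: float, rate: int):
    # Klatt-style digital resonator: y[n] = B x[n] + C y[n-1] + D y[n-2]
    # with unity gain at DC.
    T = 1.0 / rate
    D = -np.exp(-2.0 * np.pi * bandwidth * T)
    C = 2.0 * np.exp(-np.pi * bandwidth * T) * np.cos(2.0 * np.pi * center * T)
    B = 1.0 - C - D
    return np.array([B]), np.array([1.0, -C, -D])


def synth_vowel(
    spec: VowelSpec,
    duration: float = PAPER_DURATION,
    rate: int = PAPER_RATE,
    level_db_spl: float | None = PAPER_LEVEL_DB_SPL,
) -> Waveform:
    """Cascade-formant vowel: impulse train at f0 through 2nd-order resonators.

    Only the cascade branch of a formant synthesizer is modelled: a plain
    glottal impulse train (no source shaping, no amplitude ramp) filtered
    by one resonator per formant.  The output is periodic with period
    1/f0 and has spectral peaks at the formant centers.
    """
    nyquist = rate / 2
    if any(c >= nyquist for c, _ in spec.formants):
        raise ValueError("formant center at or above Nyquist")
    n = int(round(duration * rate))
    x = np.zeros(n)
    if n:
        pulse_idx = np.round(np.arange(0, duration * spec.f0) * rate / spec.f0).astype(int)
        pulse_idx = pulse_idx[pulse_idx < n]
        x[pulse_idx] = 1.0
    for center, bw in spec.formants:
        b, a = _resonator_coefficients(center, bw, rate)
        x = signal.lfilter(b, a, x)
    w = Waveform(x, rate=rate, label=f"vowel_f0={spec.f0:g}Hz")
    if level_db_spl is not None and n > 0 and w.rms > 0:
        w = set_level(w, level_db_spl)
    return w


def vowel_a(f0: float, **kwargs) -> Waveform:
    w = synth_vowel(VowelSpec(f0, VOWEL_A_FORMANTS), **kwargs)
    w.label = f"vowel_a_f0={f0:g}Hz"
    return w


def vowel_i(f0: float, **kwargs) -> Waveform:
    w = synth_vowel(VowelSpec(f0, VOWEL_I_FORMANTS), **kwargs)
    w.label = f"vowel_i_f0={f0:g}Hz"
    return w


# --- Telephone-line (high-pass) filter ------------------------------------

TELEPHONE_FSTOP_HZ = 300.0
TELEPHONE_FPASS_HZ = 350.0
TELEPHONE_ASTOP_DB = 80.0
TELEPHONE_APASS_DB = 1.0
# A 50 Hz transition with 80 dB stopband needs on the order of 1600 taps
# at 16 kHz (Kaiser estimate); the Kaiser-window design below meets the
# stopband/passband spec with a comfortable margin in the passband.
TELEPHONE_NUMTAPS = 1641

_telephone_taps_cache: dict[tuple[int, int], np.ndarray] = {}


def telephone_taps(rate: int = PAPER_RATE, numtaps: int = TELEPHONE_NUMTAPS) -> np.ndarray:
    """High-pass FIR taps for the telephone-line simulation.

    Kaiser-window design sized for >= 80 dB attenuation below 300 Hz and
    <= 1 dB ripple above 350 Hz.
    """
    key = (rate, numtaps)
    if key not in _telephone_taps_cache:
        _, beta = signal.kaiserord(
            TELEPHONE_ASTOP_DB, (TELEPHONE_FPASS_HZ - TELEPHONE_FSTOP_HZ) / (rate / 2.0)
        )
        taps = signal.firwin(
            numtaps | 1,  # odd length -> integer group delay, type-I high-pass
            0.5 * (TELEPHONE_FSTOP_HZ + TELEPHONE_FPASS_HZ),
            window=("kaiser", beta),
            pass_zero=False,
            fs=rate,
        )
        _telephone_taps_cache[key] = taps
    return _telephone_taps_cache[key]


def telephone_filter(w: Waveform, numtaps: int = TELEPHONE_NUMTAPS) -> Waveform:
    """High-pass the waveform through the telephone-line FIR, zero phase.

    The linear-phase FIR is applied once and its constant group delay
    ((numtaps-1)/2 samples) removed, so filtered and unfiltered stimuli
    stay sample-aligned and can be compared channel by channel downstream.
    """
    if w.rate != PAPER_RATE:
        raise ValueError(f"telephone filter is designed for {PAPER_RATE} Hz input")
    taps = telephone_taps(w.rate, numtaps)
    delay = (taps.size - 1) // 2
    padded = np.concatenate([w.samples, np.zeros(delay)])
    y = signal.lfilter(taps, 1.0, padded)[delay:]
    return Waveform(y, rate=w.rate, level_db_spl=None, label=w.label + "_tel")


# --- WAV I/O ---------------------------------------------------------------

def write_wav(w: Waveform, path: str | Path) -> None:
    """Write as 32-bit float WAV."""
    wavfile.write(str(path), w.rate, w.samples.astype(np.float32))


def read_wav(path: str | Path, target_rate: int = PAPER_RATE) -> Waveform:
    """Read a WAV file as a mono waveform at ``target_rate``.

    Multi-channel input is reduced to the first channel; integer PCM is
    scaled to [-1, 1]; other sampling rates are polyphase-resampled.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except (OSError, ValueError) as exc:
        raise IOError(f"could not read WAV file {path}: {exc}") from exc
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(float)
    if rate != target_rate:
        frac = Fraction(target_rate, rate).limit_denominator(10_000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator)
    return Waveform(data, rate=target_rate, label=path.stem)


# --- The full built-in stimulus set ---------------------------------------

def paper_stimulus_set() -> dict[str, list[Waveform]]:
    """Synthesize the complete built-in set, keyed by stimulus type.

    Returns 29 pure tones, 58 vowels (/a/ and /i/ at every ladder pitch)
    and their 58 high-pass-filtered "telephone" variants.
    """
    ladder = semitone_ladder()
    tones = [synth_pure_tone(f) for f in ladder]
    vowels = [vowel_a(f) for f in ladder] + [vowel_i(f) for f in ladder]
    telephone = [telephone_filter(v) for v in vowels]
    return {"tone": tones, "vowel": vowels, "telephone_vowel": telephone}
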