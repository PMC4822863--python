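"""Phase I: auditory periphery.

A waveform is turned into a 200-channel spatio-temporal activity map:
middle-ear band-pass, a bank of fourth-order gammatone filters placed at
Greenwood characteristic frequencies over cochlear positions 3-22.9 mm
(0.1 mm steps), and an inner-hair-cell stage (half-wave rectification
followed by a 1 kHz low-pass).  Averaging each channel over time yields
the place code of pitch.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .stimuli import Waveform

GREENWOOD_A = 165.4
GREENWOOD_EXP = 2.1 / 34.0

N_CHANNELS = 200
POSITION_MIN_MM = 3.0
POSITION_STEP_MM = 0.1

MIDDLE_EAR_BAND_HZ = (100.0, 6000.0)
IHC_CUTOFF_HZ = 1000.0
PLACE_WINDOW_MS = 100.0
PLACE_ONSET_SKIP_MS = 50.0


def greenwood_cf(d_mm):
    """Greenwood frequency-position map: CF(d) = 165.4*(10^(2.1 d/34) - 1).

    ``d_mm`` is distance from the cochlear apex in millimetres; scalar or
    array.  CF(3.0) is ~88 Hz and CF(22.9) ~4.1 kHz.
    """
    d = np.asarray(d_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("cochlear position must be non-negative")
    cf = GREENWOOD_A * (10.0 ** (GREENWOOD_EXP * d) - 1.0)
    return float(cf) if np.isscalar(d_mm) else cf


@dataclasses.dataclass(frozen=True)
class CochlearMap:
    """Tonotopic map: cochlear positions and their Greenwood CFs."""

    positions_mm: np.ndarray
    cfs_hz: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.positions_mm.size


def build_cochlear_map(
    n_channels: int = N_CHANNELS,
    d_min_mm: float = POSITION_MIN_MM,
    step_mm: float = POSITION_STEP_MM,
) -> CochlearMap:
    positions = d_min_mm + step_mm * np.arange(n_channels)
    return CochlearMap(positions_mm=positions, cfs_hz=greenwood_cf(positions))


@dataclasses.dataclass
class SpatioTemporalMap:
    """Channels x time matrix of instantaneous IHC activity (arbitrary units)."""

    activity: np.ndarray  # (n_channels, n_samples), >= 0
    rate: int
    cmap: CochlearMap

    @property
    def duration(self) -> float:
        return self.activity.shape[1] / self.rate


@dataclasses.dataclass
class PlaceCode:
    """Normalized per-channel mean activity (the place code of pitch)."""

    rates: np.ndarray  # (n_channels,), max 1 unless all-zero
    cmap: CochlearMap


_middle_ear_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_gammatone_cache: dict[tuple[int, int], list[tuple[np.ndarray, np.ndarray]]] = {}
_ihc_lp_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _middle_ear_sos(rate: int):
    if rate not in _middle_ear_cache:
        _middle_ear_cache[rate] = signal.butter(
            1, MIDDLE_EAR_BAND_HZ, btype="bandpass", fs=rate, output="sos"
        )
    return _middle_ear_cache[rate]


def _gammatone_bank(cmap: CochlearMap, rate: int):
    key = (rate, id(cmap))
    if key not in _gammatone_cache:
        _gammatone_cache[key] = [
            signal.gammatone(cf, "iir", fs=rate) for cf in cmap.cfs_hz
        ]
    return _gammatone_cache[key]


def _ihc_lowpass_sos(rate: int):
    if rate not in _ihc_lp_cache:
        _ihc_lp_cache[rate] = signal.butter(2, IHC_CUTOFF_HZ, fs=rate, output="sos")
    return _ihc_lp_cache[rate]


def spatiotemporal_map(w: Waveform, cmap: CochlearMap | None = None) -> SpatioTemporalMap:
    """Map a waveform to per-channel IHC activity over time.

    Processing chain per channel: first-order middle-ear band-pass
    (0.1-6 kHz), fourth-order gammatone band-pass at the channel CF,
    half-wave rectification, second-order 1 kHz low-pass, clipped at zero.
    """
    if w.samples.size == 0:
        raise ValueError("cannot build a spatio-temporal map from an empty waveform")
    if cmap is None:
        cmap = build_cochlear_map()
    x = signal.sosfilt(_middle_ear_sos(w.rate), w.samples)
    lp = _ihc_lowpass_sos(w.rate)
    activity = np.empty((cmap.n_channels, x.size))
    for ch, (b, a) in enumerate(_gammatone_bank(cmap, w.rate)):
        y = signal.lfilter(b, a, x)
        y = np.maximum(y, 0.0)  # half-wave rectification
        y = signal.sosfilt(lp, y)
        activity[ch] = np.maximum(y, 0.0)
    return SpatioTemporalMap(activity=activity, rate=w.rate, cmap=cmap)


def channel_means(
    stm: SpatioTemporalMap,
    window_ms: float = PLACE_WINDOW_MS,
    skip_ms: float = PLACE_ONSET_SKIP_MS,
) -> np.ndarray:
    """Raw (un-normalized) per-channel temporal means over the analysis window.

    The first ``skip_ms`` are excluded to avoid filter onset transients.
    """
    n = stm.activity.shape[1]
    i0 = int(round(skip_ms * 1e-3 * stm.rate))
    i1 = i0 + int(round(window_ms * 1e-3 * stm.rate))
    if i1 > n:
        raise ValueError(
            f"analysis window ({skip_ms}+{window_ms} ms) exceeds map duration "
            f"({1e3 * stm.duration:.1f} ms)"
        )
    return stm.activity[:, i0:i1].mean(axis=1)


def place_code(
    stm: SpatioTemporalMap,
    window_ms: float = PLACE_WINDOW_MS,
    skip_ms: float = PLACE_ONSET_SKIP_MS,
) -> PlaceCode:
    """Per-channel mean activity over a 100 ms window, normalized to max 1."""
    means = channel_means(stm, window_ms=window_ms, skip_ms=skip_ms)
    peak = means.max()
    if peak > 0:
        means = means / peak
    return PlaceCode(rates=means, cmap=stm.cmap)


def dominant_peak_cf(code: PlaceCode, cf_max_hz: float | None = None) -> float:
    """CF of the largest place-code peak, optionally restricted below a cap."""
    rates = code.rates
    cfs = code.cmap.cfs_hz
    if cf_max_hz is not None:
        mask = cfs <= cf_max_hz
        rates, cfs = rates[mask], cfs[mask]
    if rates.size == 0 or rates.max() == 0:
        raise ValueError("place code has no activity in the requested range")
    return float(cfs[np.argmax(rates)])
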