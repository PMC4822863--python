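"""Temporal pitch-code extraction.

Two readouts quantify what training does to spike timing:

* vector strength -- resultant length of spike phases relative to the
  stimulus fundamental (1 = perfect phase locking, ~0 = random timing);
  arranged as a pitch-neuron x stimulus matrix it shows whether each
  neuron locks selectively to its own pitch category;
* pooled inter-spike-interval histograms (ISIH) -- first-order intervals
  pooled across the pitch-neuron population, binned at 1 ms up to 50 ms;
  the dominant (modal) interval is the temporal code of pitch and should
  sit at the stimulus period 1/F0.

Analysis intervals longer than the 0.5 s stimuli are realized by repeated
presentations with independent Poisson draws; spike times stay referenced
to their own presentation onset, so phases pool coherently and intervals
never span presentation gaps.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal

from .plasticity import TrainedModel
from .spikes import SpikeTrain
from .stimuli import Waveform

ISIH_BIN_MS = 1.0
ISIH_MAX_MS = 50.0
VS_INTERVAL_S = 5.0


def _as_seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


def vector_strength(train: SpikeTrain | np.ndarray, freq: float) -> float:
    """Goldberg-Brown resultant |sum_k exp(i 2 pi f t_k)| / N; 0 if no spikes.

    Phases are referenced to the presentation onset (t = 0).
    """
    if freq <= 0:
        raise ValueError("reference frequency must be positive")
    times = train.times_s if isinstance(train, SpikeTrain) else np.asarray(train, float)
    if times.size == 0:
        return 0.0
    phases = 2.0 * np.pi * freq * times
    return float(np.abs(np.mean(np.exp(1j * phases))))


@dataclasses.dataclass
class VSMatrix:
    """Vector strength of every pitch neuron for every stimulus."""

    values: np.ndarray  # (n_neurons, n_stimuli) in [0, 1]
    neuron_labels: np.ndarray  # pitch categories (Hz)
    stimulus_freqs: np.ndarray  # stimulus pitches (Hz)

    def diagonal_gap(self) -> float:
        """Mean of the matched (diagonal) entries minus the unmatched mean."""
        v = self.values
        n = min(v.shape)
        diag_mask = np.zeros_like(v, dtype=bool)
        for i in range(v.shape[0]):
            k = int(np.argmin(np.abs(self.stimulus_freqs - self.neuron_labels[i])))
            diag_mask[i, k] = True
        return float(v[diag_mask].mean() - v[~diag_mask].mean())


def present_repeated(
    model: TrainedModel, w: Waveform, n_reps: int, seed: int
) -> list[list[np.ndarray]]:
    """Repeated presentations; returns per-rep, per-neuron spike-time arrays."""
    seqs = _as_seedseq(seed).spawn(n_reps)
    out = []
    for r in range(n_reps):
        result = model.present(w, seqs[r])
        out.append([tr.times_s for tr in result.output_trains])
    return out


def vs_matrix(
    model: TrainedModel,
    stims: Sequence[Waveform],
    stim_freqs: Sequence[float],
    interval_s: float = VS_INTERVAL_S,
    seed: int = 0,
) -> VSMatrix:
    """Vector strength of each neuron's response to each stimulus.

    Entry (i, k) pools spike phases of neuron i across enough repeated
    presentations of stimulus k to fill ``interval_s``, evaluated at
    stimulus k's pitch frequency.
    """
    stim_freqs = np.asarray(stim_freqs, float)
    n_neurons = model.categories.size
    values = np.zeros((n_neurons, len(stims)))
    child = _as_seedseq(seed).spawn(len(stims))
    for k, w in enumerate(stims):
        duration = w.duration
        n_reps = max(1, int(round(interval_s / duration)))
        reps = present_repeated(model, w, n_reps, child[k])
        for i in range(n_neurons):
            pooled = np.concatenate([rep[i] for rep in reps])
            values[i, k] = vector_strength(pooled, stim_freqs[k])
    return VSMatrix(values, model.categories.copy(), stim_freqs)


# --- Inter-spike-interval histograms ---------------------------------------

@dataclasses.dataclass
class ISIH:
    """Pooled inter-spike-interval histogram over [0, 50] ms, 1 ms bins.

    ``counts`` are raw; ``smoothed`` is span-3 moving-averaged (reflection
    padding) and normalized to max 1.  Bin centers sit on integer
    milliseconds, so bin k collects intervals in [k - 0.5, k + 0.5) ms.
    """

    counts: np.ndarray
    smoothed: np.ndarray
    bin_centers_ms: np.ndarray
    pitch_label: float | None = None


def _smooth_span3(counts: np.ndarray) -> np.ndarray:
    padded = np.pad(counts.astype(float), 1, mode="reflect")
    sm = np.convolve(padded, np.ones(3) / 3.0, mode="valid")
    peak = sm.max()
    return sm / peak if peak > 0 else sm


def pooled_isih(
    trains: Sequence[SpikeTrain | np.ndarray],
    bin_ms: float = ISIH_BIN_MS,
    max_ms: float = ISIH_MAX_MS,
    order: str = "first",
    pitch_label: float | None = None,
) -> ISIH:
    """Pool inter-spike intervals across spike trains and bin them.

    ``order="first"`` uses consecutive intervals (the default);
    ``order="all"`` uses all-order intervals up to ``max_ms``.
    Each element of ``trains`` is treated as an independent train, so
    intervals never cross train (or presentation) boundaries.
    """
    if order not in ("first", "all"):
        raise ValueError("order must be 'first' or 'all'")
    intervals = []
    for tr in trains:
        t = tr.times_s if isinstance(tr, SpikeTrain) else np.asarray(tr, float)
        if t.size < 2:
            continue
        if order == "first":
            intervals.append(np.diff(t))
        else:
            d = t[None, :] - t[:, None]
            intervals.append(d[(d > 0) & (d <= max_ms * 1e-3)])
    all_ms = np.concatenate(intervals) * 1e3 if intervals else np.empty(0)
    n_bins = int(round(max_ms / bin_ms)) + 1
    centers = np.arange(n_bins) * bin_ms
    edges = np.concatenate([[-0.5 * bin_ms], centers + 0.5 * bin_ms])
    counts, _ = np.histogram(all_ms, bins=edges)
    return ISIH(
        counts=counts,
        smoothed=_smooth_span3(counts),
        bin_centers_ms=centers,
        pitch_label=pitch_label,
    )


def dominant_interval(h: ISIH) -> float:
    """Center (ms) of the maximal smoothed bin.

    Ties on the smoothed plateau (e.g. an isolated comb line spread over
    three bins by the moving average) are resolved by the raw counts;
    remaining ties go to the shorter interval.
    """
    if h.counts.sum() == 0:
        raise ValueError("empty histogram has no dominant interval")
    plateau = np.flatnonzero(h.smoothed >= h.smoothed.max() - 1e-12)
    best = plateau[np.argmax(h.counts[plateau])]
    return float(h.bin_centers_ms[best])


def peak_spacing_ms(h: ISIH, prominence: float = 0.1) -> float:
    """Median spacing between adjacent peaks of the smoothed histogram (ms)."""
    peaks, _ = sp_signal.find_peaks(h.smoothed, prominence=prominence)
    if peaks.size < 2:
        raise ValueError("histogram has fewer than two peaks")
    return float(np.median(np.diff(h.bin_centers_ms[peaks])))


@dataclasses.dataclass
class StackedISIH:
    """One pooled ISIH per pitch category, rows in ascending pitch order."""

    rows: list[ISIH]
    pitches_hz: np.ndarray

    def matrix(self) -> np.ndarray:
        return np.vstack([r.smoothed for r in self.rows])


def model_isih(
    model: TrainedModel,
    w: Waveform,
    n_reps: int = 4,
    seed: int = 0,
    order: str = "first",
    pitch_label: float | None = None,
) -> ISIH:
    """Pooled ISIH of the whole pitch-neuron population for one stimulus."""
    reps = present_repeated(model, w, n_reps, seed)
    flat = [times for rep in reps for times in rep]
    return pooled_isih(flat, order=order, pitch_label=pitch_label)


def stacked_isih(
    model: TrainedModel,
    stims: Sequence[Waveform],
    stim_freqs: Sequence[float],
    n_reps: int = 4,
    seed: int = 0,
    order: str = "first",
) -> StackedISIH:
    """Pooled ISIHs for a full stimulus set, stacked by ascending pitch."""
    stim_freqs = np.asarray(stim_freqs, float)
    if stim_freqs.size != len(stims):
        raise ValueError("need one pitch label per stimulus")
    idx = np.argsort(stim_freqs)
    child = _as_seedseq(seed).spawn(len(stims))
    rows = [
        model_isih(
            model,
            stims[k],
            n_reps=n_reps,
            seed=child[k],
            order=order,
            pitch_label=float(stim_freqs[k]),
        )
        for k in idx
    ]
    return StackedISIH(rows=rows, pitches_hz=stim_freqs[idx])
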