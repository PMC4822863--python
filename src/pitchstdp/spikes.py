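"""Auditory-nerve spike generation.

Each cochlear channel drives one afferent modelled as an inhomogeneous
Poisson process whose intensity is the channel's instantaneous IHC
activity.  The activity scale is arbitrary, so a single calibration
constant maps it to spikes/s: the map is rescaled so its global peak
equals ``peak_rate``.  No refractoriness is imposed here; refractory
dynamics live in the integrate-and-fire output neurons.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .periphery import SpatioTemporalMap

DEFAULT_PEAK_RATE = 1300.0
"""Peak instantaneous afferent rate (spikes/s).

Fixed once by a calibration sweep so that the untrained output layer
(uniform weights w0 = 0.0075) fires at roughly 80 spikes/s when driven by
a calibrated 60 dB SPL pure tone; see docs/methods.md.  Each channel is a
population intensity (the pooled rate of all fibers innervating one
cochlear place), not a single-fiber rate.
"""

DEFAULT_SPONT_RATIO = 0.2
"""Spontaneous rate of every afferent as a fraction of the peak rate.

Auditory-nerve fibers fire spontaneously (~50-100 spikes/s against
saturation rates of a few hundred, i.e. roughly a 1:5 ratio); the pooled
population intensity inherits that baseline.  The baseline matters for
learning: it is the unmodulated background out of which the plasticity
rule must select phase-consistent synapses, and without it the pre-post
correlations of a fully-driven channel overwhelm the homeostatic term.
"""


@dataclasses.dataclass
class RateEnvelope:
    """Per-channel instantaneous Poisson intensities (spikes/s)."""

    lambda_t: np.ndarray  # (n_channels, n_samples), >= 0
    rate: int  # samples/s of the envelope grid

    @property
    def duration(self) -> float:
        return self.lambda_t.shape[1] / self.rate

    @property
    def n_channels(self) -> int:
        return self.lambda_t.shape[0]


@dataclasses.dataclass
class SpikeTrain:
    """Sorted spike times of a single neuron."""

    times_s: np.ndarray
    neuron_id: int
    duration_s: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)

    @property
    def count(self) -> int:
        return self.times_s.size

    def rate(self) -> float:
        return self.count / self.duration_s if self.duration_s > 0 else 0.0


def calibrate_rates(
    stm: SpatioTemporalMap,
    peak_rate: float = DEFAULT_PEAK_RATE,
    spont_ratio: float = DEFAULT_SPONT_RATIO,
) -> RateEnvelope:
    """Map IHC activity to Poisson intensities with a spontaneous floor.

    The driven component is scaled by one common factor (preserving the
    relative structure across channels and over time) and sits on top of a
    constant spontaneous rate ``spont_ratio * peak_rate`` shared by every
    afferent, such that the global maximum equals ``peak_rate``.  With
    ``spont_ratio=0`` this reduces to pure proportional scaling.
    """
    if peak_rate <= 0:
        raise ValueError("peak_rate must be positive")
    if not 0 <= spont_ratio < 1:
        raise ValueError("spont_ratio must be in [0, 1)")
    peak = stm.activity.max()
    if peak <= 0:
        raise ValueError("cannot calibrate an all-zero spatio-temporal map")
    spont = spont_ratio * peak_rate
    lam = spont + stm.activity * ((peak_rate - spont) / peak)
    return RateEnvelope(lambda_t=lam, rate=stm.rate)


def poisson_spikes_from_lambda(
    lam: np.ndarray, rate: int, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson spike times for one piecewise-constant intensity.

    Thinning: candidate spikes are drawn from a homogeneous process at the
    channel's maximum intensity and accepted with probability
    ``lambda(t)/lambda_max``.  Exact for an intensity that is constant
    within each envelope sample.
    """
    lam = np.asarray(lam, dtype=float)
    duration = lam.size / rate
    lam_max = lam.max() if lam.size else 0.0
    if lam_max <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_max * duration)
    if n_cand == 0:
        return np.empty(0)
    t_cand = np.sort(rng.uniform(0.0, duration, n_cand))
    idx = np.minimum((t_cand * rate).astype(int), lam.size - 1)
    keep = rng.uniform(0.0, 1.0, n_cand) < lam[idx] / lam_max
    return t_cand[keep]


def poisson_spikes(env: RateEnvelope, seed: int, channel: int | None = None):
    """Draw spike trains from a rate envelope, reproducibly under ``seed``.

    Returns a single :class:`SpikeTrain` when ``channel`` is given,
    otherwise one train per channel.
    """
    rng = np.random.default_rng(seed)
    duration = env.duration
    if channel is not None:
        times = poisson_spikes_from_lambda(env.lambda_t[channel], env.rate, rng)
        return SpikeTrain(times, neuron_id=channel, duration_s=duration)
    return [
        SpikeTrain(
            poisson_spikes_from_lambda(env.lambda_t[j], env.rate, rng),
            neuron_id=j,
            duration_s=duration,
        )
        for j in range(env.n_channels)
    ]


# --- Event-file serialization (the contract with network/analysis) ---------

def write_events(trains: list[SpikeTrain], path) -> None:
    """Two-column delimited event file: neuron_id, time_s."""
    with open(path, "w") as fh:
        fh.write("neuron_id\ttime_s\n")
        for tr in trains:
            for t in tr.times_s:
                fh.write(f"{tr.neuron_id}\t{t:.9f}\n")


def read_events(path, duration_s: float) -> list[SpikeTrain]:
    ids, times = [], []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            i, t = line.split("\t")
            ids.append(int(i))
            times.append(float(t))
    ids = np.asarray(ids, dtype=int)
    times = np.asarray(times, dtype=float)
    out = []
    for j in np.unique(ids):
        out.append(SpikeTrain(np.sort(times[ids == j]), neuron_id=int(j), duration_s=duration_s))
    return out
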