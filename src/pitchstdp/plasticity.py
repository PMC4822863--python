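"""Asymmetric STDP rule and the pitch-neuron training schedules.

The learning window is exponentially decaying on both sides with a wider,
stronger depression lobe:

    W(s) =  A_p exp(-s/tau_p)   for s > 0   (pre before post: potentiation)
         = -A_d exp(+s/tau_d)   for s < 0   (post before pre: depression)

with s = t_post - t_pre and integral A_p tau_p - A_d tau_d = -0.035 s.
A weight update accumulates W over all spike pairs and subtracts a
homeostatic term b_j = nu_bar * integral(W) per pre-synaptic spike, which
pins the trained output rate near nu_bar = 30 spikes/s.

Training is presentation-based: each pitch neuron is repeatedly driven by
0.5 s stimuli of its own pitch category with fresh Poisson draws, and its
weight row is updated (and clipped to bounds) between presentations.  The
learning rate eta and learning time T can be jointly rescaled
(eta * k, T / k) with an unchanged eta*T product; this "desk-scale" mode
is the default because the nominal T = 5000 s per category is far into
the slow-learning regime.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import stimuli
from .network import (
    DEFAULT_DT,
    LIFParams,
    LIFState,
    SimResult,
    WeightMatrix,
    W_INIT,
    run_segment,
    simulate,
)
from .periphery import CochlearMap, build_cochlear_map, spatiotemporal_map
from .spikes import DEFAULT_PEAK_RATE, RateEnvelope, SpikeTrain, calibrate_rates, poisson_spikes
from .stimuli import Waveform


@dataclasses.dataclass(frozen=True)
class STDPParams:
    """Learning-window, homeostasis and schedule constants."""

    a_p: float = 15.0
    tau_p: float = 1e-3
    a_d: float = 10.0
    tau_d: float = 5e-3
    eta: float = 1e-7
    nu_bar: float = 30.0
    w_0: float = W_INIT
    w_min: float = -0.2
    w_max: float = 0.2
    t_learn: float = 5000.0

    def __post_init__(self) -> None:
        if min(self.a_p, self.a_d, self.tau_p, self.tau_d) <= 0:
            raise ValueError("window gains and time constants must be positive")
        if self.window_integral >= 0:
            raise ValueError("learning window must be net depressing")

    @property
    def window_integral(self) -> float:
        """Closed form: integral of W over all lags = A_p tau_p - A_d tau_d (s)."""
        return self.a_p * self.tau_p - self.a_d * self.tau_d

    @property
    def b_j(self) -> float:
        """Homeostatic coefficient nu_bar * integral(W)."""
        return self.nu_bar * self.window_integral

    @property
    def pair_cutoff(self) -> float:
        """Truncation of the pair sum: |s| beyond 7 max(tau) contributes < 1e-3."""
        return 7.0 * max(self.tau_p, self.tau_d)


def stdp_window(s, p: STDPParams = STDPParams()):
    """Evaluate the learning window at lag(s) s = t_post - t_pre (seconds)."""
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    pos = s > 0
    neg = s < 0
    out[pos] = p.a_p * np.exp(-s[pos] / p.tau_p)
    out[neg] = -p.a_d * np.exp(s[neg] / p.tau_d)
    return float(out) if out.ndim == 0 else out


def _pair_window_sums(
    pre_times: np.ndarray,
    pre_syn: np.ndarray,
    n_syn: int,
    post_times: np.ndarray,
    p: STDPParams,
) -> np.ndarray:
    """Sum of W(t_post - t_pre) over all pairs within the truncation window.

    ``pre_times`` must be globally sorted with ``pre_syn`` giving the synapse
    index of each pre spike.  Returns one sum per synapse.
    """
    sums = np.zeros(n_syn)
    if pre_times.size == 0 or post_times.size == 0:
        return sums
    cutoff = p.pair_cutoff
    lo = np.searchsorted(pre_times, post_times - cutoff, side="left")
    hi = np.searchsorted(pre_times, post_times + cutoff, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return sums
    # flat index into pre_times for every (post, pre) pair in range
    starts = np.repeat(np.cumsum(counts) - counts, counts)
    flat = np.arange(total) - starts + np.repeat(lo, counts)
    s = np.repeat(post_times, counts) - pre_times[flat]
    w = stdp_window(s, p)
    np.add.at(sums, pre_syn[flat], w)
    return sums


def stdp_delta(
    pre: SpikeTrain | np.ndarray,
    post: SpikeTrain | np.ndarray,
    p: STDPParams = STDPParams(),
    eta_scale: float = 1.0,
) -> float:
    """Weight change for one synapse from one pre and one post spike train.

    Implements the batch rule: eta * (sum over pairs of W(t_post - t_pre)
    - b_j * N_pre), with the pair sum truncated at |s| > 7 max(tau).
    """
    pre_t = pre.times_s if isinstance(pre, SpikeTrain) else np.asarray(pre, float)
    post_t = post.times_s if isinstance(post, SpikeTrain) else np.asarray(post, float)
    pair_sum = _pair_window_sums(pre_t, np.zeros(pre_t.size, dtype=int), 1, post_t, p)[0]
    return float(p.eta * eta_scale * (pair_sum - p.b_j * pre_t.size))


def stdp_delta_row(
    pre_trains: Sequence[np.ndarray],
    post_times: np.ndarray,
    p: STDPParams,
    eta_scale: float = 1.0,
) -> np.ndarray:
    """Per-synapse weight changes for a whole afferent population at once."""
    n_syn = len(pre_trains)
    sizes = np.array([t.size for t in pre_trains])
    if sizes.sum() == 0:
        return np.zeros(n_syn)
    pre_all = np.concatenate([np.asarray(t, float) for t in pre_trains])
    syn_all = np.repeat(np.arange(n_syn), sizes)
    order = np.argsort(pre_all, kind="stable")
    pair_sums = _pair_window_sums(pre_all[order], syn_all[order], n_syn, post_times, p)
    return p.eta * eta_scale * (pair_sums - p.b_j * sizes)


def rate_based_delta(nu_i: float, nu_j: float, alpha: float, nu_bar: float = 30.0) -> float:
    """Mean-field reduction of the pair rule: delta_w = alpha (nu_i - nu_bar) nu_j.

    With alpha = eta * T * integral(W) this is the expected pair-rule update
    for independent Poisson pre/post trains; it is used as the oracle for
    :func:`stdp_delta` and explains the homeostatic fixed point nu_i = nu_bar.
    """
    if nu_i < 0 or nu_j < 0:
        raise ValueError("rates must be non-negative")
    return alpha * (nu_i - nu_bar) * nu_j


# --- Training schedules -----------------------------------------------------

_STIMULUS_MAKERS: dict[str, list[Callable[[float], Waveform]]] = {
    "tone": [stimuli.synth_pure_tone],
    "vowel_a": [stimuli.vowel_a],
    "vowel_i": [stimuli.vowel_i],
    "vowel": [stimuli.vowel_a, stimuli.vowel_i],
    "telephone_vowel": [
        lambda f: stimuli.telephone_filter(stimuli.vowel_a(f)),
        lambda f: stimuli.telephone_filter(stimuli.vowel_i(f)),
    ],
}

MIXABLE_TYPES = ("tone", "vowel_a", "vowel_i")


@dataclasses.dataclass
class TrainingSchedule:
    """Which stimuli drive which pitch category, and for how long."""

    mode: str  # "single-type" | "mixed-type"
    categories: np.ndarray  # pitch labels (Hz), ascending
    pools: dict[float, list[Waveform]]
    n_presentations: int
    seed: int

    def __post_init__(self) -> None:
        self.categories = np.asarray(self.categories, dtype=float)
        missing = [f for f in self.categories if f not in self.pools or not self.pools[f]]
        if missing:
            raise ValueError(f"schedule is missing stimuli for categories: {missing}")


def presentations_for(p: STDPParams, eta_scale: float, duration: float = 0.5) -> int:
    """Presentation count equivalent to learning time T/eta_scale."""
    return max(1, int(round(p.t_learn / (eta_scale * duration))))


def single_type_schedule(
    stim_type: str,
    categories: Sequence[float],
    n_presentations: int,
    seed: int = 0,
) -> TrainingSchedule:
    """All categories learned through one stimulus type."""
    makers = _STIMULUS_MAKERS[stim_type]
    pools = {float(f): [mk(float(f)) for mk in makers] for f in categories}
    return TrainingSchedule("single-type", np.asarray(categories, float), pools, n_presentations, seed)


def mixed_type_schedule(
    categories: Sequence[float],
    n_presentations: int,
    seed: int = 0,
    types: Sequence[str] = MIXABLE_TYPES,
) -> TrainingSchedule:
    """One randomly chosen stimulus type per pitch category."""
    rng = np.random.default_rng(seed)
    pools = {}
    for f in categories:
        t = types[rng.integers(len(types))]
        pools[float(f)] = [mk(float(f)) for mk in _STIMULUS_MAKERS[t]]
    return TrainingSchedule("mixed-type", np.asarray(categories, float), pools, n_presentations, seed)


# --- Training ---------------------------------------------------------------

@dataclasses.dataclass
class TrainedModel:
    """Weight matrix plus everything needed to present new stimuli to it."""

    weights: WeightMatrix
    categories: np.ndarray
    cmap: CochlearMap
    lif: LIFParams
    peak_rate: float
    dt: float = DEFAULT_DT

    _envelope_cache: dict = dataclasses.field(default_factory=dict, repr=False)

    @classmethod
    def untrained(
        cls,
        categories,
        cmap: CochlearMap | None = None,
        lif: LIFParams = LIFParams(),
        peak_rate: float = DEFAULT_PEAK_RATE,
        w0: float = W_INIT,
    ) -> "TrainedModel":
        cmap = cmap or build_cochlear_map()
        weights = WeightMatrix.uniform(categories, cmap.cfs_hz, w0)
        return cls(weights, np.asarray(categories, float), cmap, lif, peak_rate)

    def envelope(self, w: Waveform) -> RateEnvelope:
        key = w.label or id(w)
        if key not in self._envelope_cache:
            stm = spatiotemporal_map(w, self.cmap)
            self._envelope_cache[key] = calibrate_rates(stm, self.peak_rate)
        return self._envelope_cache[key]

    def present(self, w: Waveform, seed: int) -> SimResult:
        """One presentation: Poisson draw from the stimulus envelope + LIF run."""
        env = self.envelope(w)
        trains = poisson_spikes(env, seed)
        return simulate(self.weights, trains, self.lif, dt=self.dt, duration=env.duration)


@dataclasses.dataclass
class TrainingResult:
    model: TrainedModel
    trace: pd.DataFrame  # one row per presentation
    snapshots: dict[float, np.ndarray]  # fraction of training -> weight matrix copy


def _train_presentation(
    row_weights: WeightMatrix,
    env: RateEnvelope,
    seed,
    p: STDPParams,
    lif: LIFParams,
    dt: float,
    eta_scale: float,
    update_every_s: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One 0.5 s presentation with episodic weight updates.

    The Poisson input is drawn once for the whole presentation; simulation
    and plasticity then proceed in episodes of ``update_every_s`` seconds
    with membrane/conductance state carried across episode boundaries and
    the weight row updated (and clipped) after each episode.  Pairs are
    assigned to the episode of their post-synaptic spike, and pre spikes of
    neighbouring episodes still pair within the truncation window, so the
    summed update equals the whole-presentation batch rule; only the
    cadence at which it is applied is finer.
    """
    trains = poisson_spikes(env, seed)
    duration = env.duration
    sizes = np.array([tr.times_s.size for tr in trains])
    n_syn = len(trains)
    if sizes.sum():
        pre_t = np.concatenate([tr.times_s for tr in trains]) + lif.delay
        pre_syn = np.repeat(np.arange(n_syn), sizes)
        order = np.argsort(pre_t, kind="stable")
        pre_t, pre_syn = pre_t[order], pre_syn[order]
        keep = pre_t < duration
        pre_t, pre_syn = pre_t[keep], pre_syn[keep]
    else:
        pre_t = np.empty(0)
        pre_syn = np.empty(0, dtype=int)
    state = LIFState.resting(1, lif)
    cut = p.pair_cutoff
    post_all = []
    delta_total = np.zeros(n_syn)
    clipped = 0
    t0 = 0.0
    while t0 < duration - 1e-12:
        t1 = min(duration, t0 + update_every_s)
        i0, i1 = np.searchsorted(pre_t, [t0, t1])
        post = run_segment(
            row_weights, pre_t[i0:i1] - t0, pre_syn[i0:i1], lif, dt, t1 - t0, state, t_offset=t0
        )[0]
        post_all.append(post)
        j0, j1 = np.searchsorted(pre_t, [t0 - cut, t1 + cut])
        pair_sums = _pair_window_sums(pre_t[j0:j1], pre_syn[j0:j1], n_syn, post, p)
        n_pre_ep = np.bincount(pre_syn[i0:i1], minlength=n_syn)
        delta = p.eta * eta_scale * (pair_sums - p.b_j * n_pre_ep)
        new_w = row_weights.w[0] + delta
        clipped += int(np.count_nonzero((new_w < p.w_min) | (new_w > p.w_max)))
        row_weights.w[0] = np.clip(new_w, p.w_min, p.w_max)
        delta_total += delta
        t0 = t1
    return np.concatenate(post_all) if post_all else np.empty(0), delta_total, clipped


def train(
    schedule: TrainingSchedule,
    p: STDPParams = STDPParams(),
    lif: LIFParams = LIFParams(),
    cmap: CochlearMap | None = None,
    peak_rate: float = DEFAULT_PEAK_RATE,
    eta_scale: float = 100.0,
    dt: float = DEFAULT_DT,
    update_every_s: float = 0.025,
    snapshot_fractions: tuple[float, ...] = (0.1, 1.0),
) -> TrainingResult:
    """Train every pitch neuron on its own category.

    Each category is learned independently: ``n_presentations`` repeats of
    0.5 s stimuli (cycling through the category pool) with fresh Poisson
    seeds, the weight row evolving under the pair rule and clipped to
    bounds.  ``eta_scale`` multiplies eta while the presentation count
    stands in for T/eta_scale, keeping eta*T fixed.  Updates are applied
    every ``update_every_s`` of simulated time (see
    :func:`_train_presentation`): with the dense population drive a full
    0.5 s batch step at scaled eta would overshoot the homeostatic fixed
    point.  Pairing uses post-delay arrival times (t_pre + delay), i.e.
    plasticity is driven by synaptic rather than axonal events.
    """
    cmap = cmap or build_cochlear_map()
    model = TrainedModel.untrained(
        schedule.categories, cmap, lif, peak_rate, w0=p.w_0
    )
    w = model.weights.w
    n_pres = schedule.n_presentations
    snap_idx = {max(0, int(round(f * n_pres)) - 1): f for f in snapshot_fractions}
    snapshots: dict[float, np.ndarray] = {}
    rows = []
    master = np.random.SeedSequence(schedule.seed)
    cat_seqs = master.spawn(len(schedule.categories))
    for ci, freq in enumerate(schedule.categories):
        pool = schedule.pools[float(freq)]
        envs = [model.envelope(wf) for wf in pool]
        pres_seqs = cat_seqs[ci].spawn(n_pres)
        row_weights = WeightMatrix(
            w[ci : ci + 1].copy(), [freq], cmap.cfs_hz, p.w_min, p.w_max
        )
        for k in range(n_pres):
            env = envs[k % len(envs)]
            post, delta, clipped = _train_presentation(
                row_weights, env, pres_seqs[k], p, lif, dt, eta_scale, update_every_s
            )
            rows.append(
                {
                    "category_hz": float(freq),
                    "presentation": k,
                    "time_equiv_s": (k + 1) * env.duration * eta_scale,
                    "output_rate_hz": post.size / env.duration,
                    "mean_abs_dw": float(np.mean(np.abs(delta))),
                    "n_clipped": int(clipped),
                }
            )
            if k in snap_idx:
                w[ci] = row_weights.w[0]
                frac = snap_idx[k]
                snapshots.setdefault(frac, np.full_like(w, p.w_0))
                snapshots[frac][ci] = row_weights.w[0]
        w[ci] = row_weights.w[0]
    trace = pd.DataFrame(rows)
    return TrainingResult(model=model, trace=trace, snapshots=snapshots)


def mixed_type_average(runs: Sequence[WeightMatrix]) -> WeightMatrix:
    """Element-wise mean of weight matrices from repeated mixed-type runs."""
    if not runs:
        raise ValueError("need at least one weight matrix")
    shapes = {m.w.shape for m in runs}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among weight matrices: {shapes}")
    mean = np.mean([m.w for m in runs], axis=0)
    first = runs[0]
    return WeightMatrix(mean, first.row_labels, first.col_labels, first.w_min, first.w_max)
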