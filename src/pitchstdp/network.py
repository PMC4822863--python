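"""Conductance-based leaky integrate-and-fire output layer.

Each of the 29 "pitch neurons" integrates delayed, EPSC-shaped input from
the 200 Poisson afferents:

    tau_m dV_i/dt = V_p - V_i + sum_j w_ij (V_rev - V_i) sum_f eps(t - t_j^f - delta)

with a double-exponential conductance kernel eps normalized to unit area.
Integration uses exponential Euler with the conductance tracked by two
auxiliary exponential states (exact for event inputs binned to the step
grid).  A spike is emitted when V crosses threshold, after which V is
clamped at the reset potential for an absolute refractory period while
the synaptic conductances keep evolving.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .spikes import SpikeTrain

DEFAULT_DT = 1e-4  # s


@dataclasses.dataclass(frozen=True)
class LIFParams:
    """Membrane, synapse and delay parameters (SI units, potentials in mV)."""

    tau_m: float = 10e-3
    v_th: float = -50.0
    v_p: float = -65.0
    v_r: float = -65.0
    v_rev: float = 0.0
    t_ref: float = 1e-3
    delay: float = 10e-3
    tau_a: float = 0.5e-3  # EPSC rise
    tau_b: float = 1e-3  # EPSC decay

    def __post_init__(self) -> None:
        if not (self.v_r <= self.v_p < self.v_th < self.v_rev):
            raise ValueError("potentials must satisfy V_r <= V_p < V_th < V_rev")
        if not (0 < self.tau_a < self.tau_b):
            raise ValueError("EPSC time constants must satisfy 0 < tau_a < tau_b")
        if min(self.tau_m, self.t_ref) <= 0:
            raise ValueError("time constants must be positive")


def epsc_kernel(t, params: LIFParams = LIFParams()):
    """Double-exponential conductance kernel, unit area on the ms timescale.

    eps(t) = (exp(-t/tau_b) - exp(-t/tau_a)) / (tau_b - tau_a) for t >= 0
    (zero for t < 0), with the time constants expressed in milliseconds, so
    the kernel integrates to 1 over t in ms and peaks (value 0.5) at
    t* = ln(tau_b/tau_a)/(1/tau_a - 1/tau_b) = 0.693 ms.  The millisecond
    normalization matches the convention of ms-based spiking simulators and
    is what makes the published weight scale (w0 = 0.0075, bounds +-0.2)
    produce subthreshold single EPSPs summing to a dense conductance drive;
    a kernel integrating to 1 in seconds would make every single w0-EPSP
    suprathreshold and destabilize the homeostatic learning rule.
    """
    if params.tau_a == params.tau_b:
        raise ValueError("degenerate kernel: tau_a must differ from tau_b")
    t = np.asarray(t, dtype=float)
    tau_a_ms = params.tau_a * 1e3
    tau_b_ms = params.tau_b * 1e3
    out = np.where(
        t >= 0,
        (np.exp(-t / params.tau_b) - np.exp(-t / params.tau_a)) / (tau_b_ms - tau_a_ms),
        0.0,
    )
    return float(out) if out.ndim == 0 else out


W_MIN = -0.2
W_MAX = 0.2
W_INIT = 0.0075


@dataclasses.dataclass
class WeightMatrix:
    """Plastic synaptic efficacies, pitch neurons x afferents."""

    w: np.ndarray  # (n_out, n_in)
    row_labels: np.ndarray  # pitch categories (Hz), ascending
    col_labels: np.ndarray  # afferent CFs (Hz), ascending
    w_min: float = W_MIN
    w_max: float = W_MAX

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.row_labels = np.asarray(self.row_labels, dtype=float)
        self.col_labels = np.asarray(self.col_labels, dtype=float)
        if self.w.shape != (self.row_labels.size, self.col_labels.size):
            raise ValueError("weight matrix shape does not match labels")
        if np.any(self.w < self.w_min - 1e-12) or np.any(self.w > self.w_max + 1e-12):
            raise ValueError("weights outside bounds")

    @classmethod
    def uniform(cls, row_labels, col_labels, w0: float = W_INIT) -> "WeightMatrix":
        row_labels = np.asarray(row_labels, dtype=float)
        col_labels = np.asarray(col_labels, dtype=float)
        return cls(
            np.full((row_labels.size, col_labels.size), float(w0)),
            row_labels,
            col_labels,
        )

    def clipped(self, w: np.ndarray) -> np.ndarray:
        return np.clip(w, self.w_min, self.w_max)


@dataclasses.dataclass
class SimResult:
    """Output spike trains plus optional membrane traces."""

    output_trains: list[SpikeTrain]
    dt: float
    duration: float
    voltage_mv: np.ndarray | None = None  # (n_out, n_steps) when recorded


@njit(cache=True)
def _lif_core(inc, dt, tau_m, v_p, v_r, v_th, v_rev, decay_a, decay_b, ref_steps, record,
              v, xa, xb, ref):
    n_out, n_steps = inc.shape
    max_spikes = n_steps // max(ref_steps, 1) + 1
    spike_steps = np.empty((n_out, max_spikes), dtype=np.int64)
    n_spikes = np.zeros(n_out, dtype=np.int64)
    vtrace = np.empty((n_out, n_steps)) if record else np.empty((0, 0))
    status = -1  # step index of first numeric failure, -1 = ok
    for k in range(n_steps):
        for i in range(n_out):
            xa[i] = xa[i] * decay_a + inc[i, k]
            xb[i] = xb[i] * decay_b + inc[i, k]
            g = xb[i] - xa[i]
            if ref[i] > 0:
                ref[i] -= 1
                v[i] = v_r
            else:
                denom = 1.0 + g
                if denom <= 1e-9 or not np.isfinite(g):
                    status = k
                    return spike_steps, n_spikes, vtrace, status
                v_inf = (v_p + g * v_rev) / denom
                v[i] = v_inf + (v[i] - v_inf) * np.exp(-dt * denom / tau_m)
                if v[i] >= v_th:
                    spike_steps[i, n_spikes[i]] = k + 1
                    n_spikes[i] += 1
                    v[i] = v_r
                    ref[i] = ref_steps
            if record:
                vtrace[i, k] = v[i]
    return spike_steps, n_spikes, vtrace, status


def _effective_weights(weights: WeightMatrix, excitatory_only: bool) -> np.ndarray:
    """Conductance weights actually applied to the membrane.

    In the default excitatory-only mode, stored weights may be negative
    (depressed "silent" synapses that can recover under plasticity) but a
    negative weight contributes no conductance.  The literal mode applies
    negative weights as written in the membrane equation, i.e. as a
    hyperpolarizing conductance; with dense drive this can push the total
    conductance below the numerical validity of the integrator, in which
    case a numeric error is raised.
    """
    return np.maximum(weights.w, 0.0) if excitatory_only else weights.w


def _bin_increments(
    w_eff: np.ndarray,
    inputs: list[SpikeTrain] | list[np.ndarray],
    params: LIFParams,
    dt: float,
    n_steps: int,
    apply_delay: bool = True,
) -> np.ndarray:
    """Per-neuron, per-step conductance increments from delayed input spikes.

    With ``apply_delay=False`` the input times are taken to be synaptic
    arrival times already (used by the training loop, which pre-shifts them).
    """
    n_out = w_eff.shape[0]
    scale = 1.0 / ((params.tau_b - params.tau_a) * 1e3)  # ms-normalized kernel area
    inc = np.zeros((n_out, n_steps))
    all_steps = []
    all_j = []
    for j, tr in enumerate(inputs):
        times = tr.times_s if isinstance(tr, SpikeTrain) else np.asarray(tr, float)
        if times.size == 0:
            continue
        arrivals = times + params.delay if apply_delay else times
        steps = (arrivals / dt).astype(np.int64)
        steps = steps[(steps >= 0) & (steps < n_steps)]
        all_steps.append(steps)
        all_j.append(np.full(steps.size, j, dtype=np.int64))
    if not all_steps:
        return inc
    steps = np.concatenate(all_steps)
    jidx = np.concatenate(all_j)
    for i in range(n_out):
        inc[i] = np.bincount(steps, weights=w_eff[i, jidx], minlength=n_steps) * scale
    return inc


@dataclasses.dataclass
class LIFState:
    """Membrane and conductance state carried across simulation segments."""

    v: np.ndarray
    xa: np.ndarray
    xb: np.ndarray
    ref: np.ndarray

    @classmethod
    def resting(cls, n_out: int, params: LIFParams) -> "LIFState":
        return cls(
            v=np.full(n_out, params.v_p),
            xa=np.zeros(n_out),
            xb=np.zeros(n_out),
            ref=np.zeros(n_out, dtype=np.int64),
        )


def run_segment(
    weights: WeightMatrix,
    arrival_times: np.ndarray,
    arrival_syn: np.ndarray,
    params: LIFParams,
    dt: float,
    duration: float,
    state: LIFState,
    t_offset: float = 0.0,
    excitatory_only: bool = True,
) -> list[np.ndarray]:
    """Integrate one segment in place on ``state``; returns spike times.

    ``arrival_times`` are synaptic arrival times relative to the segment
    start (delay already applied) with ``arrival_syn`` giving the afferent
    index of each; returned spike times are absolute (offset by
    ``t_offset``).
    """
    w_eff = _effective_weights(weights, excitatory_only)
    n_out = w_eff.shape[0]
    n_steps = int(round(duration / dt))
    scale = 1.0 / ((params.tau_b - params.tau_a) * 1e3)
    steps = (np.asarray(arrival_times, float) / dt).astype(np.int64)
    keep = (steps >= 0) & (steps < n_steps)
    steps, syn = steps[keep], np.asarray(arrival_syn)[keep]
    inc = np.zeros((n_out, n_steps))
    for i in range(n_out):
        inc[i] = np.bincount(steps, weights=w_eff[i, syn], minlength=n_steps) * scale
    spike_steps, n_spikes, _, status = _lif_core(
        inc,
        dt,
        params.tau_m,
        params.v_p,
        params.v_r,
        params.v_th,
        params.v_rev,
        np.exp(-dt / params.tau_a),
        np.exp(-dt / params.tau_b),
        int(round(params.t_ref / dt)),
        False,
        state.v,
        state.xa,
        state.xb,
        state.ref,
    )
    if status >= 0:
        raise FloatingPointError(
            f"LIF state became invalid at t = {t_offset + status * dt:.6f} s "
            "(total conductance drove the effective leak non-positive)"
        )
    return [
        spike_steps[i, : n_spikes[i]] * dt + t_offset for i in range(weights.w.shape[0])
    ]


def simulate(
    weights: WeightMatrix,
    inputs: list[SpikeTrain] | list[np.ndarray],
    params: LIFParams = LIFParams(),
    dt: float = DEFAULT_DT,
    duration: float = 0.5,
    record_voltage: bool = False,
    excitatory_only: bool = True,
) -> SimResult:
    """Integrate the output layer for ``duration`` seconds.

    ``inputs`` holds one spike train (or bare time array) per afferent,
    ordered to match the weight-matrix columns.  By default negative stored
    weights contribute no conductance (all inputs excitatory); pass
    ``excitatory_only=False`` to apply them literally as hyperpolarizing
    conductances.
    """
    if dt > 1e-4 + 1e-12:
        raise ValueError("dt must be <= 0.1 ms")
    if len(inputs) != weights.w.shape[1]:
        raise ValueError("number of input trains must match weight columns")
    n_steps = int(round(duration / dt))
    inc = _bin_increments(
        _effective_weights(weights, excitatory_only), inputs, params, dt, n_steps
    )
    ref_steps = int(round(params.t_ref / dt))
    state = LIFState.resting(weights.w.shape[0], params)
    spike_steps, n_spikes, vtrace, status = _lif_core(
        inc,
        dt,
        params.tau_m,
        params.v_p,
        params.v_r,
        params.v_th,
        params.v_rev,
        np.exp(-dt / params.tau_a),
        np.exp(-dt / params.tau_b),
        ref_steps,
        record_voltage,
        state.v,
        state.xa,
        state.xb,
        state.ref,
    )
    if status >= 0:
        raise FloatingPointError(
            f"LIF state became invalid at t = {status * dt:.6f} s "
            "(total conductance drove the effective leak non-positive)"
        )
    trains = [
        SpikeTrain(spike_steps[i, : n_spikes[i]] * dt, neuron_id=i, duration_s=duration)
        for i in range(weights.w.shape[0])
    ]
    return SimResult(
        output_trains=trains,
        dt=dt,
        duration=duration,
        voltage_mv=vtrace if record_voltage else None,
    )


def output_rate(result: SimResult, window: tuple[float, float] | None = None) -> np.ndarray:
    """Mean firing rate (spikes/s) of each output neuron over ``window``."""
    if window is None:
        window = (0.0, result.duration)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    rates = np.array(
        [
            np.count_nonzero((tr.times_s >= t0) & (tr.times_s < t1)) / (t1 - t0)
            for tr in result.output_trains
        ]
    )
    return rates
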