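"""Fixed-step Euler integration of single neurons and coupled networks.

The study's integration scheme is forward Euler with dt = 0.025 ms; an
adaptive-step reference (scipy ``solve_ivp``) is provided as a cross-check
oracle only.  Voltage traces are recorded on a coarser grid (default 1 ms,
i.e. 1 kHz, well above the 50 Hz analysis band) while spikes are detected
at full integration resolution as interpolated upward threshold crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import NeuronParameters, params_to_matrix, resting_state
from .network import NetworkSpec, adjacency_to_csr

__all__ = ["SimulationRecord", "SimulationDivergedError", "integrate",
           "integrate_adaptive", "detect_spikes", "initial_state"]

DEFAULT_DT = 0.025          # ms
DEFAULT_THRESHOLD = -20.0   # mV; spikes overshoot 0 mV, subthreshold stays < -40
DEFAULT_REFRACTORY = 2.0    # ms


class SimulationDivergedError(RuntimeError):
    def __init__(self, step: int, t_ms: float):
        self.step = step
        self.t_ms = t_ms
        super().__init__(f"|V| exceeded {_kernels.V_BLOWUP} mV at step {step} (t = {t_ms:.3f} ms)")


@dataclass
class SimulationRecord:
    """Output of one integration run."""

    dt: float
    t_transient: float
    t_record: float
    fs: float                       # sampling rate of V_traces (Hz)
    t: np.ndarray                   # recorded time grid (ms, 0 at recording start)
    V_traces: np.ndarray            # (N, n_samples) mV
    spikes: list[np.ndarray]        # per-node sorted spike times (ms)
    final_state: np.ndarray         # (5, N)
    spec: object = None             # NetworkSpec or NeuronParameters
    integrator_tag: str = "euler"

    @property
    def N(self) -> int:
        return self.V_traces.shape[0]


def initial_state(params: list[NeuronParameters], v_jitter: float = 0.0,
                  seed: int | None = None) -> np.ndarray:
    """Default (5, N) initial condition: V = -60 mV (optionally jittered
    uniformly by +/- v_jitter, seeded), gating at steady state, a_sr = 0.1."""
    rng = np.random.default_rng(seed)
    cols = []
    for p in params:
        V0 = -60.0 + (rng.uniform(-v_jitter, v_jitter) if v_jitter > 0 else 0.0)
        cols.append(resting_state(p, V=V0).as_array())
    return np.array(cols).T.copy()


def _as_network(spec) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, object]:
    """Normalize single-neuron / network input to kernel arguments."""
    if isinstance(spec, NeuronParameters):
        P = params_to_matrix(spec)
        indptr = np.zeros(2, dtype=np.int64)
        indices = np.zeros(0, dtype=np.int64)
        return P, indptr, indices, 0.0, [spec]
    if isinstance(spec, NetworkSpec):
        indptr, indices = adjacency_to_csr(spec.C)
        return spec.param_matrix(), indptr, indices, float(spec.g), spec.params
    raise TypeError("spec must be NeuronParameters or NetworkSpec")


def integrate(spec, dt: float = DEFAULT_DT, t_transient: float = 5000.0,
              t_record: float = 30000.0, record_every_ms: float = 1.0,
              state0: np.ndarray | None = None, v_jitter: float = 0.0,
              seed: int | None = None, threshold: float = DEFAULT_THRESHOLD,
              refractory: float = DEFAULT_REFRACTORY) -> SimulationRecord:
    """Euler-integrate ``spec`` (a ``NeuronParameters`` or ``NetworkSpec``).

    The transient is integrated and discarded; traces and spike times are
    reported relative to the start of the recording window.  Deterministic
    given (spec, state0 or seed).  Raises ``SimulationDivergedError`` if
    any voltage leaves +/-500 mV.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_transient < 0 or t_record < 0:
        raise ValueError("durations must be >= 0")
    P, indptr, indices, g, params = _as_network(spec)
    if state0 is None:
        state0 = initial_state(params, v_jitter=v_jitter, seed=seed)
    state0 = np.asarray(state0, dtype=np.float64)
    if state0.ndim == 1:
        state0 = state0[:, None]
    stride = max(1, int(round(record_every_ms / dt)))
    n_transient = int(round(t_transient / dt))
    n_record = int(round(t_record / dt))
    # generous cap: 300 spikes/s sustained
    spike_cap = max(64, int(t_record * 0.3) + 64)
    V_rec, spikes, counts, S_final, blew = _kernels.euler_network(
        P, indptr, indices, g, state0, dt, n_transient, n_record, stride,
        threshold, int(round(refractory / dt)), spike_cap)
    if blew >= 0:
        raise SimulationDivergedError(blew, blew * dt)
    fs = 1000.0 / (stride * dt)
    t = np.arange(V_rec.shape[1]) * (stride * dt)
    spike_lists = [spikes[n, :counts[n]].copy() for n in range(V_rec.shape[0])]
    return SimulationRecord(dt=dt, t_transient=t_transient, t_record=t_record,
                            fs=fs, t=t, V_traces=V_rec, spikes=spike_lists,
                            final_state=S_final, spec=spec)


def integrate_adaptive(spec, t_transient: float = 5000.0, t_record: float = 10000.0,
                       record_every_ms: float = 1.0, state0: np.ndarray | None = None,
                       rtol: float = 1e-8, atol: float = 1e-10,
                       threshold: float = DEFAULT_THRESHOLD,
                       refractory: float = DEFAULT_REFRACTORY) -> SimulationRecord:
    """Adaptive-step reference integration (scipy RK45); cross-check oracle.

    Spikes are detected on a 0.1 ms dense output grid.
    """
    from scipy.integrate import solve_ivp

    P, indptr, indices, g, params = _as_network(spec)
    if state0 is None:
        state0 = initial_state(params)
    state0 = np.asarray(state0, dtype=np.float64)
    if state0.ndim == 1:
        state0 = state0[:, None]
    N = state0.shape[1]
    D = np.empty((5, N))
    Isyn = np.zeros(N)

    def rhs(t, y):
        S = y.reshape(5, N)
        _kernels._coupling_into(S, indptr, indices, g, Isyn)
        _kernels._deriv_into(S, P, Isyn, D)
        return D.ravel().copy()

    t_dense = np.arange(0.0, t_record + 1e-9, 0.1)
    sol = solve_ivp(rhs, (0.0, t_transient + t_record), state0.ravel(),
                    t_eval=t_transient + t_dense, rtol=rtol, atol=atol,
                    method="RK45")
    if not sol.success:
        raise RuntimeError(f"adaptive integration failed: {sol.message}")
    Y = sol.y.reshape(5, N, -1)
    V_dense = Y[0]
    stride = max(1, int(round(record_every_ms / 0.1)))
    V_rec = V_dense[:, ::stride]
    spikes = [detect_spikes(V_dense[n], fs=10000.0, threshold=threshold,
                            refractory=refractory) for n in range(N)]
    fs = 10000.0 / stride
    t = np.arange(V_rec.shape[1]) * (1000.0 / fs)
    return SimulationRecord(dt=np.nan, t_transient=t_transient, t_record=t_record,
                            fs=fs, t=t, V_traces=V_rec, spikes=spikes,
                            final_state=Y[:, :, -1], spec=spec,
                            integrator_tag="adaptive")


def detect_spikes(V: np.ndarray, fs: float, threshold: float = DEFAULT_THRESHOLD,
                  refractory: float = DEFAULT_REFRACTORY) -> np.ndarray:
    """Upward threshold crossings of a uniformly sampled trace (times in ms,
    linearly interpolated between samples), suppressing crossings closer
    than ``refractory`` ms to the previous accepted spike."""
    V = np.asarray(V, dtype=float)
    dt_ms = 1000.0 / fs
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        return np.zeros(0)
    frac = (threshold - V[idx]) / (V[idx + 1] - V[idx])
    times = (idx + frac) * dt_ms
    out = [times[0]]
    for t in times[1:]:
        if t - out[-1] > refractory:
            out.append(t)
    return np.asarray(out)
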