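"""Maximal Lyapunov exponent (MLE) estimation.

The estimator is the classic two-trajectory scheme: integrate a reference
orbit and a companion displaced by a small distance d0, let them separate
for a fixed renormalization interval, record log(d/d0), pull the companion
back to distance d0 along the current separation direction, and average.
MLE > 0 is the operational definition of chaos here.

Neuron and network estimates run on the study's own Euler scheme
(dt = 0.025 ms) through compiled kernels; a generic RK4 version is kept
for benchmark flows (linear contraction, Lorenz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import _kernels
from .model import NeuronParameters, params_to_matrix
from .network import NetworkSpec, adjacency_to_csr
from .simulate import initial_state

__all__ = ["MLEEstimate", "mle_two_trajectory", "neuron_mle", "network_mle",
           "classify_chaotic"]

# single-neuron estimates scatter by ~1e-3/ms around 0 on periodic orbits;
# |mle| below this band is not evidence of chaos
NOISE_BAND = 2e-3  # 1/ms


@dataclass
class MLEEstimate:
    mle: float              # 1/time-unit of the system (1/ms for neurons)
    n_renorm: int
    d0: float
    t_transient: float
    t_average: float
    converged: bool
    history: np.ndarray | None = None   # running-mean trajectory of the estimate


def _finalize(logs: np.ndarray, renorm_dt: float, d0: float,
              t_transient: float, ok: bool) -> MLEEstimate:
    if logs.size == 0:
        raise RuntimeError("trajectory diverged before any renormalization")
    running = np.cumsum(logs) / (np.arange(logs.size) + 1) / renorm_dt
    mle = float(running[-1])
    # tail stability: running mean over the last quarter moves < 5%
    q = max(2, logs.size // 4)
    tail = running[-q:]
    # relative change is ill-defined near 0; floor the scale at the noise band
    scale = max(abs(mle), NOISE_BAND)
    converged = bool(ok and (np.max(tail) - np.min(tail)) / scale < 0.05)
    return MLEEstimate(mle=mle, n_renorm=int(logs.size), d0=d0,
                       t_transient=t_transient, t_average=logs.size * renorm_dt,
                       converged=converged, history=running)


def mle_two_trajectory(f: Callable[[np.ndarray], np.ndarray], x0: np.ndarray,
                       d0: float = 1e-8, dt: float = 0.005,
                       t_transient: float = 50.0, t_average: float = 1000.0,
                       renorm_interval: float = 0.5, seed: int = 0) -> MLEEstimate:
    """Generic two-trajectory MLE of the autonomous flow dx/dt = f(x),
    integrated with fixed-step RK4.  Units follow the system's time unit."""
    if d0 <= 0:
        raise ValueError("d0 must be > 0")
    rng = np.random.default_rng(seed)

    def rk4(x, n):
        for _ in range(n):
            k1 = f(x)
            k2 = f(x + 0.5 * dt * k1)
            k3 = f(x + 0.5 * dt * k2)
            k4 = f(x + dt * k3)
            x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        return x

    x = np.asarray(x0, dtype=float)
    x = rk4(x, int(round(t_transient / dt)))
    pert = rng.standard_normal(x.shape)
    y = x + d0 * pert / np.linalg.norm(pert)
    n_sub = max(1, int(round(renorm_interval / dt)))
    renorm_dt = n_sub * dt
    n_renorms = int(round(t_average / renorm_dt))
    logs = np.empty(n_renorms)
    for i in range(n_renorms):
        x = rk4(x, n_sub)
        y = rk4(y, n_sub)
        d = float(np.linalg.norm(y - x))
        if not np.isfinite(d):
            raise RuntimeError(f"trajectory diverged at renormalization {i}")
        if d == 0.0:
            pert = rng.standard_normal(x.shape)
            y = x + d0 * pert / np.linalg.norm(pert)
            logs[i] = 0.0
            continue
        logs[i] = np.log(d / d0)
        y = x + (y - x) * (d0 / d)
    return _finalize(logs, renorm_dt, d0, t_transient, ok=True)


def network_mle(spec: NetworkSpec, dt: float = 0.025, d0: float = 1e-6,
                renorm_interval: float = 1.0, t_transient: float = 5000.0,
                t_average: float = 20000.0, seed: int = 0,
                state0: np.ndarray | None = None,
                v_jitter: float = 0.0) -> MLEEstimate:
    """MLE of the coupled network in the full 5N-dimensional state space
    (unweighted Euclidean norm), using the study's Euler integration."""
    indptr, indices = adjacency_to_csr(spec.C)
    P = spec.param_matrix()
    if state0 is None:
        state0 = initial_state(spec.params, v_jitter=v_jitter, seed=seed)
    renorm_steps = max(1, int(round(renorm_interval / dt)))
    renorm_dt = renorm_steps * dt
    n_renorms = int(round(t_average / renorm_dt))
    logs, ok = _kernels.mle_network(P, indptr, indices, float(spec.g),
                                    np.asarray(state0, dtype=np.float64), dt,
                                    int(round(t_transient / dt)), renorm_steps,
                                    n_renorms, d0, seed % (2**31))
    return _finalize(np.asarray(logs), renorm_dt, d0, t_transient, ok)


def neuron_mle(params: NeuronParameters, dt: float = 0.025, d0: float = 1e-6,
               renorm_interval: float = 1.0, t_transient: float = 5000.0,
               t_average: float = 50000.0, seed: int = 0,
               state0: np.ndarray | None = None) -> MLEEstimate:
    """MLE of an isolated neuron (5-dimensional state space)."""
    P = params_to_matrix(params)
    indptr = np.zeros(2, dtype=np.int64)
    indices = np.zeros(0, dtype=np.int64)
    if state0 is None:
        state0 = initial_state([params])
    state0 = np.asarray(state0, dtype=np.float64)
    if state0.ndim == 1:
        state0 = state0[:, None]
    renorm_steps = max(1, int(round(renorm_interval / dt)))
    renorm_dt = renorm_steps * dt
    n_renorms = int(round(t_average / renorm_dt))
    logs, ok = _kernels.mle_network(P, indptr, indices, 0.0, state0, dt,
                                    int(round(t_transient / dt)), renorm_steps,
                                    n_renorms, d0, seed % (2**31))
    return _finalize(np.asarray(logs), renorm_dt, d0, t_transient, ok)


def classify_chaotic(mle: float, tol: float = 0.0) -> str:
    """'chaotic' iff mle > tol (strict); the boundary is non-chaotic."""
    if tol < 0:
        raise ValueError("tol must be >= 0")
    return "chaotic" if mle > tol else "non_chaotic"
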