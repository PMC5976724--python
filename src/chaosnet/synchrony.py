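"""Instantaneous phase extraction and global synchrony metrics.

Each voltage trace is zero-phase low-pass filtered at 50 Hz and
transformed with a continuous wavelet transform (complex Morlet mother,
omega0 = 6 by default).  The node's predominant frequency is the scale of
maximal time-averaged wavelet power, and its instantaneous phase is the
complex angle of the transform at that single scale — frequency and phase
in one step.

Global synchrony is the Kuramoto order parameter: the modulus R(t) of the
population-mean unit phasor, time-averaged to R.  Metastability chi is the
temporal variance of R(t): zero both for full lock and for full asynchrony,
large only when coherence waxes and wanes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

__all__ = ["PhaseEnsemble", "SynchronyMetrics", "extract_phase",
           "order_parameter", "order_parameter_series", "metastability",
           "synchrony_metrics"]


class UndefinedPhaseError(ValueError):
    pass


@dataclass
class PhaseEnsemble:
    """Per-node instantaneous phases (radians, continuous / unwrapped),
    predominant frequencies (Hz), and the common sampling rate."""

    phases: np.ndarray   # (N, T)
    freqs: np.ndarray    # (N,)
    fs: float

    @property
    def N(self) -> int:
        return self.phases.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]


@dataclass
class SynchronyMetrics:
    R: float                 # time-mean order parameter, in [0, 1]
    chi: float               # temporal variance of R_t, in [0, 0.25]
    R_t: np.ndarray          # instantaneous order parameter series


def _morlet_name(w0: float) -> str:
    # pywt cmorB-C: psi(t) ~ exp(2 pi i C t) exp(-t^2 / B); the standard
    # Morlet exp(i w0 t) exp(-t^2/2) maps to C = w0/(2 pi), B = 2
    return f"cmor2.0-{w0 / (2.0 * np.pi):.6f}"


def extract_phase(V_traces: np.ndarray, fs: float, lowpass_hz: float = 50.0,
                  fmin: float = 0.5, fmax: float = 50.0, n_scales: int = 48,
                  w0: float = 6.0, filter_order: int = 4,
                  trim_edges: bool = True) -> PhaseEnsemble:
    """Instantaneous phase of each row of ``V_traces`` at its predominant
    frequency.

    Requires fs > 2 * lowpass_hz.  Half a wavelet support (3 Gaussian
    sigmas of the envelope at the chosen scale) is discarded at each end
    of the series — uniformly across nodes, so the ensemble keeps a shared
    time base.  A constant trace has no phase and raises
    ``UndefinedPhaseError``.
    """
    V = np.atleast_2d(np.asarray(V_traces, dtype=float))
    if fs <= 2 * lowpass_hz:
        raise ValueError("need fs > 2 * lowpass cutoff")
    flat = np.ptp(V, axis=1) < 1e-9
    if np.any(flat):
        raise UndefinedPhaseError(f"constant trace(s) at node(s) {np.flatnonzero(flat)}")
    sos = signal.butter(filter_order, lowpass_hz, fs=fs, output="sos")
    Vf = signal.sosfiltfilt(sos, V, axis=1)
    # remove DC: the discretized Morlet is only near-zero-mean, so a large
    # offset would otherwise leak power into the largest scales
    Vf = Vf - Vf.mean(axis=1, keepdims=True)

    wavelet = _morlet_name(w0)
    freqs_grid = np.geomspace(fmin, fmax, n_scales)
    fc = pywt.central_frequency(wavelet)
    scales = fc * fs / freqs_grid
    N, T = Vf.shape
    phases = np.empty((N, T))
    freqs = np.empty(N)
    best_scales = np.empty(N)
    for n in range(N):  # per node: keeps peak memory at one (n_scales, T) block
        coef, _ = pywt.cwt(Vf[n], scales, wavelet, sampling_period=1.0 / fs,
                           method="fft")
        power = np.mean(np.abs(coef) ** 2, axis=1)
        k = int(np.argmax(power))
        freqs[n] = freqs_grid[k]
        best_scales[n] = scales[k]
        phases[n] = np.unwrap(np.angle(coef[k]))
    if trim_edges:
        # Gaussian envelope sigma in samples is scale * sqrt(B/2) = scale
        # (B = 2); keep everything beyond 3 sigma of both ends
        n_edge = int(np.ceil(3.0 * np.max(best_scales)))
        n_edge = min(n_edge, (T - 2) // 2)
        if n_edge > 0:
            phases = phases[:, n_edge:T - n_edge]
    return PhaseEnsemble(phases=phases, freqs=freqs, fs=fs)


def order_parameter(phases: np.ndarray) -> float:
    """Modulus of the mean unit phasor of one snapshot of N phases."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("need at least one phase")
    return float(np.abs(np.mean(np.exp(1j * phases))))


def order_parameter_series(phases: np.ndarray) -> np.ndarray:
    """R(t) for a (N, T) phase array."""
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    return np.abs(np.mean(np.exp(1j * phases), axis=0))


def metastability(R_t: np.ndarray) -> float:
    """Temporal variance of the instantaneous order parameter (mean over
    samples, so chi does not depend on the sampling rate)."""
    R_t = np.asarray(R_t, dtype=float)
    if R_t.size < 2:
        raise ValueError("need at least two samples")
    return float(np.var(R_t))


def synchrony_metrics(ens: PhaseEnsemble | np.ndarray) -> SynchronyMetrics:
    """R, chi and R(t) of a phase ensemble."""
    phases = ens.phases if isinstance(ens, PhaseEnsemble) else np.asarray(ens)
    R_t = order_parameter_series(phases)
    return SynchronyMetrics(R=float(R_t.mean()), chi=metastability(R_t), R_t=R_t)
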