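"""Surrogate phase ensembles and voltage-like traces with closed-form
ground truth, so every analysis stage is testable without ODE runs.

Phase-level kinds bypass filtering/wavelets entirely and carry exact
expected values of R, chi, FC and FCD; voltage-level kinds (spike trains,
subthreshold oscillations) are amplitude-matched to the HB + I_h regime
(roughly -90 to +40 mV) so spike-detector thresholds transfer.  None of
the fixtures emulates chaos — chaos testing uses real ODE systems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["SurrogateSpec", "generate"]


@dataclass
class SurrogateSpec:
    kind: str                   # locked | independent | constant_lag |
                                # block_switching | spike_train | subthreshold
    N: int = 10
    fs: float = 1000.0          # Hz
    duration_ms: float = 10000.0
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0


def _time(spec: SurrogateSpec) -> np.ndarray:
    n = int(round(spec.duration_ms * spec.fs / 1000.0))
    return np.arange(n) / spec.fs  # seconds


def _locked(spec: SurrogateSpec):
    f = spec.params.get("freq_hz", 4.0)
    t = _time(spec)
    phases = np.tile(2 * np.pi * f * t, (spec.N, 1))
    gt = dict(R=1.0, chi=0.0, fc_offdiag=1.0, fcd_all=1.0, fcd_variance=0.0)
    return dict(phases=phases, fs=spec.fs), gt


def _independent(spec: SurrogateSpec):
    """Uniform random initial phases, incommensurate frequencies: at any
    sample the ensemble is (approximately) a uniform random phase draw;
    the t=0 snapshot is exactly one."""
    f0 = spec.params.get("freq_hz", 4.0)
    jitter = spec.params.get("freq_jitter", 0.3)
    rng = np.random.default_rng(spec.seed)
    t = _time(spec)
    f = f0 * (1 + jitter * (2 * rng.random(spec.N) - 1))
    phi0 = rng.uniform(0, 2 * np.pi, spec.N)
    phases = phi0[:, None] + 2 * np.pi * f[:, None] * t[None, :]
    gt = dict(expected_R=np.sqrt(np.pi) / (2 * np.sqrt(spec.N)),
              fcd_offdiag_mean=0.0)
    return dict(phases=phases, fs=spec.fs), gt


def _constant_lag(spec: SurrogateSpec):
    """phi_k(t) = 2 pi f t + k * lag: pair (k, l) has fixed lag (k-l)*lag,
    so FC_kl = |cos((k-l) lag / 2)| exactly and R_t is constant."""
    f = spec.params.get("freq_hz", 4.0)
    lag = spec.params.get("lag_rad", np.pi / 2)
    t = _time(spec)
    k = np.arange(spec.N)
    phases = 2 * np.pi * f * t[None, :] + (k * lag)[:, None]
    R = float(np.abs(np.mean(np.exp(1j * k * lag))))
    fc = np.abs(np.cos(np.subtract.outer(k, k) * lag / 2.0))
    np.fill_diagonal(fc, 1.0)
    gt = dict(R=R, chi=0.0, fc_matrix=fc, fcd_all=1.0, fcd_variance=0.0)
    return dict(phases=phases, fs=spec.fs), gt


def _block_switching(spec: SurrogateSpec):
    """Alternating blocks of two fixed lag patterns A/B.

    With non-overlapping FC windows of exactly one block length, every
    window is pure, FCD entries are 1 (same state) or c (across states,
    c = Pearson correlation of the two FC vectors), and the off-diagonal
    FCD variance approaches p(1-p)(1-c)^2 with p the fraction of A-blocks.
    """
    f = spec.params.get("freq_hz", 4.0)
    block_ms = spec.params.get("block_ms", 2000.0)
    lag_scale = spec.params.get("lag_scale", np.pi / 3)
    rng = np.random.default_rng(spec.seed)
    t = _time(spec)
    n_block = int(round(block_ms * spec.fs / 1000.0))
    offs_A = rng.uniform(-lag_scale, lag_scale, spec.N)
    offs_B = rng.uniform(-lag_scale, lag_scale, spec.N)
    state = (np.arange(t.size) // n_block) % 2   # 0 = A, 1 = B
    offsets = np.where(state[None, :] == 0, offs_A[:, None], offs_B[:, None])
    phases = 2 * np.pi * f * t[None, :] + offsets

    def fc_of(offs):
        m = np.abs(np.cos(np.subtract.outer(offs, offs) / 2.0))
        np.fill_diagonal(m, 1.0)
        return m

    fcA, fcB = fc_of(offs_A), fc_of(offs_B)
    rows, cols = np.tril_indices(spec.N, k=-2)
    va, vb = fcA[rows, cols], fcB[rows, cols]
    c = float(np.corrcoef(va, vb)[0, 1])
    n_blocks = t.size // n_block
    states = (np.arange(n_blocks) % 2)
    pA = float(np.mean(states == 0))
    gt = dict(fc_A=fcA, fc_B=fcB, between_state_corr=c,
              window_states=states, block_ms=block_ms,
              fcd_variance=pA * (1 - pA) * (1 - c) ** 2)
    return dict(phases=phases, fs=spec.fs), gt


def _spike_waveform(fs: float) -> np.ndarray:
    """Stereotyped ~3 ms action-potential bump peaking near +30 mV."""
    n = max(3, int(round(3e-3 * fs)))
    x = np.linspace(-1, 1, n)
    return 95.0 * np.exp(-(x / 0.45) ** 2)   # added on a -65 mV baseline


def _spike_train(spec: SurrogateSpec):
    """Voltage-like trace: subthreshold sinusoid plus spike bumps.

    params: rate_hz (the slow-cycle rate; spikes ride the sine peaks),
    spikes_per_burst (>= 2 makes every event a burst), spike_every
    (spike only on every n-th cycle: cycle skipping), sub_amp_mv.
    """
    rate = spec.params.get("rate_hz", 4.0)
    spb = spec.params.get("spikes_per_burst", 1)
    every = int(spec.params.get("spike_every", 1))
    amp = spec.params.get("sub_amp_mv", 10.0)
    t = _time(spec)
    V = -65.0 + amp * np.sin(2 * np.pi * rate * t - np.pi / 2)[None, :].repeat(spec.N, 0)
    wf = _spike_waveform(spec.fs)
    period_s = 1.0 / rate
    spike_times = []
    intra_gap = 6e-3  # s between spikes inside a burst
    for c in range(0, int(spec.duration_ms / 1000.0 * rate), every):
        t0 = c * period_s + period_s / 2.0  # sine peak
        for s in range(spb):
            spike_times.append(t0 + s * intra_gap)
    st = np.array([x for x in spike_times if x * spec.fs + wf.size < t.size])
    for x in st:
        i = int(round(x * spec.fs))
        for n in range(spec.N):
            V[n, i:i + wf.size] += wf
    gt = dict(spike_times_ms=st * 1000.0, firing_rate=st.size / (spec.duration_ms / 1000.0),
              n_events=int(st.size / max(spb, 1)), spikes_per_event=spb,
              burst_fraction=1.0 if spb >= 2 else 0.0, freq_hz=rate)
    return dict(V=V, fs=spec.fs), gt


def _subthreshold(spec: SurrogateSpec):
    f = spec.params.get("freq_hz", 4.0)
    amp = spec.params.get("sub_amp_mv", 10.0)
    noise = spec.params.get("noise_sd_mv", 0.0)
    rng = np.random.default_rng(spec.seed)
    t = _time(spec)
    V = -65.0 + amp * np.sin(2 * np.pi * f * t)[None, :].repeat(spec.N, 0)
    if noise > 0:
        V = V + rng.normal(0.0, noise, V.shape)
    gt = dict(freq_hz=f, firing_rate=0.0, pattern_code=1,
              clean_phase=np.mod(2 * np.pi * f * t - np.pi / 2, 2 * np.pi))
    return dict(V=V, fs=spec.fs), gt


_KINDS = {
    "locked": _locked,
    "independent": _independent,
    "constant_lag": _constant_lag,
    "block_switching": _block_switching,
    "spike_train": _spike_train,
    "subthreshold": _subthreshold,
}


def generate(spec: SurrogateSpec) -> tuple[dict, dict]:
    """Build the surrogate described by ``spec``.

    Returns (data, ground_truth): data holds either 'phases' or 'V' plus
    'fs'; ground_truth the closed-form expected metrics.  Deterministic
    given spec.seed.
    """
    try:
        fn = _KINDS[spec.kind]
    except KeyError:
        raise ValueError(f"unknown surrogate kind {spec.kind!r}; "
                         f"known: {sorted(_KINDS)}") from None
    return fn(spec)
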