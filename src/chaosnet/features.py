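"""Firing-rate / firing-pattern characterization, burst statistics,
parameter-plane scanning, and matched-firing-rate population sampling.

The scan walks a grid of the slow conductances (g_sd, g_sr) at fixed g_h,
simulating each isolated neuron and recording its maximal Lyapunov
exponent, firing rate and firing-pattern code.  Populations of chaotic,
non-chaotic and NoIh (g_h = 0) parameter sets with the *same distribution*
of firing rates are then drawn by matching per-bin counts in 0.1 Hz bins,
which removes rate heterogeneity as a confound when comparing network
dynamics across node types.

Firing-pattern codes:
  0 no oscillation, 1 subthreshold oscillation (no spikes),
  2 spikes with cycle skipping, 3 regular tonic spiking, 4 burst firing,
  5 tonic 20-50 spikes/s, 6 tonic > 50 spikes/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .lyapunov import NOISE_BAND, classify_chaotic, neuron_mle
from .model import NeuronParameters
from .simulate import SimulationRecord, SimulationDivergedError, integrate

__all__ = [
    "firing_rate", "estimate_slow_period", "group_events", "burst_fraction",
    "mean_burst_fraction", "classify_pattern", "scan_parameter_plane",
    "sample_matched_populations", "MatchedPopulations", "ParameterScanPoint",
    "DEFAULT_SCAN_REGIONS", "InfeasibleMatchingError",
]

# grids over the slow-conductance plane used throughout the study;
# the g_h = 0.4 grid is concentrated on the strip where isolated firing
# rates fall in the matched 3.0-4.5 spikes/s band (derived from our own
# coarse MLE/rate scan), the g_h = 0 (NoIh) grid follows its boundary
DEFAULT_SCAN_REGIONS = {
    "gsd_gsr": dict(
        g_sd=np.round(np.arange(0.18, 0.3551, 0.0025), 4),
        g_sr=np.round(np.arange(0.26, 0.3401, 0.0025), 4),
        g_h=0.4,
    ),
    "noih": dict(
        g_sd=np.round(np.arange(0.175, 0.3001, 0.005), 4),
        g_sr=np.round(np.arange(0.18, 0.4401, 0.005), 4),
        g_h=0.0,
    ),
}


class InfeasibleMatchingError(RuntimeError):
    def __init__(self, bins_by_region: dict[str, list[float]]):
        self.bins_by_region = bins_by_region
        super().__init__(f"rate bins empty in source regions: {bins_by_region}")


def firing_rate(spikes: np.ndarray, t_record: float) -> float:
    """Spikes per second from spike times over ``t_record`` ms."""
    if t_record <= 0:
        raise ValueError("t_record must be > 0")
    return len(spikes) / (t_record / 1000.0)


def estimate_slow_period(V: np.ndarray, fs: float, fmax: float = 20.0,
                         fmin: float = 0.3, clip_mv: float = -20.0) -> float | None:
    """Period (ms) of the subthreshold slow oscillation.

    The trace is clipped at ``clip_mv`` (suppressing spike waveforms whose
    harmonics would otherwise dominate the spectrum), low-pass filtered at
    ``fmax`` and the dominant Welch peak below ``fmax`` Hz taken.  Returns
    None when no oscillation survives (flat trace, or activity confined to
    the spike band as in fast tonic firing).
    """
    V = np.asarray(V, dtype=float)
    if np.ptp(V) < 1.0:  # < 1 mV peak-to-peak: no oscillation
        return None
    Vc = np.minimum(V, clip_mv)
    if fs > 2.5 * fmax:
        sos = signal.butter(4, fmax, fs=fs, output="sos")
        Vc = signal.sosfiltfilt(sos, Vc)
    if np.ptp(Vc) < 1.0:
        return None
    nper = min(Vc.size, int(8 * fs / fmin))
    f, P = signal.welch(Vc - Vc.mean(), fs=fs, nperseg=min(nper, Vc.size))
    m = (f >= fmin) & (f <= fmax)
    if not np.any(m) or np.all(P[m] <= 0):
        return None
    Pm = P[m]
    # a real rhythm stands far above the band's median power; a flat
    # (filtered-noise) spectrum does not
    if np.max(Pm) < 10.0 * np.median(Pm):
        return None
    return 1000.0 / f[m][np.argmax(Pm)]


def group_events(spikes: np.ndarray, slow_period: float | None = None,
                 V_trace: np.ndarray | None = None, fs: float | None = None,
                 isi_factor: float = 0.5) -> list[np.ndarray]:
    """Partition sorted spike times into oscillation events.

    Consecutive spikes join one event when their ISI is below
    ``isi_factor`` x the slow-oscillation period (the model is a parabolic
    burster: events ride slow cycles).  The period may be given directly
    or estimated from ``V_trace``; with neither, the median ISI stands in.
    An event with >= 2 spikes is a burst.
    """
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size == 0:
        return []
    if slow_period is None and V_trace is not None and fs is not None:
        slow_period = estimate_slow_period(V_trace, fs)
    if slow_period is None:
        isis = np.diff(spikes)
        slow_period = float(np.median(isis)) if isis.size else np.inf
    cut = isi_factor * slow_period
    events, current = [], [spikes[0]]
    for prev, t in zip(spikes[:-1], spikes[1:]):
        if t - prev < cut:
            current.append(t)
        else:
            events.append(np.asarray(current))
            current = [t]
    events.append(np.asarray(current))
    return events


def burst_fraction(events: list[np.ndarray]) -> float:
    """b_k = Nb / Te: bursts (events with >= 2 spikes) over total events."""
    if not events:
        return 0.0
    return sum(1 for e in events if len(e) >= 2) / len(events)


def mean_burst_fraction(b_values) -> float:
    """Network mean of per-neuron burst fractions, (1/N) sum b_k."""
    b = np.asarray(list(b_values), dtype=float)
    if b.size == 0:
        raise ValueError("need at least one neuron")
    return float(b.mean())


def classify_pattern(V: np.ndarray, spikes: np.ndarray, fs: float,
                     t_record: float, skip_excess: float = 1.2,
                     tonic_cv: float = 0.1) -> int:
    """Firing-pattern code 0..6 for one neuron (total and deterministic).

    Rate bands first (6: > 50/s, 5: 20-50/s); then burst firing (4) when
    most events carry >= 2 spikes; skipping (2) when slow cycles outnumber
    events by >= 20%; else regular tonic (3).  Irregular non-bursting
    firing that skips no cycles is classed with skipping (2) unless its
    ISI CV is below ``tonic_cv``.
    """
    spikes = np.asarray(spikes, dtype=float)
    period = estimate_slow_period(V, fs)
    if spikes.size == 0:
        return 1 if period is not None else 0
    fr = firing_rate(spikes, t_record)
    if fr > 50.0:
        return 6
    if fr >= 20.0:
        return 5
    events = group_events(spikes, slow_period=period)
    if burst_fraction(events) > 0.5:
        return 4
    if period is not None:
        n_cycles = t_record / period
        if n_cycles >= skip_excess * len(events):
            return 2
    if spikes.size >= 3:
        isis = np.diff(spikes)
        cv = isis.std() / isis.mean()
        if cv >= tonic_cv:
            return 2
    return 3


@dataclass
class ParameterScanPoint:
    g_sd: float
    g_sr: float
    g_h: float
    mle: float = np.nan
    mle_converged: bool = False
    firing_rate: float = np.nan
    firing_pattern: int = -1
    spikes_per_burst: float = np.nan
    failed: bool = False


def _spikes_per_burst(events: list[np.ndarray]) -> float:
    counts = [len(e) for e in events if len(e) >= 2]
    return float(np.mean(counts)) if counts else np.nan


def scan_parameter_plane(g_sd_values, g_sr_values, g_h: float,
                         base_params: NeuronParameters | None = None,
                         t_transient: float = 3000.0, t_record: float = 10000.0,
                         mle_policy: str = "band", mle_band: tuple = (3.0, 4.5),
                         mle_t_transient: float = 3000.0,
                         mle_t_average: float = 15000.0,
                         seed: int = 0) -> pd.DataFrame:
    """Characterize every (g_sd, g_sr) grid point at fixed g_h in isolation.

    ``mle_policy``: 'all' estimates the Lyapunov exponent everywhere,
    'band' only where the firing rate falls in ``mle_band`` (the costly
    estimate is needed only where populations are drawn), 'none' skips it.
    Divergent simulations are flagged per point, never abort the scan.
    Deterministic given the seed.
    """
    if len(g_sd_values) < 1 or len(g_sr_values) < 1:
        raise ValueError("need at least one value per axis")
    if mle_policy not in ("all", "band", "none"):
        raise ValueError(f"unknown mle_policy {mle_policy!r}")
    base = base_params or NeuronParameters()
    points = []
    for i, gsd in enumerate(g_sd_values):
        for j, gsr in enumerate(g_sr_values):
            p = base.with_(g_sd=float(gsd), g_sr=float(gsr), g_h=float(g_h))
            pt = ParameterScanPoint(g_sd=float(gsd), g_sr=float(gsr), g_h=float(g_h))
            try:
                rec = integrate(p, t_transient=t_transient, t_record=t_record)
            except SimulationDivergedError:
                pt.failed = True
                points.append(pt)
                continue
            sp = rec.spikes[0]
            pt.firing_rate = firing_rate(sp, t_record)
            pt.firing_pattern = classify_pattern(rec.V_traces[0], sp, rec.fs, t_record)
            if pt.firing_pattern == 4:
                pt.spikes_per_burst = _spikes_per_burst(
                    group_events(sp, V_trace=rec.V_traces[0], fs=rec.fs))
            want_mle = mle_policy == "all" or (
                mle_policy == "band" and mle_band[0] <= pt.firing_rate <= mle_band[1])
            if want_mle:
                est = neuron_mle(p, t_transient=mle_t_transient,
                                 t_average=mle_t_average,
                                 seed=seed + 7919 * i + j)
                pt.mle = est.mle
                pt.mle_converged = est.converged
            points.append(pt)
    return pd.DataFrame([vars(pt) for pt in points])


@dataclass
class MatchedPopulations:
    """Chaotic / non-chaotic / NoIh parameter sets with identical per-bin
    firing-rate histograms (0.1 Hz bins)."""

    populations: dict[str, pd.DataFrame]
    rate_bins: np.ndarray
    n_per_bin: int
    ks_pvalues: dict[tuple[str, str], float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> pd.DataFrame:
        return self.populations[key]

    def labels(self) -> list[str]:
        return list(self.populations)


def sample_matched_populations(regions: dict[str, pd.DataFrame],
                               rate_band: tuple[float, float] = (3.0, 4.5),
                               bin_width: float = 0.1,
                               n_per_bin: int | None = None,
                               seed: int = 0) -> MatchedPopulations:
    """Draw equal per-rate-bin counts of parameter sets from each region.

    ``regions`` maps a label (e.g. 'chaotic') to a scan frame already
    restricted to that region; rows outside ``rate_band`` are dropped.
    The per-bin draw count is the minimum bin occupancy over all regions
    (capped at ``n_per_bin`` if given; a warning is issued if the request
    had to shrink).  A bin empty in any region raises
    ``InfeasibleMatchingError``.  Pairwise Kolmogorov-Smirnov tests on the
    drawn firing rates are reported.
    """
    lo, hi = rate_band
    edges = np.round(np.arange(lo, hi + bin_width / 2, bin_width), 10)
    n_bins = len(edges) - 1
    rng = np.random.default_rng(seed)
    binned: dict[str, list[pd.DataFrame]] = {}
    empty: dict[str, list[float]] = {}
    for label, df in regions.items():
        sub = df[(df.firing_rate >= lo) & (df.firing_rate < hi) & ~df.get("failed", False)]
        groups = []
        for b in range(n_bins):
            sel = sub[(sub.firing_rate >= edges[b]) & (sub.firing_rate < edges[b + 1])]
            if len(sel) == 0:
                empty.setdefault(label, []).append(float(edges[b]))
            groups.append(sel)
        binned[label] = groups
    if empty:
        raise InfeasibleMatchingError(empty)
    avail = min(min(len(g) for g in groups) for groups in binned.values())
    take = avail if n_per_bin is None else min(n_per_bin, avail)
    if n_per_bin is not None and take < n_per_bin:
        warnings.warn(f"per-bin count shrunk from {n_per_bin} to {take} "
                      "(limited by the sparsest region bin)")
    pops = {}
    for label, groups in binned.items():
        picks = [g.iloc[rng.choice(len(g), size=take, replace=False)] for g in groups]
        pops[label] = pd.concat(picks, ignore_index=True)
    ks = {}
    labels = list(pops)
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            res = stats.ks_2samp(pops[labels[a]].firing_rate,
                                 pops[labels[b]].firing_rate)
            ks[(labels[a], labels[b])] = float(res.pvalue)
    return MatchedPopulations(populations=pops, rate_bins=edges,
                              n_per_bin=take, ks_pvalues=ks)


def split_by_chaos(scan: pd.DataFrame, tol: float = NOISE_BAND) -> dict[str, pd.DataFrame]:
    """Split a scan frame into chaotic (MLE above the estimator noise band)
    and non-chaotic (at or below it) regions."""
    has_mle = scan.dropna(subset=["mle"])
    cls = has_mle.mle.map(lambda m: classify_chaotic(m, tol=tol))
    return {"chaotic": has_mle[cls == "chaotic"].reset_index(drop=True),
            "non_chaotic": has_mle[cls == "non_chaotic"].reset_index(drop=True)}
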