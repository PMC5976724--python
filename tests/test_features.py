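"""Firing-rate statistics, event/burst grouping, pattern codes, scans and
matched-population sampling."""

import numpy as np
import pandas as pd
import pytest

from chaosnet.features import (InfeasibleMatchingError, burst_fraction,
                               classify_pattern, firing_rate, group_events,
                               mean_burst_fraction, sample_matched_populations,
                               scan_parameter_plane, split_by_chaos)
from chaosnet.model import NeuronParameters
from chaosnet.simulate import detect_spikes
from chaosnet.surrogates import SurrogateSpec, generate


@pytest.mark.parametrize("n, t_ms, rate", [(0, 10000, 0.0), (35, 10000, 3.5),
                                           (80, 10000, 8.0)])
def test_firing_rate(n, t_ms, rate):
    assert firing_rate(np.arange(n), t_ms) == pytest.approx(rate)


def test_firing_rate_rejects_zero_duration():
    with pytest.raises(ValueError):
        firing_rate(np.array([1.0]), 0.0)


def test_group_events_and_burst_fraction():
    """3 bursts of 3 spikes + 2 singles -> 5 events, 3 bursts, b = 0.6."""
    spikes = np.array([100.0, 110.0, 120.0, 400.0, 700.0, 710.0, 720.0,
                       1000.0, 1300.0, 1310.0, 1320.0])
    events = group_events(spikes, slow_period=300.0)
    assert [len(e) for e in events] == [3, 1, 3, 1, 3]
    assert burst_fraction(events) == pytest.approx(0.6)


def test_group_events_singletons():
    events = group_events(np.array([0.0, 500.0, 1000.0]), slow_period=300.0)
    assert len(events) == 3
    assert burst_fraction(events) == 0.0
    assert group_events(np.array([])) == []


def test_mean_burst_fraction():
    assert mean_burst_fraction([0.0, 0.0]) == 0.0
    assert mean_burst_fraction([0.0, 1.0, 0.0, 1.0]) == 0.5
    vals = [0.1, 0.5, 0.7, 0.2]
    oracle = sum(vals) / len(vals)
    assert mean_burst_fraction(vals) == pytest.approx(oracle)
    with pytest.raises(ValueError):
        mean_burst_fraction([])


def _surrogate_code(kind_params, duration=10000.0):
    data, _ = generate(SurrogateSpec("spike_train", N=1, duration_ms=duration,
                                     params=kind_params))
    sp = detect_spikes(data["V"][0], fs=data["fs"])
    return classify_pattern(data["V"][0], sp, data["fs"], duration)


def test_classify_pattern_codes():
    # flat -> 0, subthreshold sine -> 1
    assert classify_pattern(np.full(8000, -60.0), np.array([]), 1000.0, 8000) == 0
    sub, _ = generate(SurrogateSpec("subthreshold", N=1, duration_ms=8000))
    assert classify_pattern(sub["V"][0], np.array([]), sub["fs"], 8000) == 1
    # regular tonic at 4/s -> 3; bursts of 3 -> 4
    assert _surrogate_code(dict(rate_hz=4.0)) == 3
    assert _surrogate_code(dict(rate_hz=4.0, spikes_per_burst=3)) == 4
    # skipping: slow cycles at 4 Hz, spikes on every other cycle -> 2
    assert _surrogate_code(dict(rate_hz=4.0, spike_every=2)) == 2
    # rate bands: 30/s -> 5, 60/s -> 6
    assert _surrogate_code(dict(rate_hz=30.0, sub_amp_mv=2.0)) == 5
    assert _surrogate_code(dict(rate_hz=60.0, sub_amp_mv=2.0)) == 6


def test_scan_small_grid(default_params):
    scan = scan_parameter_plane([0.21, 0.25], [0.24, 0.28], g_h=0.4,
                                t_transient=1000.0, t_record=4000.0,
                                mle_policy="none")
    assert len(scan) == 4
    assert not scan.failed.any()
    assert (scan.firing_rate > 0).all()
    assert set(scan.firing_pattern) <= set(range(7))
    # the reference point appears with the firing rate of a standalone run
    from chaosnet import integrate
    solo = integrate(default_params.with_(g_sd=0.21, g_sr=0.28),
                     t_transient=1000.0, t_record=4000.0)
    row = scan[(scan.g_sd == 0.21) & (scan.g_sr == 0.28)].iloc[0]
    assert row.firing_rate == pytest.approx(firing_rate(solo.spikes[0], 4000.0))


def test_scan_rejects_bad_policy():
    with pytest.raises(ValueError):
        scan_parameter_plane([0.2], [0.3], 0.4, mle_policy="sometimes")


def _toy_region(rates, seed=0):
    rng = np.random.default_rng(seed)
    n = len(rates)
    return pd.DataFrame(dict(
        g_sd=rng.uniform(0.2, 0.3, n), g_sr=rng.uniform(0.2, 0.3, n),
        g_h=np.full(n, 0.4), firing_rate=np.asarray(rates, dtype=float),
        mle=np.zeros(n), failed=np.zeros(n, dtype=bool)))


def test_matched_sampling_identical_regions():
    rates = np.repeat(np.arange(3.0, 4.5, 0.1), 3)
    regions = {k: _toy_region(rates, seed=i) for i, k in
               enumerate(["chaotic", "non_chaotic", "noih"])}
    mp = sample_matched_populations(regions, seed=1)
    assert mp.n_per_bin == 3
    assert len(mp.rate_bins) == 16          # 15 bins spanning 3.0-4.5 Hz
    hists = [np.histogram(mp[k].firing_rate, bins=mp.rate_bins)[0]
             for k in mp.labels()]
    assert all(np.array_equal(h, hists[0]) for h in hists)
    assert all(p == pytest.approx(1.0) for p in mp.ks_pvalues.values())


def test_matched_sampling_shrinks_with_warning():
    rates = np.repeat(np.arange(3.0, 4.5, 0.1), 2)
    regions = {"a": _toy_region(rates), "b": _toy_region(rates, 1)}
    with pytest.warns(UserWarning, match="shrunk"):
        mp = sample_matched_populations(regions, n_per_bin=5, seed=0)
    assert mp.n_per_bin == 2


def test_matched_sampling_reports_empty_bins():
    good = np.repeat(np.arange(3.0, 4.5, 0.1), 2)
    bad = good[good > 3.25]    # bins 3.0-3.2 empty in region b
    with pytest.raises(InfeasibleMatchingError) as exc:
        sample_matched_populations({"a": _toy_region(good),
                                    "b": _toy_region(bad)}, seed=0)
    assert 3.0 in exc.value.bins_by_region["b"]


def test_split_by_chaos():
    df = _toy_region(np.linspace(3.0, 4.4, 10))
    df["mle"] = np.linspace(-4e-3, 5e-3, 10)
    parts = split_by_chaos(df)
    assert (parts["chaotic"].mle > 2e-3).all()
    assert (parts["non_chaotic"].mle <= 2e-3).all()
    assert len(parts["chaotic"]) + len(parts["non_chaotic"]) == 10
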