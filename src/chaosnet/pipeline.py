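"""End-to-end experiment orchestration: population -> g-sweep -> metrics.

For every (population, gap conductance g, network seed) the pipeline
builds a Newman-Watts network (topology seeds shared across populations
and g values, so conditions are compared on the same set of connectivity
matrices), draws node parameters from the population, integrates, and
measures synchrony (R), metastability (chi), optionally the network MLE,
the FCD multi-stability variance and the mean burst fraction.  Results
aggregate across seeds only (never across time) as mean with SD and SEM.

Profiles: the full study runs N = 250 with 10-20 seeds overnight; the
``test`` profile (N = 50, 3 seeds, shorter records) exercises the same
code at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fcd import fc_windows, fcd_matrix, multistability_variance, DEFAULT_EXCLUDE_BAND
from .features import burst_fraction, estimate_slow_period, group_events, mean_burst_fraction
from .lyapunov import network_mle
from .model import NeuronParameters
from .network import NetworkSpec
from .simulate import integrate
from .synchrony import extract_phase, synchrony_metrics

__all__ = ["SweepConfig", "run_sweep", "aggregate_runs", "compare_conditions",
           "default_g_grid", "population_to_params"]


def default_g_grid(n_log: int = 25) -> np.ndarray:
    """0 plus log-spaced gap conductances in [1e-4, 1] (mS/cm^2)."""
    return np.concatenate([[0.0], np.geomspace(1e-4, 1.0, n_log)])


@dataclass
class SweepConfig:
    populations: dict                     # label -> scan frame or [NeuronParameters]
    g_values: np.ndarray = field(default_factory=default_g_grid)
    N: int = 250
    K: int = 5
    p: float = 0.1
    n_seeds: int = 10
    dt: float = 0.025
    t_transient: float = 5000.0
    t_record: float = 30000.0
    record_every_ms: float = 1.0
    v_jitter: float = 5.0
    compute_mle: bool = False
    mle_t_average: float = 10000.0
    compute_fcd: bool = True
    fcd_width_ms: float = 2000.0
    fcd_overlap: float = 0.9
    fcd_exclude_band: int = DEFAULT_EXCLUDE_BAND
    compute_bursts: bool = False
    out_dir: str | Path | None = None
    base_seed: int = 0

    def __post_init__(self):
        g = np.asarray(self.g_values, dtype=float)
        if np.any(g < 0) or np.any(np.diff(g) < 0):
            raise ValueError("g values must be non-negative and sorted")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        self.g_values = g


def population_to_params(population, N: int, seed: int) -> list[NeuronParameters]:
    """Draw N per-node parameter sets from a population (scan frame with
    g_sd/g_sr/g_h columns, or an explicit list), with replacement."""
    rng = np.random.default_rng(seed)
    if isinstance(population, pd.DataFrame):
        idx = rng.integers(len(population), size=N)
        return [NeuronParameters(g_sd=float(r.g_sd), g_sr=float(r.g_sr),
                                 g_h=float(r.g_h))
                for r in population.iloc[idx].itertuples()]
    population = list(population)
    idx = rng.integers(len(population), size=N)
    return [population[i] for i in idx]


def _run_one(cfg: SweepConfig, label: str, g: float, i_seed: int) -> dict:
    seed_topology = cfg.base_seed + i_seed
    seed_params = cfg.base_seed + 104729 + i_seed
    seed_init = cfg.base_seed + 1299709 + i_seed
    params = population_to_params(cfg.populations[label], cfg.N, seed_params)
    spec = NetworkSpec.build(cfg.N, cfg.K, cfg.p, g, params,
                             seed_topology=seed_topology, seed_params=seed_params)
    rec = integrate(spec, dt=cfg.dt, t_transient=cfg.t_transient,
                    t_record=cfg.t_record, record_every_ms=cfg.record_every_ms,
                    v_jitter=cfg.v_jitter, seed=seed_init)
    ens = extract_phase(rec.V_traces, rec.fs)
    met = synchrony_metrics(ens)
    row = dict(population=label, g=g, seed=i_seed, R=met.R, chi=met.chi,
               mle=np.nan, fcd_variance=np.nan, mb=np.nan)
    if cfg.compute_mle:
        est = network_mle(spec, dt=cfg.dt, t_transient=cfg.t_transient,
                          t_average=cfg.mle_t_average, seed=seed_init,
                          v_jitter=cfg.v_jitter)
        row["mle"] = est.mle
    if cfg.compute_fcd:
        fcs = fc_windows(ens, width_ms=cfg.fcd_width_ms, overlap=cfg.fcd_overlap)
        row["fcd_variance"] = multistability_variance(
            fcd_matrix(fcs), exclude_band=cfg.fcd_exclude_band)
    if cfg.compute_bursts:
        bs = []
        for n in range(rec.N):
            period = estimate_slow_period(rec.V_traces[n], rec.fs)
            bs.append(burst_fraction(group_events(rec.spikes[n], slow_period=period)))
        row["mb"] = mean_burst_fraction(bs)
    return row


def run_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """Execute the sweep; returns one row per (population, g, seed).

    With ``cfg.out_dir`` set, completed runs are read back from
    ``runs.csv`` and skipped, making the sweep resumable; failed runs are
    logged and excluded (never silently averaged over).
    """
    done = pd.DataFrame()
    path = None
    if cfg.out_dir is not None:
        path = Path(cfg.out_dir) / "runs.csv"
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.exists():
            done = pd.read_csv(path)
    rows = list(done.to_dict("records"))
    have = {(r["population"], round(float(r["g"]), 12), int(r["seed"])) for r in rows}
    n_failed = 0
    for label in cfg.populations:
        for g in cfg.g_values:
            for i_seed in range(cfg.n_seeds):
                key = (label, round(float(g), 12), i_seed)
                if key in have:
                    continue
                try:
                    row = _run_one(cfg, label, float(g), i_seed)
                except Exception as exc:   # per-run failures must not kill the sweep
                    n_failed += 1
                    warnings.warn(f"run {key} failed: {exc!r}")
                    continue
                rows.append(row)
                if path is not None:
                    pd.DataFrame(rows).to_csv(path, index=False)
    if n_failed:
        warnings.warn(f"{n_failed} run(s) failed and were excluded")
    return pd.DataFrame(rows)


def aggregate_runs(runs: pd.DataFrame) -> pd.DataFrame:
    """Per-(population, g) mean, SD and SEM across seeds."""
    out = []
    for (label, g), grp in runs.groupby(["population", "g"]):
        row = dict(population=label, g=g, n=len(grp))
        for col in ("R", "chi", "mle", "fcd_variance", "mb"):
            vals = grp[col].dropna().to_numpy()
            row[f"{col}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{col}_sd"] = vals.std(ddof=1) if vals.size > 1 else np.nan
            row[f"{col}_sem"] = (vals.std(ddof=1) / np.sqrt(vals.size)
                                 if vals.size > 1 else np.nan)
        out.append(row)
    return pd.DataFrame(out).sort_values(["population", "g"]).reset_index(drop=True)


def compare_conditions(curves: dict[str, pd.DataFrame],
                       metrics: tuple[str, ...] = ("R", "chi", "mle", "fcd_variance")
                       ) -> pd.DataFrame:
    """Per-g differences of aggregated means between conditions.

    All curves must share the same g grid; rows are (g, metric,
    label_a - label_b difference) with the seed-level SDs carried along.
    """
    labels = list(curves)
    base = curves[labels[0]]
    for lab in labels[1:]:
        if not np.allclose(curves[lab].g.to_numpy(), base.g.to_numpy()):
            raise ValueError("curves have mismatched g grids")
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ca, cb = curves[labels[a]], curves[labels[b]]
            for m in metrics:
                for i in range(len(base)):
                    rows.append(dict(
                        g=float(base.g.iloc[i]), metric=m,
                        pair=f"{labels[a]}-{labels[b]}",
                        difference=float(ca[f"{m}_mean"].iloc[i] - cb[f"{m}_mean"].iloc[i]),
                        sd_a=float(ca[f"{m}_sd"].iloc[i]),
                        sd_b=float(cb[f"{m}_sd"].iloc[i])))
    return pd.DataFrame(rows)
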