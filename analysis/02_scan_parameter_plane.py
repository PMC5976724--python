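#!/usr/bin/env python
"""Scan the slow-conductance (g_sd, g_sr) plane at g_h = 0.4 and g_h = 0
(NoIh), recording firing rate, firing pattern and — where the rate falls
in the matched 3.0-4.5 spikes/s band — the maximal Lyapunov exponent.

The NoIh plane contains no chaos; in the g_h = 0.4 plane chaos hugs the
boundary between firing and silence.  Writes results/scan_gh04.csv and
results/scan_noih.csv (inputs of 03_match_populations.py).

--profile test uses the shipped desk-scale grids (~4 min); --profile
paper refines both grid and averaging times (overnight-scale).
"""

import argparse
from pathlib import Path

import numpy as np

from chaosnet.features import DEFAULT_SCAN_REGIONS, scan_parameter_plane
from chaosnet.lyapunov import NOISE_BAND


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--profile", choices=["test", "paper"], default="test")
    args = ap.parse_args()

    long_run = args.profile == "paper"
    kw = dict(seed=args.seed,
              t_record=20000.0 if long_run else 10000.0,
              mle_t_average=50000.0 if long_run else 15000.0)
    args.out.mkdir(parents=True, exist_ok=True)
    for name, key in [("scan_gh04", "gsd_gsr"), ("scan_noih", "noih")]:
        reg = DEFAULT_SCAN_REGIONS[key]
        gsd, gsr = reg["g_sd"], reg["g_sr"]
        if long_run:
            gsd = np.linspace(gsd[0], gsd[-1], 2 * len(gsd))
            gsr = np.linspace(gsr[0], gsr[-1], 2 * len(gsr))
        scan = scan_parameter_plane(gsd, gsr, g_h=reg["g_h"], **kw)
        scan.to_csv(args.out / f"{name}.csv", index=False)
        inband = scan.dropna(subset=["mle"])
        print(f"{name}: {len(scan)} points, {len(inband)} in the 3.0-4.5 "
              f"spikes/s band, {(inband.mle > NOISE_BAND).sum()} chaotic")
    print(f"wrote scans under {args.out}/")


if __name__ == "__main__":
    main()
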