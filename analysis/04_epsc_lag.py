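#!/usr/bin/env python
"""EPSC threshold conductances and the EPSP-to-AP lag grid.

A somatic conductance EPSC (0.5 ms time-to-peak, 3 ms decay, reversal
0 mV) is ramped from 6 to 11 nS in 0.25 nS steps for the human-type AIS
(30 um, no Kv1) and mouse-type AIS (10 um, 20 nS/um^2 Kv1); then the lag
from EPSC onset to AP onset at a fixed 8.5 nS input is mapped over the
length x Kv1 grid.

Outputs: results/epsc_thresholds.csv, results/lag_grid.csv,
results/lag_grid.png
"""

from pathlib import Path

import pandas as pd

import fsneuron as fs
from fsneuron.cli import _render_heatmap
from fsneuron.experiments import SweepSpec, sweep_epsc_lag
from fsneuron.protocols import EPSCProtocol, find_threshold_epsc

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

LENGTHS = [10.0, 12.5, 15.0, 17.5, 20.0, 22.5, 25.0, 27.5, 30.0]
GKV1 = [0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0, 17.5, 20.0]


def main() -> None:
    config = fs.standard_config()
    proto = EPSCProtocol()
    rows = []
    for tag, L, gk in (("human-type", 30.0, 0.0), ("mouse-type", 10.0, 20.0)):
        cell = fs.build_cell(fs.with_overrides(config, {
            "ais": {"length_um": L, "gkv1_nS_per_um2": gk}}))
        g, lags = find_threshold_epsc(cell, proto)
        rows.append({"ais_type": tag, "ais_length_um": L, "gkv1_nS_per_um2": gk,
                     "g_threshold_nS": g, "lag_at_8p5_nS_ms": lags.get(8.5)})
        print(f"{tag}: EPSC threshold {g} nS; lag at 8.5 nS = {lags.get(8.5)} ms")
    pd.DataFrame(rows).to_csv(RESULTS / "epsc_thresholds.csv", index=False)

    spec = SweepSpec(axes={"ais_length": LENGTHS, "gkv1": GKV1},
                     scope="epsc_lag", epsc_g_peak=8.5)
    res = sweep_epsc_lag(config, spec)
    res.table.to_csv(RESULTS / "lag_grid.csv", index=False)
    ok = res.ok()
    print(f"lag grid: {len(ok)}/{len(res.table)} points spiked; "
          f"lags {ok['lag_ms'].min():.1f} to {ok['lag_ms'].max():.1f} ms")
    _render_heatmap(res.table, spec.axes, "epsc_lag", RESULTS / "lag_grid.png")


if __name__ == "__main__":
    main()
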