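#!/usr/bin/env python
"""Calibrate the standard model and characterize its baseline physiology.

Runs the coordinate-descent calibration against the baseline targets
(AP threshold -43 mV, input resistance and apparent tau inside the human
interquartile ranges, resting potential near the leak reversal), then
records the calibrated cell's rheobase, threshold, latency, passive
features and an example suprathreshold voltage trace.

Outputs: results/calibration.json, results/baseline_features.csv,
results/baseline_trace.csv
"""

import json
from pathlib import Path

import pandas as pd

import fsneuron as fs
from fsneuron.experiments import calibrate_baseline, measure_threshold
from fsneuron.features import ap_features, detect_aps
from fsneuron.io import write_trace
from fsneuron.protocols import StepProtocol

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    config, report = calibrate_baseline()
    print(f"calibration converged in {report.iterations} iterations; "
          f"scales {report.scales}")
    with open(RESULTS / "calibration.json", "w") as f:
        json.dump({"iterations": report.iterations, "converged": report.converged,
                   "scales": report.scales, "measured": report.measured}, f, indent=2)

    cell = fs.build_cell(config)
    rheo, thr, lat = measure_threshold(cell)
    tr = fs.integrate(cell, StepProtocol(amplitude=rheo, duration=250.0))
    ap = detect_aps(tr)[0]
    feats = ap_features(tr, ap)
    feats.rheobase, feats.latency = rheo, lat

    row = {**feats.as_dict(), "rin_MOhm": report.measured["rin"],
           "tau_ms": report.measured["tau"], "v_rest_mV": report.measured["v_rest"]}
    pd.DataFrame([row]).to_csv(RESULTS / "baseline_features.csv", index=False)
    # decimate the stored trace to 0.2 ms sampling to keep the CSV small
    import fsneuron.cell as _cell

    dec = _cell.VoltageTrace(dt=tr.dt * 20, t0=tr.t0, vm=tr.vm[::20],
                             channels=tr.channels, i_stim=tr.i_stim[::20],
                             g_syn=tr.g_syn[::20], metadata=tr.metadata)
    write_trace(dec, RESULTS / "baseline_trace.csv")

    print(f"standard cell: threshold {thr:.2f} mV at rheobase {rheo:.0f} pA "
          f"(latency {lat:.1f} ms); Rin {report.measured['rin']:.0f} MOhm, "
          f"tau {report.measured['tau']:.2f} ms")
    print(f"AP: peak {feats.peak:.1f} mV, half-width {feats.half_width:.3f} ms, "
          f"max rise {feats.max_rise:.0f} mV/ms, max fall {feats.max_fall:.0f} mV/ms")


if __name__ == "__main__":
    main()
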