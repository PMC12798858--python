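#!/usr/bin/env python
"""Single-axis AIS sweeps: threshold vs AIS length and vs Kv1 density.

Longer AIS (total Nav1.6 and Kv1 scaling with length) lowers the AP
firing threshold; raising Kv1 density at fixed geometry raises it.

Outputs: results/sweep_ais_length.csv, results/sweep_gkv1.csv
"""

from pathlib import Path

from fsneuron import standard_config
from fsneuron.experiments import SweepSpec, sweep_threshold

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    config = standard_config()

    lengths = SweepSpec(axes={"ais_length": [10.0, 15.0, 20.0, 25.0, 30.0]})
    res = sweep_threshold(config, lengths)
    res.table.to_csv(RESULTS / "sweep_ais_length.csv", index=False)
    print(res.table[["ais_length", "threshold_mV", "rheobase_pA", "status"]]
          .to_string(index=False))

    kv1 = SweepSpec(axes={"gkv1": [0.0, 5.0, 10.0, 15.0, 20.0]})
    res = sweep_threshold(config, kv1)
    res.table.to_csv(RESULTS / "sweep_gkv1.csv", index=False)
    print(res.table[["gkv1", "threshold_mV", "rheobase_pA", "status"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
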