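# fsneuron

Conductance-based model of a neocortical fast-spiking (parvalbumin)
interneuron with a parameterizable axon initial segment (AIS), plus the
electrophysiological feature definitions needed to analyse it the way
whole-cell recordings are analysed.

## The scientific problem

Human fast-spiking interneurons differ from their mouse counterparts in
two AIS properties: the AIS is moderately longer, and it is nearly devoid
of low-voltage-activated Kv1 potassium channels that are prominent in
mouse cells.  Human cells also fire at a more hyperpolarized threshold
despite electrically slower somata.  This package implements the
simulation side of that story: a three-section cable model (point soma,
140 × 0.8 µm axon carrying the AIS, 200 × 1 µm dendrite) with
Hodgkin–Huxley-style currents

    I_i = g_i · m_i^p · h_i · (E_i − V),      dx/dt = (x_inf(V) − x)/tau_x(V)

(sigmoidal steady states, bell-shaped time constants), Nav1.6 and Kv1
confined to the AIS, Nav1.2 in the soma/proximal dendrite, Kv3
repolarizing currents, and leak/M/Kir/Ih background conductances.  The
model lets you ask how AIS length, Kv1 density, AIS position, axon
diameter and axial resistance move two quantities: the AP firing
threshold (defined operationally as the membrane potential where dV/dt
first reaches 10 mV/ms on the phase plot) and the lag from a somatic
EPSC to the AP it triggers.

The package contains:

* `fsneuron.kinetics` / `fsneuron.cell` — gating maths and the
  discretized cable integrator (implicit voltage step, exponential-Euler
  gates, compiled with numba);
* `fsneuron.protocols` — square-pulse steps, bisection rheobase search,
  dual-exponential EPSC conductance injection;
* `fsneuron.features` — phase-plot threshold detection, AP waveform
  features, input resistance and apparent membrane time constant, per the
  operational definitions used for patch-clamp data;
* `fsneuron.experiments` — baseline calibration (deterministic coordinate
  descent) and the AIS parameter sweeps;
* `fsneuron.synthetic` — synthetic traces with exact ground truth and
  quantile-matched feature cohorts, used to validate the feature
  extractor;
* `fsneuron.io` / `fsneuron.cli` — strict config validation, CSV trace
  I/O, and the `fsneuron` command-line tool;
* `analysis/` — numbered driver scripts that run the full simulation
  program and write tables under `results/`.

## Worked example

```python
import fsneuron as fs
from fsneuron.experiments import measure_threshold, SweepSpec, sweep_threshold

config = fs.standard_config()          # shipped calibrated standard model
cell = fs.build_cell(config)

rheo, thr, lat = measure_threshold(cell)
print(f"rheobase {rheo:.0f} pA, threshold {thr:.1f} mV, latency {lat:.1f} ms")

res = sweep_threshold(config, SweepSpec(axes={"ais_length": [10., 20., 30.]}))
print(res.table[["ais_length", "threshold_mV"]])
```

prints (phase-plot threshold at the 10 mV/ms criterion, 250-ms steps from
−70 mV, 1-pA rheobase bisection):

```
rheobase 54 pA, threshold -42.8 mV, latency 34.0 ms
   ais_length  threshold_mV
0        10.0    -35.828583
1        20.0    -42.833073
2        30.0    -47.009216
```

A longer AIS (total Nav1.6/Kv1 conductance scaling with length) lowers
the firing threshold by several millivolts — the model's core behaviour.
The same machinery drives the Kv1-density series, the joint
length × Kv1 threshold and EPSC-lag heatmaps, and the axon geometry
sweeps; run the numbered scripts in `analysis/` to generate all tables
into `results/`:

```bash
python analysis/01_calibrate_baseline.py
python analysis/02_ais_length_and_kv1.py
...
```

The CLI exposes the same operations
(`fsneuron rheobase`, `fsneuron sweep`, `fsneuron epsc-threshold`,
`fsneuron features`, `fsneuron synth`, `fsneuron calibrate`).

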