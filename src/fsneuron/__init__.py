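"""fsneuron: conductance-based fast-spiking interneuron model with a
parameterizable axon initial segment (AIS).

The package simulates a three-section cable model of a parvalbumin
fast-spiking interneuron, measures its electrophysiological features with
the same operational definitions used for whole-cell recordings (phase-plot
threshold at 10 mV/ms, rheobase, half-width, Rin, apparent tau), and runs
the AIS parameter sweeps (length, Kv1/Nav1.6 density, position, axon
geometry) that link AIS composition to spike threshold and EPSP-to-AP lag.
"""

from importlib import resources as _resources

import yaml as _yaml

from .cell import (
    AISSpec,
    CellModel,
    CompartmentGeometry,
    ConfigError,
    IntegrationError,
    VoltageTrace,
    build_cell,
    integrate,
    solve_holding_bias,
)
from .kinetics import (
    ChannelSpec,
    GateKinetics,
    GateState,
    channel_current,
    gate_derivative,
    steady_state,
    time_constant,
)

__version__ = "0.1.0"


def standard_config() -> dict:
    """The shipped standard (human-calibrated) model configuration."""
    with _resources.files("fsneuron.params").joinpath("standard_human.yaml").open() as f:
        return _yaml.safe_load(f)


def with_overrides(config: dict, overrides: dict) -> dict:
    """Deep-merged copy of ``config`` with ``overrides`` applied."""
    import copy

    out = copy.deepcopy(config)

    def merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    merge(out, overrides)
    return out
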