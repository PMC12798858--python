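"""Shared fixtures: the standard model, a fast miniature cell, passive variants."""

import numpy as np
import pytest

import fsneuron as fs


@pytest.fixture(scope="session")
def standard_cfg():
    return fs.standard_config()


@pytest.fixture(scope="session")
def standard_cell(standard_cfg):
    return fs.build_cell(standard_cfg)


@pytest.fixture(scope="session")
def small_cfg(standard_cfg):
    """Miniature active cell (short sections, coarse grid) for fast tests."""
    return fs.with_overrides(standard_cfg, {
        "geometry": {
            "axon": {"length_um": 60.0, "segment_length_um": 3.0},
            "dendrite": {"length_um": 80.0, "segment_length_um": 8.0},
        },
        "ais": {"start_um": 6.0, "length_um": 12.0},
    })


@pytest.fixture(scope="session")
def small_cell(small_cfg):
    return fs.build_cell(small_cfg)


def soma_only_config(resistance_MOhm=700.0, cm_pF=25.0, e_leak=-68.0):
    """Isolated passive soma: no cables, no active channels."""
    return {
        "geometry": {
            "soma": {"cm_total_pF": cm_pF, "leak_resistance_MOhm": resistance_MOhm},
            "e_leak_mV": e_leak,
        },
        "channels": {},
    }


def passive_cable_config(standard_cfg):
    """Full standard geometry with every voltage-gated conductance removed."""
    cfg = fs.with_overrides(standard_cfg, {
        "ais": {"gnav16_nS_per_um2": 0.0, "gkv1_nS_per_um2": 0.0},
    })
    for name, ch in cfg["channels"].items():
        if ch["p"] > 0:
            ch["regions"] = {k: 0.0 for k, v in ch["regions"].items()
                             if not isinstance(v, str)}
    return cfg


@pytest.fixture(scope="session")
def passive_soma_cell():
    return fs.build_cell(soma_only_config())


@pytest.fixture(scope="session")
def passive_cable_cfg(standard_cfg):
    return passive_cable_config(standard_cfg)
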