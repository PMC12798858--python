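"""Three-section fast-spiking interneuron model with a parameterizable AIS.

The cell is a point soma flanked by two discretized cylinders: an axon
carrying the axon initial segment (AIS) as a contiguous subregion, and a
dendrite.  Nodes form one unbranched chain

    dendrite tip ... dendrite ... SOMA ... axon ... axon tip

so the discretized cable operator is tridiagonal.  Axial resistance is
specified per unit cable length (MOhm/um): a segment of length dx
contributes dx * Ra MOhm in series.

Channel placement follows the model's regional layout: Nav1.6 and Kv1 in
the AIS (densities set by the AIS spec, total conductance scaling linearly
with AIS length), Nav1.2 in soma and proximal dendrite, Kv3 in AIS, soma
and dendrite, and leak/M/Kir/Ih in soma and dendrite.

Units: mV, ms, nS, pA, pF, um (1/MOhm = 1000 nS).
"""

from __future__ import annotations

import copy
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _engine
from .kinetics import ChannelSpec, GateKinetics

__all__ = [
    "ConfigError",
    "IntegrationError",
    "CompartmentGeometry",
    "AISSpec",
    "CellModel",
    "VoltageTrace",
    "build_cell",
    "solve_holding_bias",
    "integrate",
]


class ConfigError(ValueError):
    """Invalid model configuration; message names the offending field."""


class IntegrationError(RuntimeError):
    """Numerical divergence during integration."""


# --------------------------------------------------------------------------
# geometry types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentGeometry:
    """Geometry of one cylinder section (soma is held separately)."""

    length: float              # um
    diameter: float            # um
    segment_length: float      # um
    cm_per_area: float         # fF/um^2
    ra_per_length: float       # MOhm per um of cable

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigError(f"cylinder length must be > 0, got {self.length}")
        if self.diameter <= 0:
            raise ConfigError(f"cylinder diameter must be > 0, got {self.diameter}")
        if not 0 < self.segment_length <= self.length:
            raise ConfigError(
                f"segment_length {self.segment_length} must be in (0, length={self.length}]"
            )
        if self.cm_per_area <= 0:
            raise ConfigError("cm_per_area must be > 0")
        if self.ra_per_length <= 0:
            raise ConfigError("ra_per_length must be > 0")

    @property
    def n_segments(self) -> int:
        return int(round(self.length / self.segment_length))

    @property
    def area_per_segment(self) -> float:
        return math.pi * self.diameter * (self.length / self.n_segments)


@dataclass(frozen=True)
class AISSpec:
    """AIS window on the axon plus its two signature channel densities."""

    start: float               # um from soma
    length: float              # um
    gnav16_density: float      # nS/um^2
    gkv1_density: float        # nS/um^2

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ConfigError(f"ais.start must be >= 0, got {self.start}")
        if self.length <= 0:
            raise ConfigError(f"ais.length must be > 0, got {self.length}")
        if self.gnav16_density < 0 or self.gkv1_density < 0:
            raise ConfigError("AIS channel densities must be >= 0")


@dataclass
class VoltageTrace:
    """Uniformly sampled simulated (or synthetic) membrane-potential record."""

    dt: float                          # ms
    t0: float                          # ms
    vm: np.ndarray                     # (T,) or (T, R) mV
    channels: tuple = ("soma",)        # recorded-compartment names
    i_stim: Optional[np.ndarray] = None   # pA
    g_syn: Optional[np.ndarray] = None    # nS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vm = np.atleast_1d(np.asarray(self.vm, dtype=float))
        if self.vm.ndim == 1:
            self.vm = self.vm[:, None]
        for arr in (self.i_stim, self.g_syn):
            if arr is not None and len(arr) != len(self.vm):
                raise ValueError("stimulus and voltage records must have equal length")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.vm))

    @property
    def v_soma(self) -> np.ndarray:
        return self.vm[:, self.channels.index("soma")]

    def __len__(self) -> int:
        return len(self.vm)


# --------------------------------------------------------------------------
# the assembled cell
# --------------------------------------------------------------------------

_REGIONS = ("ais", "soma", "dendrite", "dendrite_proximal")


class CellModel:
    """Discretized cell: per-node capacitances, axial couplings and channels.

    Built by :func:`build_cell`; holds the validated configuration, the
    compiled per-node conductance arrays consumed by the integration
    kernel, and a cache of settled holding states.
    """

    def __init__(self, config: dict):
        self.config = copy.deepcopy(config)
        self._settle_cache: dict = {}
        self._compile()

    # -- construction -----------------------------------------------------

    def _compile(self) -> None:
        cfg = self.config
        geo = cfg["geometry"]
        soma_cfg = geo["soma"]
        self.e_leak = float(geo["e_leak_mV"])

        axon_cfg = geo.get("axon")
        dend_cfg = geo.get("dendrite")
        self.axon = (
            CompartmentGeometry(
                length=axon_cfg["length_um"],
                diameter=axon_cfg["diameter_um"],
                segment_length=axon_cfg["segment_length_um"],
                cm_per_area=axon_cfg["cm_fF_per_um2"],
                ra_per_length=axon_cfg["ra_MOhm_per_um"],
            )
            if axon_cfg
            else None
        )
        self.dendrite = (
            CompartmentGeometry(
                length=dend_cfg["length_um"],
                diameter=dend_cfg["diameter_um"],
                segment_length=dend_cfg["segment_length_um"],
                cm_per_area=dend_cfg["cm_fF_per_um2"],
                ra_per_length=dend_cfg["ra_MOhm_per_um"],
            )
            if dend_cfg
            else None
        )

        ais_cfg = cfg.get("ais")
        if ais_cfg is not None and self.axon is None:
            raise ConfigError("ais requires an axon section")
        self.ais = (
            AISSpec(
                start=ais_cfg["start_um"],
                length=ais_cfg["length_um"],
                gnav16_density=ais_cfg["gnav16_nS_per_um2"],
                gkv1_density=ais_cfg["gkv1_nS_per_um2"],
            )
            if ais_cfg
            else None
        )
        if self.ais is not None:
            if self.ais.start + self.ais.length > self.axon.length + 1e-9:
                raise ConfigError(
                    f"ais.start + ais.length = {self.ais.start + self.ais.length} um "
                    f"extends past axon length {self.axon.length} um"
                )

        nd = self.dendrite.n_segments if self.dendrite else 0
        na = self.axon.n_segments if self.axon else 0
        n = nd + 1 + na
        self.n_nodes = n
        self.soma_idx = nd
        self.n_dend = nd
        self.n_axon = na

        # capacitance
        c = np.empty(n, dtype=np.float64)
        c[self.soma_idx] = float(soma_cfg["cm_total_pF"])
        if c[self.soma_idx] <= 0:
            raise ConfigError("soma cm_total_pF must be > 0")
        if self.dendrite:
            # node j (0..nd-1) is distance (nd - j - 0.5)*dx from soma
            c[:nd] = self.dendrite.area_per_segment * self.dendrite.cm_per_area * 1e-3
        if self.axon:
            c[nd + 1:] = self.axon.area_per_segment * self.axon.cm_per_area * 1e-3

        # axial couplings (nS); soma-to-first-segment sees a half segment
        g_ax = np.empty(n - 1, dtype=np.float64) if n > 1 else np.empty(0)
        if self.dendrite:
            dx = self.dendrite.length / nd
            r_full = self.dendrite.ra_per_length * dx          # MOhm
            g_ax[: nd - 1] = 1e3 / r_full
            g_ax[nd - 1] = 1e3 / (r_full / 2.0)
        if self.axon:
            dx = self.axon.length / na
            r_full = self.axon.ra_per_length * dx
            g_ax[nd] = 1e3 / (r_full / 2.0)
            g_ax[nd + 1:] = 1e3 / r_full
        self.c = c
        self.g_ax = g_ax

        self._compile_channels()

        # recording sites: soma plus AIS midpoint when present
        rec = [self.soma_idx]
        names = ["soma"]
        if self.ais is not None:
            mid = self.ais.start + self.ais.length / 2.0
            rec.append(self.soma_idx + 1 + self._axon_node_at(mid))
            names.append("ais_mid")
        self.rec_idx = np.array(rec, dtype=np.int64)
        self.rec_names = tuple(names)

    def _axon_node_at(self, dist_um: float) -> int:
        dx = self.axon.length / self.axon.n_segments
        return min(int(dist_um / dx), self.axon.n_segments - 1)

    def _axon_overlap(self, lo: float, hi: float) -> np.ndarray:
        """Overlap length (um) of [lo, hi] with each axon segment."""
        na = self.axon.n_segments
        dx = self.axon.length / na
        edges = np.arange(na + 1) * dx
        return np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)

    def _compile_channels(self) -> None:
        cfg = self.config
        n = self.n_nodes
        nd = self.n_dend
        soma = self.soma_idx

        specs: list[ChannelSpec] = []
        gbars: list[np.ndarray] = []

        chan_cfg = cfg["channels"]
        for name, ch in chan_cfg.items():
            p = int(ch["p"])
            act = _gate_from_cfg(ch.get("activation"), name, "activation")
            inact = _gate_from_cfg(ch.get("inactivation"), name, "inactivation")
            spec = ChannelSpec(name=name, p=p, e_rev=float(ch["e_mV"]),
                               activation=act, inactivation=inact)
            gbar = np.zeros(n, dtype=np.float64)
            regions = ch.get("regions", {})
            for region, value in regions.items():
                if region == "ais":
                    if self.ais is None:
                        continue
                    if value == "from_ais_nav16":
                        dens = self.ais.gnav16_density
                    elif value == "from_ais_kv1":
                        dens = self.ais.gkv1_density
                    else:
                        dens = float(value)
                    if dens < 0:
                        raise ConfigError(f"channel {name}: negative AIS density")
                    ov = self._axon_overlap(self.ais.start, self.ais.start + self.ais.length)
                    gbar[soma + 1:] += dens * math.pi * self.axon.diameter * ov
                elif region == "soma":
                    val = float(value)
                    if val < 0:
                        raise ConfigError(f"channel {name}: negative somatic conductance")
                    gbar[soma] += val
                elif region == "dendrite":
                    if self.dendrite is None:
                        continue
                    dens = float(value)
                    if dens < 0:
                        raise ConfigError(f"channel {name}: negative dendritic density")
                    gbar[:nd] += dens * self.dendrite.area_per_segment
                elif region == "dendrite_proximal":
                    if self.dendrite is None:
                        continue
                    dens = float(value)
                    if dens < 0:
                        raise ConfigError(f"channel {name}: negative dendritic density")
                    frac = float(cfg["geometry"]["dendrite"].get("proximal_fraction", 0.2))
                    n_prox = max(1, int(round(frac * nd)))
                    # proximal dendrite nodes are the ones nearest the soma
                    gbar[nd - n_prox: nd] += dens * self.dendrite.area_per_segment
                else:
                    raise ConfigError(f"channel {name}: unknown region {region!r}")
            specs.append(spec)
            gbars.append(gbar)

        # implicit somatic leak from the stated soma resistance
        soma_r = float(cfg["geometry"]["soma"]["leak_resistance_MOhm"])
        if soma_r <= 0:
            raise ConfigError("soma leak_resistance_MOhm must be > 0")
        leak_gbar = np.zeros(n, dtype=np.float64)
        leak_gbar[soma] = 1e3 / soma_r
        specs.append(ChannelSpec(name="leak_soma", p=0, e_rev=self.e_leak))
        gbars.append(leak_gbar)

        self.channels = specs
        K = len(specs)
        self.gbar = np.stack(gbars)
        self.p_exp = np.array([s.p for s in specs], dtype=np.int64)
        self.e_rev = np.array([s.e_rev for s in specs], dtype=np.float64)
        self.has_act = np.array([s.activation is not None for s in specs])
        self.has_inact = np.array([s.inactivation is not None for s in specs])
        self.act = np.zeros((K, 6), dtype=np.float64)
        self.inact = np.zeros((K, 6), dtype=np.float64)
        for k, s in enumerate(specs):
            if s.activation is not None:
                self.act[k] = s.activation.as_array()
            if s.inactivation is not None:
                self.inact[k] = s.inactivation.as_array()
        # guard against division by zero for ungated channels in the kernel
        for k in range(K):
            if not self.has_act[k]:
                self.act[k] = [0.0, 1.0, 1.0, 1.0, 0.0, 1.0]
            if not self.has_inact[k]:
                self.inact[k] = [0.0, 1.0, 1.0, 1.0, 0.0, 1.0]
        (self._g_ptr, self._g_idx, self._a_ptr, self._a_idx,
         self._h_ptr, self._h_idx) = _engine.channel_index_lists(
            self.gbar, self.has_act, self.has_inact)

    # -- identity ---------------------------------------------------------

    @property
    def digest(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- state handling ---------------------------------------------------

    def _steady_gates(self, v0: float):
        return _engine.steady_gates(v0, self.gbar, self.act, self.has_act,
                                    self.inact, self.has_inact)

    def _run(self, v, m, h, i_stim, g_syn, dt, clamp=False, v_clamp=0.0,
             e_syn=0.0, stop_after_spike_ms=0.0):
        margin = int(round(stop_after_spike_ms / dt)) if stop_after_spike_ms > 0 else 0
        vrec, diverged, n_done = _engine.run_kernel(
            self.c, self.g_ax, self.soma_idx, self.gbar, self.p_exp,
            self.e_rev, self.act, self.inact, self.has_inact,
            self._g_ptr, self._g_idx, self._a_ptr, self._a_idx,
            self._h_ptr, self._h_idx,
            v, m, h, dt, i_stim, g_syn, e_syn, self.rec_idx, clamp, v_clamp,
            margin,
        )
        if diverged >= 0:
            raise IntegrationError(
                f"|Vm| exceeded 200 mV at t = {diverged * dt:.3f} ms (dt = {dt} ms); "
                "reduce dt or review parameters"
            )
        return vrec[:n_done]

    def settled_state(self, v_hold: float, dt: float, settle_ms: float = 200.0):
        """Holding bias plus relaxed (v, m, h) at ``v_hold``; cached per cell.

        The soma is voltage-clamped at ``v_hold`` until the distal
        compartments and gates relax, the clamp current is read from the
        steady state, and the resulting constant bias is verified to hold
        the unclamped soma within 0.1 mV without spikes.
        """
        key = (float(v_hold), float(dt), float(settle_ms))
        if key in self._settle_cache:
            return self._settle_cache[key]

        n_settle = int(round(max(settle_ms, 300.0) / dt))
        zeros = np.zeros(n_settle, dtype=np.float64)
        v = np.full(self.n_nodes, v_hold, dtype=np.float64)
        m, h = self._steady_gates(v_hold)
        self._run(v, m, h, zeros, zeros, dt, clamp=True, v_clamp=v_hold)

        bias = self._clamp_current(v, m, h)

        # verification: constant-bias relaxation, no clamp
        v2, m2, h2 = v.copy(), m.copy(), h.copy()
        n_ver = int(round(settle_ms / dt))
        vrec = self._run(v2, m2, h2, np.full(n_ver, bias), np.zeros(n_ver), dt)
        v_end = vrec[-1, 0]
        drift = np.abs(vrec[-n_ver // 5:, 0] - v_hold).max()
        if drift > 0.1 or np.any(vrec[:, 0] > v_hold + 20.0):
            raise IntegrationError(
                f"no stable holding state at {v_hold} mV (somatic Vm drifted to "
                f"{v_end:.2f} mV); the model may be spontaneously active — review parameters"
            )
        state = (bias, v2, m2, h2)
        self._settle_cache[key] = state
        return state

    def _clamp_current(self, v, m, h) -> float:
        """Constant somatic current balancing all other currents at steady state."""
        s = self.soma_idx
        i_ion = 0.0
        for k, spec in enumerate(self.channels):
            g = self.gbar[k, s]
            if g == 0.0:
                continue
            g = g * m[k, s] ** spec.p * (h[k, s] if self.has_inact[k] else 1.0)
            i_ion += g * (spec.e_rev - v[s])
        i_ax = 0.0
        if s > 0:
            i_ax += self.g_ax[s - 1] * (v[s - 1] - v[s])
        if s < self.n_nodes - 1:
            i_ax += self.g_ax[s] * (v[s + 1] - v[s])
        return -(i_ion + i_ax)


def _gate_from_cfg(d: Optional[dict], chan: str, which: str) -> Optional[GateKinetics]:
    if d is None:
        return None
    try:
        return GateKinetics(
            v_half=float(d["v_half_mV"]),
            v_slope=float(d["v_slope_mV"]),
            tau_max=float(d["tau_max_ms"]),
            tau_min=float(d["tau_min_ms"]),
            v_tau_half=float(d["v_tau_half_mV"]),
            v_tau_slope=float(d["v_tau_slope_mV"]),
        )
    except KeyError as e:
        raise ConfigError(f"channel {chan} {which}: missing key {e}") from None
    except ValueError as e:
        raise ConfigError(f"channel {chan} {which}: {e}") from None


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def build_cell(config: dict) -> CellModel:
    """Assemble and discretize the cell described by a validated config dict."""
    return CellModel(config)


def solve_holding_bias(cell: CellModel, v_hold: float, dt: float = 0.01) -> float:
    """Constant somatic bias current (pA) holding the soma at ``v_hold``."""
    bias, *_ = cell.settled_state(v_hold, dt)
    return bias


def integrate(cell: CellModel, protocol, dt: float = 0.01,
              stop_after_spike_ms: float = 0.0) -> VoltageTrace:
    """Run one stimulation protocol from the settled holding state.

    ``protocol`` must provide ``v_hold`` (mV) and ``waveforms(dt) ->
    (i_stim pA, g_syn nS, e_syn mV, t0 ms)``.  The holding bias is added to
    the commanded current; the returned trace starts at protocol time
    ``t0`` with the settling transient already discarded.  A positive
    ``stop_after_spike_ms`` truncates the run that long after the first
    recorded compartment crosses 0 mV (used by spike-or-not searches).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    settle_ms = float(cell.config.get("simulation", {}).get("settle_ms", 200.0))
    bias, v, m, h = cell.settled_state(protocol.v_hold, dt, settle_ms)
    i_stim, g_syn, e_syn, t0 = protocol.waveforms(dt)
    vrec = cell._run(v.copy(), m.copy(), h.copy(), i_stim + bias, g_syn, dt,
                     e_syn=e_syn, stop_after_spike_ms=stop_after_spike_ms)
    n = len(vrec)
    return VoltageTrace(
        dt=dt,
        t0=t0,
        vm=vrec,
        channels=cell.rec_names,
        i_stim=i_stim[:n],
        g_syn=g_syn[:n],
        metadata={"model_digest": cell.digest, "v_hold": protocol.v_hold,
                  "bias_pA": bias, "protocol": getattr(protocol, "name", "custom")},
    )
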