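"""Stimulation protocols: square current steps, rheobase search, EPSC series.

A protocol object describes the command waveform delivered at the soma of a
cell held at ``v_hold`` (default -70 mV): a square current pulse for step
protocols, or a transient synaptic conductance (reversal 0 mV) for EPSC
protocols.  The EPSC is a dual-exponential conductance with a 0.5 ms time
to peak and a 3 ms decay, normalized so its maximum equals the requested
peak conductance exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .cell import CellModel, VoltageTrace, integrate
from .features import detect_aps

__all__ = [
    "StepProtocol",
    "EPSCProtocol",
    "epsc_conductance_waveform",
    "run_step_protocol",
    "find_rheobase",
    "find_threshold_epsc",
    "NoRheobaseError",
]


class NoRheobaseError(RuntimeError):
    """No spike found anywhere inside the search bracket."""


@dataclass
class StepProtocol:
    """One square somatic current pulse (a sweep series passes many amplitudes)."""

    amplitude: float           # pA
    duration: float = 250.0    # ms
    v_hold: float = -70.0      # mV
    onset: float = 20.0        # ms of pre-stimulus baseline in the record
    tail: float = 50.0         # ms after stimulus offset
    name: str = "step"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("step duration must be > 0")
        if not math.isfinite(self.amplitude):
            raise ValueError("step amplitude must be finite")

    def waveforms(self, dt: float):
        n = int(round((self.onset + self.duration + self.tail) / dt))
        i_stim = np.zeros(n, dtype=np.float64)
        i0 = int(round(self.onset / dt))
        i1 = int(round((self.onset + self.duration) / dt))
        i_stim[i0:i1] = self.amplitude
        return i_stim, np.zeros(n, dtype=np.float64), 0.0, 0.0


@dataclass
class EPSCProtocol:
    """Somatic conductance-injection EPSC series.

    ``peak_conductances`` is the ascending search grid (nS); kinetics are
    time-to-peak and decay time constant of the dual-exponential waveform.
    """

    peak_conductances: Sequence[float] = field(
        default_factory=lambda: tuple(np.round(np.arange(6.0, 11.0 + 1e-9, 0.25), 2))
    )
    time_to_peak: float = 0.5   # ms
    decay_tau: float = 3.0      # ms
    e_rev: float = 0.0          # mV
    v_hold: float = -70.0       # mV
    onset: float = 20.0         # ms
    window: float = 60.0        # ms recorded after onset
    name: str = "epsc"

    def __post_init__(self) -> None:
        if self.time_to_peak <= 0:
            raise ValueError("time_to_peak must be > 0")
        if self.decay_tau <= self.time_to_peak:
            raise ValueError("decay_tau must exceed the rise shaping (time_to_peak)")

    def single(self, g_peak: float) -> "EPSCProtocol":
        p = EPSCProtocol(**{**self.__dict__, "peak_conductances": (g_peak,)})
        return p

    @property
    def g_peak(self) -> float:
        if len(self.peak_conductances) != 1:
            raise ValueError("waveforms() needs a single-conductance protocol; use .single()")
        return float(self.peak_conductances[0])

    def waveforms(self, dt: float):
        g = epsc_conductance_waveform(self, self.g_peak, dt)
        n_pre = int(round(self.onset / dt))
        n = n_pre + int(round(self.window / dt))
        g_syn = np.zeros(n, dtype=np.float64)
        m = min(len(g), n - n_pre)
        g_syn[n_pre:n_pre + m] = g[:m]
        return np.zeros(n, dtype=np.float64), g_syn, self.e_rev, 0.0


def _dual_exp_rise_tau(time_to_peak: float, decay_tau: float) -> float:
    """Rise time constant of A*(exp(-t/tau_d) - exp(-t/tau_r)) peaking at time_to_peak."""
    td = decay_tau

    def peak_time(tr):
        return td * tr / (td - tr) * math.log(td / tr)

    return brentq(lambda tr: peak_time(tr) - time_to_peak, 1e-6, td * (1 - 1e-9),
                  xtol=1e-12)


def epsc_conductance_waveform(p: EPSCProtocol, g_peak: float, dt: float) -> np.ndarray:
    """Dual-exponential conductance time course (nS), sampled at dt from onset.

    The waveform is normalized analytically so its continuous-time maximum
    equals ``g_peak`` and occurs at ``time_to_peak``; it is zero at onset
    and decays with ``decay_tau``.
    """
    if g_peak <= 0:
        raise ValueError("g_peak must be > 0")
    if dt > p.time_to_peak:
        raise ValueError(
            f"dt = {dt} ms undersamples the {p.time_to_peak} ms EPSC rise"
        )
    tr = _dual_exp_rise_tau(p.time_to_peak, p.decay_tau)
    td = p.decay_tau
    t = np.arange(0.0, p.time_to_peak + 8.0 * td, dt)
    raw = np.exp(-t / td) - np.exp(-t / tr)
    peak = (math.exp(-p.time_to_peak / td) - math.exp(-p.time_to_peak / tr))
    return g_peak * raw / peak


def run_step_protocol(cell: CellModel, amplitudes: Sequence[float],
                      duration: float = 250.0, v_hold: float = -70.0,
                      dt: float = 0.01) -> list[VoltageTrace]:
    """One trace per amplitude, each starting from the identical holding state."""
    return [
        integrate(cell, StepProtocol(amplitude=a, duration=duration, v_hold=v_hold), dt)
        for a in amplitudes
    ]


def _spikes_at(cell: CellModel, amplitude: float, duration: float,
               v_hold: float, dt: float) -> tuple[bool, VoltageTrace]:
    from .cell import IntegrationError

    try:
        tr = integrate(cell, StepProtocol(amplitude=amplitude, duration=duration,
                                          v_hold=v_hold), dt,
                       stop_after_spike_ms=6.0)
    except IntegrationError:
        # a passive cell driven past the +/-200 mV guard never spiked; treat
        # the amplitude as non-spiking rather than aborting the search
        return False, None
    aps = detect_aps(tr)
    onset = 20.0
    n_in_step = [a for a in aps if onset <= a.threshold_time <= onset + duration + 2.0]
    return len(n_in_step) > 0, tr


def find_rheobase(cell: CellModel, duration: float = 250.0, resolution: float = 1.0,
                  v_hold: float = -70.0, dt: float = 0.01, i_max: float = 1000.0,
                  return_trace: bool = False, bracket_hint=None):
    """Smallest step amplitude (within ``resolution``) eliciting >= 1 AP.

    Bisection between a subthreshold and a suprathreshold bracket; the
    suprathreshold bracket is grown geometrically up to ``i_max``.  A
    ``bracket_hint`` (lo, hi) — e.g. from a neighbouring sweep point —
    warm-starts the search and is widened until it truly brackets.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    lo, hi = (0.0, 50.0) if bracket_hint is None else bracket_hint
    lo = max(lo, 0.0)
    spiking, tr = _spikes_at(cell, hi, duration, v_hold, dt)
    while not spiking:
        lo = hi
        hi *= 2.0
        if hi > i_max:
            raise NoRheobaseError(
                f"no AP up to {i_max} pA ({duration} ms step at {v_hold} mV)"
            )
        spiking, tr = _spikes_at(cell, hi, duration, v_hold, dt)
    tr_hi = tr
    while lo > 0.0:
        spiking_lo, tr_lo = _spikes_at(cell, lo, duration, v_hold, dt)
        if not spiking_lo:
            break
        hi, tr_hi = lo, tr_lo
        lo = max(lo - max(4.0 * resolution, 0.25 * lo), 0.0)
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        spiking, tr = _spikes_at(cell, mid, duration, v_hold, dt)
        if spiking:
            hi, tr_hi = mid, tr
        else:
            lo = mid
    if return_trace:
        return hi, tr_hi
    return hi


def find_threshold_epsc(cell: CellModel, p: EPSCProtocol, dt: float = 0.01):
    """Smallest listed EPSC conductance eliciting an AP, plus per-conductance lags.

    Returns ``(g_threshold or None, lags)`` where ``lags`` maps each
    suprathreshold conductance to the EPSC-onset-to-AP-onset lag in ms
    (10 mV/ms phase-plot criterion).
    """
    gs = list(p.peak_conductances)
    if any(b <= a for a, b in zip(gs, gs[1:])):
        raise ValueError("peak_conductances must be ascending")
    g_thr = None
    lags: dict[float, float] = {}
    for g in gs:
        tr = integrate(cell, p.single(g), dt)
        aps = detect_aps(tr)
        aps = [a for a in aps if a.threshold_time >= p.onset]
        if aps:
            lags[g] = aps[0].threshold_time - p.onset
            if g_thr is None:
                g_thr = g
    return g_thr, lags
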