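"""Synthetic traces and cohorts with exact, annotated ground truth.

Three generators back the test suite (and any user wanting known-answer
inputs):

* :func:`synth_ap_trace` — an AP train built from sums of logistic
  sigmoids.  The template is smooth and analytically differentiable, so
  the programmed features (the Vm at which dV/dt first reaches the
  10 mV/ms criterion, the peak, spike times) are solved to root-finding
  precision on the continuous waveform and returned as annotations —
  independent of any sampled-trace feature extractor.
* :func:`synth_passive_trace` — an exact single-exponential charging
  response with known Rin and tau.
* :func:`synth_cohort` — per-cell feature tables drawn from
  quantile-matched shifted log-normal distributions, parameterized by the
  median/IQR summaries reported for human and mouse fast-spiking
  interneuron cohorts.

All randomness flows from explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .cell import VoltageTrace

__all__ = [
    "SyntheticCellSpec",
    "CohortSpec",
    "synth_ap_trace",
    "synth_passive_trace",
    "synth_cohort",
    "TABLE_HUMAN",
    "TABLE_MOUSE",
]

_Z75 = 0.6744897501960817   # 75th percentile of the standard normal

#: median and (1st, 3rd) quartiles of AP and passive features, human cohort
TABLE_HUMAN = {
    "threshold": (-38.9, (-42.8, -34.2)),
    "initial_rise_slope": (30.9, (23.8, 35.5)),
    "peak": (15.6, (9.08, 25.0)),
    "half_width": (0.496, (0.407, 0.676)),
    "rheobase": (87.4, (47.5, 140.0)),
    "latency": (19.6, (12.6, 33.7)),
    "spike_count": (3.8, (1.8, 11.8)),
    "ahp_amplitude": (-19.7, (-23.6, -16.2)),
    "max_rise": (246.9, (170.5, 335.9)),
    "max_fall": (-122.8, (-165.0, -82.7)),
    "rin": (187.9, (103.8, 279.8)),
    "tau_apparent": (6.65, (4.22, 8.17)),
    "cm_estimate": (32.4, (24.3, 53.7)),
}

#: same features for the mouse cohort
TABLE_MOUSE = {
    "threshold": (-32.5, (-35.9, -28.3)),
    "initial_rise_slope": (33.2, (28.9, 39.0)),
    "peak": (15.9, (8.2, 23.5)),
    "half_width": (0.362, (0.320, 0.416)),
    "rheobase": (247.6, (142.2, 418.4)),
    "latency": (50.5, (17.9, 79.9)),
    "spike_count": (5.0, (2.5, 8.0)),
    "ahp_amplitude": (-18.6, (-21.1, -15.9)),
    "max_rise": (255.3, (202.1, 320.7)),
    "max_fall": (-153.7, (-213.9, -113.7)),
    "rin": (125.7, (89.5, 167.5)),
    "tau_apparent": (4.17, (3.27, 6.12)),
    "cm_estimate": (35.1, (26.3, 50.6)),
}


@dataclass
class SyntheticCellSpec:
    """Shape parameters of the synthetic AP template (defaults: human medians)."""

    true_threshold: float = -38.9   # mV at the 10 mV/ms crossing
    true_peak: float = 15.6         # mV
    ahp_depth: float = -19.7        # mV, trough minus threshold (negative)
    max_rise: float = 246.9         # mV/ms, sets upstroke steepness
    max_fall: float = -122.8        # mV/ms, sets downstroke steepness
    v_hold: float = -70.0           # mV baseline
    noise_sd: float = 0.0           # mV additive Gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_peak <= self.true_threshold:
            raise ValueError("peak must exceed threshold")
        if self.ahp_depth >= 0:
            raise ValueError("ahp_depth is negative-going (trough below threshold)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class CohortSpec:
    """Cohort summary to match: per-feature (median, (q1, q3)) plus size and seed."""

    n: int = 100
    features: dict = field(default_factory=lambda: dict(TABLE_HUMAN))
    family: str = "shifted-lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        for name, (med, (q1, q3)) in self.features.items():
            lo, hi = min(q1, q3), max(q1, q3)
            if not lo <= med <= hi:
                raise ValueError(f"{name}: median {med} outside quartiles ({lo}, {hi})")


# --------------------------------------------------------------------------
# AP template
# --------------------------------------------------------------------------

def _sigma(z):
    from scipy.special import expit

    return expit(z)


class _APTemplate:
    """Continuous AP train: baseline + per-spike logistic up/down/recovery.

    Each spike is the sum of an upstroke logistic (amplitude ``a_up``),
    a downstroke logistic (``a_down``) and a slow AHP-recovery logistic
    (``a_rec = a_down - a_up``), so the waveform returns to the pre-spike
    plateau ``v_pre`` after each event.
    """

    def __init__(self, spec: SyntheticCellSpec, spike_times, v_pre: float,
                 approach_tau=2.0, criterion=10.0):
        self.spec = spec
        self.spike_times = list(spike_times)
        self.approach_tau = approach_tau
        self.criterion = criterion
        self.v_pre = v_pre

        peak, thr = spec.true_peak, spec.true_threshold
        trough = thr + spec.ahp_depth
        self.a_up = peak - v_pre
        if self.a_up <= 0:
            raise ValueError("plateau above programmed peak")
        self.s_up = self.a_up / (4.0 * spec.max_rise)
        self.a_down = peak - trough
        self.s_down = self.a_down / (4.0 * abs(spec.max_fall))
        # separation between up- and downstroke centers keeps the crossing
        # on the rising limb nearly uncontaminated (residual handled by the
        # full-derivative solve in synth_ap_trace)
        self.gap = 6.0 * (self.s_up + self.s_down)
        self.a_rec = self.a_down - self.a_up   # trough back up to plateau
        self.s_rec = 1.5

    def _parts(self, t0):
        return (
            (self.a_up, t0, self.s_up),
            (-self.a_down, t0 + self.gap, self.s_down),
            (self.a_rec, t0 + self.gap + 8.0, self.s_rec),
        )

    def value(self, t):
        t = np.asarray(t, dtype=float)
        spec = self.spec
        v = self.v_pre + (spec.v_hold - self.v_pre) * np.exp(
            -np.clip(t, 0.0, None) / self.approach_tau
        )
        for t0 in self.spike_times:
            for a, c, s in self._parts(t0):
                v = v + a * _sigma((t - c) / s)
        return v

    def derivative(self, t):
        t = np.asarray(t, dtype=float)
        spec = self.spec
        dv = -(spec.v_hold - self.v_pre) / self.approach_tau * np.exp(
            -np.clip(t, 0.0, None) / self.approach_tau
        )
        for t0 in self.spike_times:
            for a, c, s in self._parts(t0):
                sig = _sigma((t - c) / s)
                dv = dv + a / s * sig * (1.0 - sig)
        return dv

    def annotate(self):
        """Exact per-spike threshold crossings and peaks of the continuous waveform."""
        ann = []
        for t0 in self.spike_times:
            t_cross = brentq(
                lambda t: self.derivative(t) - self.criterion,
                t0 - 12.0 * self.s_up, t0, xtol=1e-12,
            )
            t_peak = minimize_scalar(
                lambda t: -self.value(t), bounds=(t0 - 2.0, t0 + self.gap),
                method="bounded", options={"xatol": 1e-10},
            ).x
            ann.append({
                "threshold": float(self.value(t_cross)),
                "threshold_time": float(t_cross),
                "peak": float(self.value(t_peak)),
                "peak_time": float(t_peak),
            })
        return ann


def _solve_template(spec: SyntheticCellSpec, spike_times, criterion: float):
    """Pick the plateau v_pre so the full-template crossing hits the programmed
    threshold to root-finding precision."""

    def err(v_pre):
        tpl = _APTemplate(spec, spike_times[:1], v_pre, criterion=criterion)
        return tpl.annotate()[0]["threshold"] - spec.true_threshold

    lo = spec.v_hold - 60.0
    hi = spec.true_threshold - 0.05
    if err(hi) < 0:
        raise ValueError(
            "template cannot place the criterion crossing at the programmed "
            "threshold; increase max_rise or the threshold-to-peak span"
        )
    v_pre = brentq(err, lo, hi, xtol=1e-10)
    return _APTemplate(spec, spike_times, v_pre, criterion=criterion)


def synth_ap_trace(spec: SyntheticCellSpec, spike_times=(30.0,), dt: float = 0.02,
                   duration: Optional[float] = None, criterion: float = 10.0):
    """Synthetic AP train plus exact ground-truth annotations.

    Returns ``(trace, annotations)`` where ``annotations`` holds, per
    spike, the exact threshold (Vm at the continuous-time dV/dt =
    ``criterion`` crossing), its time, and the peak.  Raises if ``dt`` is
    too coarse to resolve the programmed crossing unambiguously.
    """
    if spike_times:
        tpl = _solve_template(spec, list(spike_times), criterion)
    else:
        tpl = _APTemplate(spec, [], spec.v_hold + 2.0, criterion=criterion)
    if dt > tpl.s_up:
        raise ValueError(
            f"dt = {dt} ms too coarse for upstroke time scale {tpl.s_up:.3g} ms"
        )
    if duration is None:
        duration = (max(spike_times) if spike_times else 10.0) + 60.0
    t = np.arange(0.0, duration, dt)
    v = tpl.value(t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=v.shape)
    trace = VoltageTrace(dt=dt, t0=0.0, vm=v, channels=("soma",),
                         metadata={"synthetic": True, "seed": spec.seed})
    annotations = {
        "spikes": tpl.annotate() if spike_times else [],
        "v_pre": tpl.v_pre,
        "spike_count": len(spike_times),
    }
    return trace, annotations


def synth_passive_trace(rin: float, tau: float, step_pA: float = 50.0,
                        noise_sd: float = 0.0, seed: int = 0, dt: float = 0.02,
                        v_hold: float = -70.0, onset: float = 20.0,
                        duration: float = 250.0, tail: float = 80.0) -> VoltageTrace:
    """Exact RC charging response: dV_ss = Rin * I with time constant tau."""
    if rin <= 0 or tau <= 0:
        raise ValueError("rin and tau must be positive")
    n = int(round((onset + duration + tail) / dt))
    t = np.arange(n) * dt
    dv_ss = rin * step_pA * 1e-3   # MOhm * pA = uV -> mV via 1e-3
    v = np.full(n, v_hold, dtype=float)
    on = t >= onset
    v[on] += dv_ss * (1.0 - np.exp(-(t[on] - onset) / tau))
    off = t >= onset + duration
    v_off = dv_ss * (1.0 - math.exp(-duration / tau))
    v[off] = v_hold + v_off * np.exp(-(t[off] - onset - duration) / tau)
    i_stim = np.where(on & ~off, step_pA, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return VoltageTrace(dt=dt, t0=0.0, vm=v, channels=("soma",), i_stim=i_stim,
                        metadata={"synthetic": True, "rin": rin, "tau": tau})


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def _shifted_lognormal_params(med: float, q1: float, q3: float):
    """(shift, mu, sigma, mirrored) matching the three quantiles exactly.

    For a shifted log-normal X = c + exp(mu + sigma*Z):
    median = c + e^mu, quartiles c + e^(mu -/+ z75*sigma), and the quartile
    gap ratio (q3-med)/(med-q1) equals e^(z75*sigma).  Left-skewed triples
    (ratio < 1) are handled by mirroring about the median.
    """
    lo, hi = min(q1, q3), max(q1, q3)
    g1, g3 = med - lo, hi - med
    if g1 <= 0 or g3 <= 0:
        raise ValueError(f"degenerate quartiles ({q1}, {med}, {q3})")
    mirrored = g3 < g1
    if mirrored:
        g1, g3 = g3, g1
    sigma = math.log(g3 / g1) / _Z75
    if sigma < 1e-12:
        raise ValueError("symmetric quartiles: use a normal instead")
    emu = g1 / (1.0 - math.exp(-_Z75 * sigma))
    return med - emu, math.log(emu), sigma, mirrored


def _sample_feature(rng, med, q1, q3, n):
    lo, hi = min(q1, q3), max(q1, q3)
    g1, g3 = med - lo, hi - med
    if abs(math.log(g3 / g1)) < 1e-9:   # symmetric: plain normal
        return rng.normal(med, g1 / _Z75, size=n)
    shift, mu, sigma, mirrored = _shifted_lognormal_params(med, q1, q3)
    x = shift + rng.lognormal(mu, sigma, size=n)
    if mirrored:
        x = 2.0 * med - x
    return x


def synth_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-cell feature table whose medians/quartiles match the spec.

    Each feature is drawn independently from a quantile-matched shifted
    log-normal (or its mirror for left-skewed triples); the output columns
    match the feature-extraction schema.
    """
    if spec.family not in ("shifted-lognormal",):
        raise ValueError(f"unknown distribution family {spec.family!r}")
    rng = np.random.default_rng(spec.seed)
    data = {"cell_id": np.arange(spec.n)}
    for name, (med, (q1, q3)) in spec.features.items():
        data[name] = _sample_feature(rng, med, q1, q3, spec.n)
    return pd.DataFrame(data)
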