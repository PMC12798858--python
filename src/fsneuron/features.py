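"""Electrophysiological feature extraction for simulated and recorded traces.

The AP firing threshold is defined operationally on the phase plot: the
membrane potential at which dV/dt first reaches 10 mV/ms on the rising
limb of a validated spike.  All other AP features (half-width, AHP
amplitude measured from threshold to trough, phase-plot rise/fall extrema,
initial rise slope) and the passive features (input resistance from
subthreshold steps, apparent membrane time constant from a single
exponential fit to the charging phase) follow the same operational
definitions used for whole-cell recordings of fast-spiking interneurons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .cell import VoltageTrace

logger = logging.getLogger(__name__)

__all__ = [
    "APWindow",
    "APFeatures",
    "PassiveFeatures",
    "phase_plot",
    "detect_aps",
    "ap_features",
    "latency_and_count",
    "measure_rin",
    "measure_tau",
]

#: validation level: a threshold crossing only counts as an AP if the
#: subsequent Vm maximum exceeds this; it must sit above the largest
#: subthreshold EPSP (thresholds reach -36 mV in short-AIS/high-Kv1
#: configurations) yet below the model's AIS-driven somatic spike peaks
SPIKE_VALIDATION_MV = -20.0
#: axonal validation level used when the trace carries the AIS voltage:
#: a genuine axonal AP overshoots 0 mV in every model configuration
AIS_SPIKE_MV = 0.0
DEFAULT_CRITERION = 10.0   # mV/ms


@dataclass
class APWindow:
    """One detected spike: sample indices plus the interpolated threshold point."""

    i_threshold: int        # sample index just after the criterion crossing
    i_peak: int
    i_trough: Optional[int]     # None if the record ends before a trough
    threshold: float        # mV, interpolated at the criterion crossing
    threshold_time: float   # ms


@dataclass
class APFeatures:
    threshold: Optional[float] = None        # mV
    peak: Optional[float] = None             # mV
    half_width: Optional[float] = None       # ms
    ahp_amplitude: Optional[float] = None    # mV, trough minus threshold (negative)
    max_rise: Optional[float] = None         # mV/ms
    max_fall: Optional[float] = None         # mV/ms
    initial_rise_slope: Optional[float] = None   # 1/ms
    latency: Optional[float] = None          # ms
    spike_count: Optional[int] = None
    rheobase: Optional[float] = None         # pA

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class PassiveFeatures:
    rin: float              # MOhm
    tau_apparent: float     # ms
    cm_estimate: float      # pF  (tau / Rin, in pF given MOhm and ms)

    def __post_init__(self) -> None:
        if self.rin <= 0 or self.tau_apparent <= 0:
            raise ValueError("Rin and tau must be positive")


def _as_trace(trace) -> VoltageTrace:
    if isinstance(trace, VoltageTrace):
        return trace
    raise TypeError(f"expected VoltageTrace, got {type(trace)!r}")


def phase_plot(trace: VoltageTrace, channel: int = 0,
               prefilter: bool = False):
    """(V, dV/dt) pairs with the derivative from central differences.

    ``prefilter`` applies a 3-point median filter to Vm first (for noisy
    recorded/synthetic traces; simulated traces are noiseless and are not
    smoothed by default).
    """
    tr = _as_trace(trace)
    v = tr.vm[:, channel].astype(float)
    if len(v) < 3:
        raise ValueError("trace shorter than 3 samples")
    if prefilter:
        from scipy.signal import medfilt
        v = medfilt(v, 3)
    dvdt = np.gradient(v, tr.dt)
    return v, dvdt


def detect_aps(trace: VoltageTrace, criterion: float = DEFAULT_CRITERION,
               channel: int = 0, interpolate: bool = True,
               prefilter: bool = False) -> list[APWindow]:
    """Locate APs: dV/dt criterion crossing -> validated peak -> trough.

    Each AP begins at the start of the last contiguous ``dv/dt >=
    criterion`` run preceding a validated spike peak (one above
    ``SPIKE_VALIDATION_MV``); the threshold is the Vm at that crossing,
    linearly interpolated between the bracketing samples.
    """
    if criterion <= 0:
        raise ValueError("criterion must be > 0")
    tr = _as_trace(trace)
    v, dvdt = phase_plot(tr, channel=channel, prefilter=prefilter)
    n = len(v)
    above = dvdt >= criterion
    # bridge sub-criterion dips shorter than 0.06 ms: derivative noise can
    # briefly interrupt a genuine upstroke run, whereas a real EPSP-to-AP
    # separation lasts far longer than this
    gap = max(int(round(0.06 / tr.dt)), 1)
    if gap > 1:
        below = np.flatnonzero(~above)
        i = 0
        while i < len(below):
            j = i
            while j + 1 < len(below) and below[j + 1] == below[j] + 1:
                j += 1
            if (below[j] - below[i] + 1) <= gap and below[i] > 0 and below[j] < n - 1:
                if above[below[i] - 1] and above[below[j] + 1]:
                    above[below[i]:below[j] + 1] = True
            i = j + 1

    # candidate spike peaks: local Vm maxima above the validation level.
    # For simulated traces that also carry the AIS-midpoint voltage, the
    # validation uses the axonal spike (unambiguously > 0 mV) instead of
    # the somatic amplitude: the somatic correlate of an axonal AP can be
    # modest in strongly isolated configurations, but it is still the
    # event whose phase-plot crossing defines the threshold.
    peaks = np.flatnonzero(
        (v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:]) & (v[1:-1] > SPIKE_VALIDATION_MV)
    ) + 1
    if channel == 0 and "ais_mid" in getattr(tr, "channels", ()):
        va = tr.vm[:, tr.channels.index("ais_mid")]
        ais_ok = va > AIS_SPIKE_MV
        cand = np.flatnonzero(
            (v[1:-1] >= v[:-2]) & (v[1:-1] > v[2:])
        ) + 1
        # somatic local maxima with an axonal spike within +/- 1 ms
        w = max(int(round(1.0 / tr.dt)), 1)
        peaks = np.array([
            ip for ip in cand
            if ais_ok[max(ip - w, 0):ip + w + 1].any()
        ], dtype=np.int64)

    windows: list[APWindow] = []
    i_done = 0
    for ip in peaks:
        if ip <= i_done:
            continue
        # AP onset: start of the last contiguous dv/dt >= criterion run on
        # the upstroke (an EPSP rise can also exceed the criterion, but its
        # run ends before the spike's own regenerative run begins)
        seg = above[i_done:ip]
        idx = np.flatnonzero(seg)
        if len(idx) == 0:
            continue
        j = idx[-1]
        while j > 0 and seg[j - 1]:
            j -= 1
        ic = j + i_done
        if ic == 0:
            continue
        # trough: Vm minimum between the peak and the next sustained rise;
        # if the record ends while still repolarizing there is no trough
        k = ip
        i_trough: Optional[int] = None
        while k + 1 < n:
            k += 1
            if v[k] > v[k - 1]:
                break
        else:
            k = None
        if k is not None and k > ip:
            i_trough = int(np.argmin(v[ip:k + 1])) + ip
            if i_trough == ip:
                i_trough = None
        if interpolate and dvdt[ic] != dvdt[ic - 1]:
            f = (criterion - dvdt[ic - 1]) / (dvdt[ic] - dvdt[ic - 1])
            f = min(max(f, 0.0), 1.0)
        else:
            f = 1.0
        thr = v[ic - 1] + f * (v[ic] - v[ic - 1])
        t_thr = tr.t0 + (ic - 1 + f) * tr.dt
        windows.append(APWindow(i_threshold=ic, i_peak=ip, i_trough=i_trough,
                                threshold=thr, threshold_time=t_thr))
        i_done = i_trough if i_trough is not None else ip
    return windows


def ap_features(trace: VoltageTrace, window: APWindow,
                criterion: float = DEFAULT_CRITERION,
                channel: int = 0) -> APFeatures:
    """Waveform features of one detected AP (missing fields stay None)."""
    tr = _as_trace(trace)
    v, dvdt = phase_plot(tr, channel=channel)
    thr = window.threshold
    i_peak = window.i_peak
    peak = float(v[i_peak])
    feats = APFeatures(threshold=thr, peak=peak)

    i_end = window.i_trough if window.i_trough is not None else len(v) - 1

    # half-width at 50% of threshold-to-peak amplitude
    half_level = thr + 0.5 * (peak - thr)
    i0 = window.i_threshold
    up = _crossing_time(tr, v, half_level, lo=max(i0 - 2, 0), hi=i_peak, rising=True)
    down = _crossing_time(tr, v, half_level, lo=i_peak, hi=i_end, rising=False)
    if up is not None and down is not None:
        feats.half_width = down - up

    # AHP amplitude from threshold to the post-peak trough (negative-going)
    if window.i_trough is not None:
        trough_v = float(v[window.i_trough])
        if trough_v < thr:
            feats.ahp_amplitude = trough_v - thr

    seg = slice(max(i0 - 1, 0), i_end + 1)
    feats.max_rise = float(np.max(dvdt[seg]))
    feats.max_fall = float(np.min(dvdt[seg]))

    # initial rise slope: max d(dVdt)/dV on the phase plot above the
    # criterion point and below the phase-plot peak
    i_maxrise = int(np.argmax(dvdt[seg])) + seg.start
    if i_maxrise > i0:
        dv = np.diff(v[i0 - 1:i_maxrise + 1])
        dd = np.diff(dvdt[i0 - 1:i_maxrise + 1])
        ok = dv > 1e-12
        if np.any(ok):
            feats.initial_rise_slope = float(np.max(dd[ok] / dv[ok]))
    return feats


def _crossing_time(tr, v, level, lo, hi, rising=True) -> Optional[float]:
    seg = v[lo:hi + 1]
    if rising:
        idx = np.flatnonzero((seg[:-1] < level) & (seg[1:] >= level))
    else:
        idx = np.flatnonzero((seg[:-1] >= level) & (seg[1:] < level))
    if len(idx) == 0:
        return None
    i = idx[0] + lo
    f = (level - v[i]) / (v[i + 1] - v[i]) if v[i + 1] != v[i] else 0.0
    return tr.t0 + (i + f) * tr.dt


def latency_and_count(trace: VoltageTrace, step_onset: float,
                      step_duration: Optional[float] = None,
                      criterion: float = DEFAULT_CRITERION):
    """(latency to first AP threshold crossing, number of APs in the step)."""
    tr = _as_trace(trace)
    aps = detect_aps(tr, criterion=criterion)
    t_end = math.inf if step_duration is None else step_onset + step_duration
    aps = [a for a in aps if step_onset <= a.threshold_time <= t_end]
    if not aps:
        return None, 0
    return aps[0].threshold_time - step_onset, len(aps)


def measure_rin(traces: Sequence[VoltageTrace], amplitudes: Sequence[float],
                step_onset: float, step_duration: float) -> float:
    """Input resistance (MOhm): mean over sweeps of dV_ss / dI.

    The steady-state deflection is averaged over the final 20% of the
    step.  Sweeps containing an AP are excluded with a warning; if all are
    excluded this is an error.
    """
    if len(traces) != len(amplitudes):
        raise ValueError("one amplitude per trace required")
    ratios = []
    for tr, di in zip(traces, amplitudes):
        if di == 0:
            raise ValueError("zero-amplitude sweep cannot yield Rin")
        if detect_aps(tr):
            logger.warning("measure_rin: sweep with %s pA contains an AP; excluded", di)
            continue
        t = tr.t
        base = tr.v_soma[t < step_onset]
        v0 = float(np.mean(base)) if len(base) else float(tr.v_soma[0])
        lo = step_onset + 0.8 * step_duration
        hi = step_onset + step_duration
        sel = (t >= lo) & (t <= hi)
        if not np.any(sel):
            raise ValueError("trace does not cover the final 20% of the step")
        dv = float(np.mean(tr.v_soma[sel])) - v0
        ratios.append(dv / di * 1e3)   # mV/pA -> MOhm
    if not ratios:
        raise ValueError("all sweeps contained APs; no subthreshold sweep for Rin")
    return float(np.mean(ratios))


def measure_tau(trace: VoltageTrace, step_onset: float,
                tau_guess: float = 10.0) -> float:
    """Apparent membrane time constant from the ascending phase of a step.

    Least-squares fit of V(t) = V_ss - dV * exp(-(t - t_on)/tau) over the
    window from step onset to five times the initial tau guess.
    """
    tr = _as_trace(trace)
    t = tr.t
    sel = (t >= step_onset) & (t <= step_onset + 5.0 * tau_guess)
    if np.count_nonzero(sel) < 5:
        raise ValueError("fit window contains fewer than 5 samples")
    tt = t[sel] - step_onset
    vv = tr.v_soma[sel]

    def model(x, v_ss, dv, tau):
        return v_ss - dv * np.exp(-x / tau)

    v0 = vv[0]
    v_ss0 = vv[-1]
    try:
        popt, pcov = curve_fit(model, tt, vv, p0=(v_ss0, v_ss0 - v0, tau_guess),
                               maxfev=10000)
    except RuntimeError as e:
        raise RuntimeError(f"tau fit did not converge: {e}") from None
    resid = vv - model(tt, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    span = float(np.ptp(vv))
    if span > 0 and rms > 0.25 * span:
        raise RuntimeError(
            f"tau fit not credible (rms residual {rms:.3g} mV vs span {span:.3g} mV)"
        )
    tau = float(abs(popt[2]))
    return tau
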