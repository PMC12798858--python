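"""Baseline calibration and the AIS parameter-sweep experiments.

The sweeps reproduce the simulation program linking AIS composition to
excitability: AP threshold as a function of AIS length and Kv1 density
(singly and on a joint grid), AIS position, axon diameter/axial
resistance coupling, and the EPSC-to-AP lag at fixed synaptic strength.
Thresholds inside sweeps are measured the same way throughout: a 250-ms
somatic square pulse at the 1-pA-resolution rheobase, threshold read from
the first AP's dV/dt = 10 mV/ms phase-plot crossing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import standard_config, with_overrides
from .cell import CellModel, build_cell
from .features import detect_aps, measure_rin, measure_tau
from .protocols import (
    EPSCProtocol,
    NoRheobaseError,
    StepProtocol,
    find_rheobase,
    find_threshold_epsc,
)
from .cell import integrate

logger = logging.getLogger(__name__)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "CalibrationReport",
    "CalibrationError",
    "measure_threshold",
    "baseline_features",
    "calibrate_baseline",
    "sweep_threshold",
    "sweep_epsc_lag",
    "sweep_geometry",
    "DIAMETER_RA_PAIRS",
]

#: physically coupled (diameter um, Ra MOhm/um) pairs: wider axons have
#: proportionally lower axial resistance per unit length
DIAMETER_RA_PAIRS = ((0.6, 1.1), (0.7, 1.0), (0.8, 0.9), (0.9, 0.8))

_AXIS_TO_OVERRIDE = {
    "ais_length": ("ais", "length_um"),
    "ais_start": ("ais", "start_um"),
    "gkv1": ("ais", "gkv1_nS_per_um2"),
    "gnav16": ("ais", "gnav16_nS_per_um2"),
    "axon_diameter": ("geometry", "axon", "diameter_um"),
    "ra": ("geometry", "axon", "ra_MOhm_per_um"),
}


@dataclass
class SweepSpec:
    """Parameter axes (name -> values) plus measurement scope.

    Axis names: ``ais_length`` (um), ``gkv1``/``gnav16`` (nS/um^2),
    ``ais_start`` (um), ``axon_diameter`` (um), ``ra`` (MOhm/um).
    ``scope`` is ``"threshold"`` or ``"epsc_lag"``; lag sweeps use the
    fixed ``epsc_g_peak``.
    """

    axes: dict
    scope: str = "threshold"
    epsc_g_peak: float = 8.5        # nS
    step_duration: float = 250.0    # ms
    rheobase_resolution: float = 1.0  # pA

    def __post_init__(self) -> None:
        if self.scope not in ("threshold", "epsc_lag"):
            raise ValueError(f"unknown sweep scope {self.scope!r}")
        for name, values in self.axes.items():
            if name not in _AXIS_TO_OVERRIDE:
                raise ValueError(f"unknown sweep axis {name!r}")
            if len(values) == 0:
                raise ValueError(f"axis {name!r} is empty")


@dataclass
class SweepResult:
    """Long-format sweep table; failures are explicit rows, never dropped."""

    table: pd.DataFrame
    spec: SweepSpec
    model_digest: str

    def ok(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "ok"]


def _axis_overrides(names: Sequence[str], point) -> dict:
    over: dict = {}
    for name, value in zip(names, point):
        keys = _AXIS_TO_OVERRIDE[name]
        d = over
        for k in keys[:-1]:
            d = d.setdefault(k, {})
        d[keys[-1]] = float(value)
    return over


def measure_threshold(cell: CellModel, duration: float = 250.0,
                      resolution: float = 1.0, dt: float = 0.01,
                      bracket_hint=None):
    """(rheobase pA, threshold mV, latency ms) from the rheobase sweep."""
    rheo, tr = find_rheobase(cell, duration=duration, resolution=resolution,
                             dt=dt, return_trace=True, bracket_hint=bracket_hint)
    aps = [a for a in detect_aps(tr) if a.threshold_time >= 20.0]
    return rheo, aps[0].threshold, aps[0].threshold_time - 20.0


def _run_grid(config: dict, spec: SweepSpec, dt: float, worker) -> SweepResult:
    names = list(spec.axes)
    rows = []
    for point in itertools.product(*(spec.axes[n] for n in names)):
        row = dict(zip(names, (float(p) for p in point)))
        try:
            cell = build_cell(with_overrides(config, _axis_overrides(names, point)))
            row.update(worker(cell))
            row.setdefault("status", "ok")
        except NoRheobaseError:
            row["status"] = "no_spike"
        except Exception as e:  # noqa: BLE001 - per-point failures stay visible
            logger.warning("sweep point %s failed: %s", row, e)
            row["status"] = f"error: {type(e).__name__}"
        rows.append(row)
    table = pd.DataFrame(rows)
    return SweepResult(table=table, spec=spec,
                       model_digest=build_cell(config).digest)


def sweep_threshold(config: dict, spec: SweepSpec, dt: float = 0.01) -> SweepResult:
    """AP threshold (and rheobase, latency) at every grid point.

    Neighbouring grid points warm-start each other's rheobase bracket;
    the bisection itself still verifies both bracket sides, so results
    are independent of the visiting order.
    """
    last_rheo = [None]

    def worker(cell):
        hint = None
        if last_rheo[0] is not None:
            r = last_rheo[0]
            hint = (max(r - 30.0, 0.0), r + 30.0)
        rheo, thr, lat = measure_threshold(cell, spec.step_duration,
                                           spec.rheobase_resolution, dt,
                                           bracket_hint=hint)
        last_rheo[0] = rheo
        return {"threshold_mV": thr, "rheobase_pA": rheo, "latency_ms": lat}

    return _run_grid(config, spec, dt, worker)


def sweep_epsc_lag(config: dict, spec: SweepSpec, dt: float = 0.01) -> SweepResult:
    """EPSC-onset-to-AP-onset lag at fixed peak conductance per grid point."""
    proto = EPSCProtocol(peak_conductances=(spec.epsc_g_peak,))

    def worker(cell):
        _, lags = find_threshold_epsc(cell, proto, dt)
        if spec.epsc_g_peak not in lags:
            return {"status": "no_spike"}
        return {"lag_ms": lags[spec.epsc_g_peak]}

    return _run_grid(config, spec, dt, worker)


def sweep_geometry(config: dict, mode: str,
                   diameters: Sequence[float] = (0.6, 0.7, 0.8, 0.9),
                   ras: Sequence[float] = (0.8, 0.95, 1.1),
                   area_scales: Sequence[float] = (0.75, 1.0, 1.25),
                   dt: float = 0.01) -> SweepResult:
    """Axon diameter / axial-resistance sweeps in three coupling modes.

    ``physical``: diameter and Ra co-vary along DIAMETER_RA_PAIRS while
    per-area channel densities stay fixed, so total AIS conductance
    scales with diameter (membrane area = pi * diameter * length).
    ``ra_alone``: Ra varies with geometry (hence surface area and total
    conductance) fixed.  ``area_alone``: total AIS channel conductance
    scales while Ra and diameter stay fixed (implemented by scaling the
    two AIS densities).
    """
    if mode == "physical":
        axes = {"axon_diameter": [d for d, _ in DIAMETER_RA_PAIRS
                                  if d in diameters]}
        pair = dict(DIAMETER_RA_PAIRS)
        spec = SweepSpec(axes=axes)
        names = ["axon_diameter"]
        points = [(d,) for d in axes["axon_diameter"]]
        extra = [{"geometry": {"axon": {"ra_MOhm_per_um": pair[d]}}} for (d,) in points]
    elif mode == "ra_alone":
        spec = SweepSpec(axes={"ra": list(ras)})
        names = ["ra"]
        points = [(r,) for r in ras]
        extra = [{} for _ in points]
    elif mode == "area_alone":
        base_ais = config["ais"]
        spec = SweepSpec(axes={})
        names = []
        points = []
        extra = []
        rows = []
        for s in area_scales:
            over = {"ais": {
                "gnav16_nS_per_um2": base_ais["gnav16_nS_per_um2"] * s,
                "gkv1_nS_per_um2": base_ais["gkv1_nS_per_um2"] * s,
            }}
            row = {"area_scale": float(s)}
            try:
                cell = build_cell(with_overrides(config, over))
                rheo, thr, lat = measure_threshold(cell, dt=dt)
                row.update(threshold_mV=thr, rheobase_pA=rheo, status="ok")
            except NoRheobaseError:
                row["status"] = "no_spike"
            rows.append(row)
        return SweepResult(table=pd.DataFrame(rows),
                           spec=SweepSpec(axes={"gnav16": list(area_scales)}),
                           model_digest=build_cell(config).digest)
    else:
        raise ValueError(f"unknown geometry mode {mode!r}")

    rows = []
    for point, ex in zip(points, extra):
        row = dict(zip(names, (float(p) for p in point)))
        if mode == "physical":
            row["ra"] = ex["geometry"]["axon"]["ra_MOhm_per_um"]
        try:
            over = with_overrides(_axis_overrides(names, point), ex)
            cell = build_cell(with_overrides(config, over))
            rheo, thr, lat = measure_threshold(cell, dt=dt)
            row.update(threshold_mV=thr, rheobase_pA=rheo, status="ok")
        except NoRheobaseError:
            row["status"] = "no_spike"
        rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), spec=spec,
                       model_digest=build_cell(config).digest)


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

class CalibrationError(RuntimeError):
    """Iteration cap reached before all targets were inside tolerance."""

    def __init__(self, message: str, report: "CalibrationReport"):
        super().__init__(message)
        self.report = report


@dataclass
class CalibrationReport:
    iterations: int
    converged: bool
    scales: dict
    measured: dict
    targets: dict
    history: list = field(default_factory=list)


#: default calibration targets: (value, tolerance); Rin/tau tolerances are
#: the human interquartile half-ranges
DEFAULT_TARGETS = {
    "threshold": (-43.0, 0.5),     # mV
    "rin": (187.9, 88.0),          # MOhm
    "tau": (6.65, 1.98),           # ms
    "v_rest": (-68.0, 6.0),        # mV, unbiased resting potential
}

#: conductance dials (multiplicative scales) in fixed iteration order
_DIALS = {
    "gnav16": {"ais": "gnav16_nS_per_um2"},
    "gnav12": ("nav12",),
    "gkv3": ("kv3",),
    "leak": ("leak_dend",),
    "gih": ("ih",),
}


def _apply_scales(config: dict, scales: dict) -> dict:
    over: dict = {"channels": {}}
    for dial, s in scales.items():
        target = _DIALS[dial]
        if isinstance(target, dict):
            key = target["ais"]
            over.setdefault("ais", {})[key] = config["ais"][key] * s
        else:
            chan = target[0]
            regions = {k: (v if isinstance(v, str) else v * s)
                       for k, v in config["channels"][chan]["regions"].items()}
            over["channels"][chan] = {"regions": regions}
    return with_overrides(config, over)


def baseline_features(config: dict, dt: float = 0.01) -> dict:
    """Threshold, Rin, tau and resting potential of one configuration."""
    cell = build_cell(config)
    out: dict = {}
    try:
        _, out["threshold"], _ = measure_threshold(cell, dt=dt)
    except NoRheobaseError:
        out["threshold"] = None
    tr = integrate(cell, StepProtocol(amplitude=10.0, duration=250.0), dt)
    if detect_aps(tr):
        out["rin"] = out["tau"] = None
    else:
        out["rin"] = measure_rin([tr], [10.0], 20.0, 250.0)
        out["tau"] = measure_tau(tr, 20.0)
    # unbiased resting potential: relax 400 ms without holding current
    import numpy as _np

    v = _np.full(cell.n_nodes, -70.0)
    m, h = cell._steady_gates(-70.0)
    zeros = _np.zeros(int(400.0 / dt))
    vrec = cell._run(v, m, h, zeros, zeros, dt)
    out["v_rest"] = float(vrec[-1, 0])
    return out


def _calibration_loss(measured: dict, targets: dict) -> float:
    loss = 0.0
    for name, (tgt, tol) in targets.items():
        v = measured.get(name)
        loss += 25.0 if v is None else ((v - tgt) / tol) ** 2
    return loss


def calibrate_baseline(config: Optional[dict] = None,
                       targets: Optional[dict] = None,
                       max_iter: int = 40, step: float = 0.15,
                       dt: float = 0.01):
    """Deterministic coordinate descent on conductance scales.

    Walks the dials {gnav16, gnav12, gkv3, leak, gih} in fixed order from
    the shipped defaults, multiplying each by (1 ± step) and keeping any
    move that lowers the weighted squared target error; the step halves
    when a full pass makes no progress.  Stops as soon as every target is
    inside its tolerance.  Returns ``(calibrated_config, report)``;
    raises :class:`CalibrationError` (with the best-so-far report) at the
    iteration cap.
    """
    config = config or standard_config()
    targets = targets or DEFAULT_TARGETS
    scales = {d: 1.0 for d in _DIALS}
    measured = baseline_features(config, dt)
    loss = _calibration_loss(measured, targets)
    history = [{"iteration": 0, "scales": dict(scales),
                "measured": dict(measured), "loss": loss}]

    def within(meas):
        return all(
            meas.get(k) is not None and abs(meas[k] - t) <= tol
            for k, (t, tol) in targets.items()
        )

    it = 0
    cur_step = step
    converged = within(measured)
    while not converged and it < max_iter:
        improved = False
        for dial in _DIALS:
            if it >= max_iter or converged:
                break
            it += 1
            best = (loss, scales[dial], measured)
            for factor in (1.0 - cur_step, 1.0 + cur_step):
                trial = dict(scales)
                trial[dial] = scales[dial] * factor
                meas = baseline_features(_apply_scales(config, trial), dt)
                l2 = _calibration_loss(meas, targets)
                if l2 < best[0]:
                    best = (l2, trial[dial], meas)
            if best[0] < loss - 1e-9:
                loss, scales[dial], measured = best
                improved = True
                history.append({"iteration": it, "scales": dict(scales),
                                "measured": dict(measured), "loss": loss})
                converged = within(measured)
        if not improved:
            cur_step /= 2.0
            if cur_step < 0.005:
                break

    report = CalibrationReport(iterations=it, converged=converged,
                               scales=scales, measured=measured,
                               targets=targets, history=history)
    final = _apply_scales(config, scales)
    if not converged:
        raise CalibrationError(
            f"calibration cap: {it} iterations, residual loss {loss:.3g}; "
            f"best measured {measured}", report,
        )
    return final, report
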