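"""Spirometry and respiratory-mechanics analysis.

Derives from maneuver traces: exhalation onset (back-extrapolation),
FEV_x / FVC / their ratio, the FEV_x calibration rule that picks the
species-appropriate timed volume, multistroke inspiratory capacity, and
quasistatic compliance from a single-exponential fit to the deflation
limb of a PV loop (``V(P) = A - B * exp(-K * P)``), with the customary
R^2 > 0.9 acceptance gate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InputError, NoExhalationError, CalibrationError
from .types import FlowVolumeTrace, PVLoop, ManeuverSegment
from .synthetic import salazar_knowles_volume


@dataclass
class SpirometryResult:
    """Timed and total forced-expiratory volumes for one maneuver."""

    t0_s: float
    x_seconds: float
    fev_ml: float
    fvc_ml: float
    ratio: float
    truncated: bool = False
    body_length_cm: float | None = None
    fev_per_cm: float | None = None
    fvc_per_cm: float | None = None


@dataclass
class CalibrationResult:
    """Outcome of the FEV_x grid search over control maneuvers."""

    x_star_s: float
    floor: float
    quantile: str | float
    table: pd.DataFrame  # columns: x_seconds, then ratio_<i> per control, then stat


@dataclass
class ComplianceFit:
    """Deflation-limb exponential fit and the derived quasistatic compliance."""

    a_ml: float
    b_ml: float
    k_per_cmh2o: float
    cst_ml_cmh2o: float
    p_ref_cmh2o: float
    r_squared: float
    accepted: bool
    linear_fallback: bool = False


def detect_exhalation_start(
    trace: FlowVolumeTrace, noise_floor_frac: float = 0.02
) -> float:
    """Exhalation onset t0 by back-extrapolation of the rising flow limb.

    A line is fitted to the samples between 25% and 75% of peak flow on
    the rising limb; t0 is its zero-crossing, clamped to the trace range.
    If the rise is effectively instantaneous (fewer than two usable
    samples), t0 falls back to the first sample with flow above the noise
    floor.
    """
    flow = trace.flow_ml_s
    peak_idx = int(np.argmax(flow))
    peak = flow[peak_idx]
    floor = noise_floor_frac * peak if peak > 0 else 0.0
    if peak <= 0 or not np.any(flow > floor):
        raise NoExhalationError("no expiratory flow above the noise floor")
    # rising limb: from the last below-floor sample before the peak
    below = np.flatnonzero(flow[: peak_idx + 1] <= floor)
    start_idx = int(below[-1]) if below.size else 0
    rise = slice(start_idx, peak_idx + 1)
    t_rise = trace.time_s[rise]
    f_rise = flow[rise]
    sel = (f_rise >= 0.25 * peak) & (f_rise <= 0.75 * peak)
    if sel.sum() >= 2:
        slope, intercept = np.polyfit(t_rise[sel], f_rise[sel], 1)
        if slope > 0:
            t0 = -intercept / slope
            return float(np.clip(t0, trace.time_s[0], trace.time_s[-1]))
    first_above = int(np.flatnonzero(flow > floor)[0])
    return float(trace.time_s[first_above])


def compute_spirometry(
    trace: FlowVolumeTrace,
    x_seconds: float = 0.4,
    body_length_cm: float | None = None,
    end_flow_frac: float = 0.01,
    end_sustain_s: float = 0.05,
) -> SpirometryResult:
    """FEV_x, FVC, and their ratio from a forced-expiration trace.

    FEV_x is the cumulative exhaled volume at ``t0 + x`` by linear
    interpolation.  The end-of-test criterion (flow below
    ``end_flow_frac`` of peak sustained for ``end_sustain_s``) decides
    whether the maneuver was complete; FVC is the cumulative volume at
    the end of the trace, flagged ``truncated`` if the criterion was
    never met.  With ``body_length_cm``, length-normalised variants are
    attached (the ratio is unchanged by the common factor).
    """
    if x_seconds <= 0:
        raise InputError(f"x must be positive, got {x_seconds}")
    t0 = detect_exhalation_start(trace)
    vol_at = lambda t: float(np.interp(t, trace.time_s, trace.volume_ml))
    v0 = vol_at(t0)
    fev = max(vol_at(min(t0 + x_seconds, trace.time_s[-1])) - v0, 0.0)
    fvc = float(trace.volume_ml[-1]) - v0
    if fvc <= 0:
        raise InputError("FVC is zero - no exhaled volume after onset")

    peak = float(np.max(trace.flow_ml_s))
    n_sustain = max(int(round(end_sustain_s / trace.dt)), 1)
    low = trace.flow_ml_s < end_flow_frac * peak
    after_onset = trace.time_s > t0
    low &= after_onset
    # sustained low-flow window after onset?
    truncated = True
    run = 0
    for is_low in low:
        run = run + 1 if is_low else 0
        if run >= n_sustain:
            truncated = False
            break
    ratio = min(fev / fvc, 1.0)
    res = SpirometryResult(
        t0_s=t0,
        x_seconds=x_seconds,
        fev_ml=fev,
        fvc_ml=fvc,
        ratio=ratio,
        truncated=truncated,
        body_length_cm=body_length_cm,
    )
    if body_length_cm is not None:
        res.fev_per_cm = normalize_by_length(fev, body_length_cm)
        res.fvc_per_cm = normalize_by_length(fvc, body_length_cm)
    return res


def calibrate_fev_x(
    control_traces,
    floor: float = 0.7,
    grid=None,
    quantile: str | float = "min",
) -> CalibrationResult:
    """Pick the smallest timed volume x at which controls stay above the floor.

    For each grid value x, the FEV_x:FVC ratio is computed for every
    control maneuver; x* is the smallest x at which the chosen summary of
    control ratios is strictly greater than ``floor``.  The default
    summary (``"min"``) requires all controls to clear the floor;
    ``"median"`` or a numeric quantile in (0, 1) relax that.

    Raises :class:`CalibrationError` (carrying the ratio table) if the
    criterion is never met on the grid.
    """
    controls = list(control_traces)
    if not controls:
        raise InputError("need at least one control trace")
    if grid is None:
        grid = np.round(np.arange(0.1, 1.01, 0.1), 10)
    grid = np.sort(np.asarray(grid, dtype=float))
    if grid.size == 0:
        raise InputError("calibration grid is empty")

    ratios = np.empty((grid.size, len(controls)))
    for j, tr in enumerate(controls):
        for i, x in enumerate(grid):
            ratios[i, j] = compute_spirometry(tr, x_seconds=x).ratio
    if quantile == "min":
        stat = ratios.min(axis=1)
    elif quantile == "median":
        stat = np.median(ratios, axis=1)
    else:
        stat = np.quantile(ratios, float(quantile), axis=1)

    table = pd.DataFrame(ratios, columns=[f"ratio_{j}" for j in range(len(controls))])
    table.insert(0, "x_seconds", grid)
    table["stat"] = stat

    meets = stat > floor  # strictly greater, matching the ">0.7" rule
    if not meets.any():
        raise CalibrationError(
            f"no grid value yields a {quantile} control ratio > {floor}", table=table
        )
    x_star = float(grid[int(np.argmax(meets))])
    return CalibrationResult(x_star_s=x_star, floor=floor, quantile=quantile, table=table)


def ic_multistroke(
    seg1: ManeuverSegment,
    seg2: ManeuverSegment,
    correction_delta: float = 0.0,
) -> float:
    """Inspiratory capacity from the two-stroke maneuver.

    The two delivered volumes (PEEP->mid and mid->opening pressure) are
    summed; because lung volume is a state function, this equals a single
    full stroke for any monotone PV relationship.  The optional
    ``correction_delta`` divides out a known multistroke recruitment
    overestimate: ``IC = (v1 + v2) / (1 + delta)``.
    """
    if not math.isclose(seg1.end_cmh2o, seg2.start_cmh2o, abs_tol=1e-9):
        raise InputError(
            f"segments must abut: first ends at {seg1.end_cmh2o} cmH2O but "
            f"second starts at {seg2.start_cmh2o} cmH2O"
        )
    if correction_delta < 0:
        raise InputError("correction delta must be >= 0")
    return (seg1.volume_ml + seg2.volume_ml) / (1.0 + correction_delta)


def fit_pv_compliance(
    loop: PVLoop,
    p_ref_cmh2o: float = 5.0,
    r2_gate: float = 0.9,
    k_collapse: float = 1e-3,
) -> ComplianceFit:
    """Quasistatic compliance from the deflation limb of a PV loop.

    Fits ``V(P) = A - B * exp(-K * P)`` by nonlinear least squares and
    reports ``Cst = dV/dP at P_ref = B * K * exp(-K * P_ref)``.  Fits
    with R^2 at or below the gate are flagged ``accepted=False`` and
    should be excluded from averages.  If K collapses toward zero the
    relation is effectively linear and a straight-line fallback is used
    (``Cst`` = slope).
    """
    p, v = loop.limb_points("deflation")
    if p.size < 4:
        raise InputError(f"deflation limb needs >= 4 points, got {p.size}")
    if np.ptp(p) < 10.0:
        raise InputError(
            f"deflation limb must span >= 10 cmH2O, spans {np.ptp(p):.1f}"
        )
    if np.any(np.diff(p) <= 0):
        raise InputError("deflation-limb pressures contain duplicates")

    def _r2(y, y_hat):
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            return 1.0
        return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot

    linear = False
    a = b = k = float("nan")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                salazar_knowles_volume,
                p,
                v,
                p0=(float(v.max()), float(np.ptp(v)) or 1.0, 0.1),
                bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, 10.0]),
                maxfev=10000,
            )
        a, b, k = (float(x) for x in popt)
        if k <= k_collapse:
            linear = True
    except RuntimeError:
        linear = True

    if linear:
        slope, intercept = np.polyfit(p, v, 1)
        cst = float(slope)
        r2 = _r2(v, slope * p + intercept)
        a, b, k = float(intercept), 0.0, 0.0
    else:
        cst = b * k * math.exp(-k * p_ref_cmh2o)
        r2 = _r2(v, salazar_knowles_volume(p, a, b, k))

    return ComplianceFit(
        a_ml=a,
        b_ml=b,
        k_per_cmh2o=k,
        cst_ml_cmh2o=cst,
        p_ref_cmh2o=p_ref_cmh2o,
        r_squared=r2,
        accepted=r2 > r2_gate,
        linear_fallback=linear,
    )


def normalize_by_length(value: float, length_cm: float) -> float:
    """Index a volume or capacity to body length (mL -> mL/cm)."""
    if length_cm <= 0:
        raise InputError(f"body length must be positive, got {length_cm}")
    return value / length_cm
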