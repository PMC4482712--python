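"""Action-potential biomarkers and the S1-S2 restitution protocol.

Eight scalar outputs summarise each simulator run: six are measured
directly on the final S1 beat (maximum upstroke velocity, peak and dome
voltage, APD90, resting voltage, APD50) and two characterise restitution
dynamics (the maximum slope of the fitted APD-restitution curve and the
minimum diastolic interval that still elicits a beat).

Repolarisation thresholds are referenced to the plateau dome: the APD at
fraction ``f`` ends where V first falls below ``dome - f*(dome - rest)``,
timed from the instant of maximum dV/dt.  Referencing the spike peak
instead is available via ``reference="peak"`` but shortens APD50 by
~60 ms because the sodium spike inflates the amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .errors import (
    CensoredMeasurementError,
    InsufficientCurveError,
    NoActionPotentialError,
    RestitutionFitError,
)
from .lr1991 import APTrace, Conductances, StimulusProtocol, run_s1_protocol, run_s2

__all__ = [
    "Biomarkers",
    "RestitutionCurve",
    "RestitutionFit",
    "CouplingScan",
    "extract_ap_biomarkers",
    "measure_apd",
    "restitution_protocol",
    "fit_restitution",
    "max_restitution_slope",
]

#: an S2 beat counts as captured only if its APD90 exceeds this (ms)
CAPTURE_APD90 = 100.0
#: upstroke detection threshold (mV/ms)
UPSTROKE_THRESHOLD = 1.0
#: offset from the upstroke used to skip the sodium spike when locating
#: the plateau dome (ms)
DOME_OFFSET = 20.0


@dataclass(frozen=True)
class Biomarkers:
    """The eight scalar outputs of one simulator run.

    ``apdr_slope`` and ``min_di`` are NaN when only the S1 beat was
    analysed.  Column order of :meth:`as_array` matches the design-set
    layout.
    """

    max_dvdt: float
    peak_v: float
    dome_v: float
    apd90: float
    resting_v: float
    apd50: float
    apdr_slope: float = math.nan
    min_di: float = math.nan

    FIELDS = ("max_dvdt", "peak_v", "dome_v", "apd90", "resting_v",
              "apd50", "apdr_slope", "min_di")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS])

    def with_restitution(self, apdr_slope: float, min_di: float) -> "Biomarkers":
        return Biomarkers(self.max_dvdt, self.peak_v, self.dome_v, self.apd90,
                          self.resting_v, self.apd50, apdr_slope, min_di)


@dataclass
class RestitutionCurve:
    """(DI, APD90) pairs collected from S2 beats, plus the minimum DI."""

    points: Sequence[tuple]
    min_di: float

    def as_arrays(self):
        arr = np.asarray(self.points, dtype=float)
        return arr[:, 0], arr[:, 1]

    def to_csv(self, path) -> None:
        di, apd = self.as_arrays()
        np.savetxt(path, np.column_stack([di, apd]), delimiter=",",
                   header="di_ms,apd90_ms", comments="")


@dataclass(frozen=True)
class RestitutionFit:
    """Parameters of APD(DI) = a - b*exp(-DI/c) and the slope at min DI."""

    a: float
    b: float
    c: float
    max_slope: float


@dataclass(frozen=True)
class CouplingScan:
    """Two-stage S2 coupling schedule: coarse decrements from the S1 cycle
    length until capture fails, then 1 ms refinement of the failure edge."""

    decrement: float = 10.0
    refine: float = 1.0


def _interp_crossing(t: np.ndarray, v: np.ndarray, idx: int, threshold: float) -> float:
    """Linear interpolation of the downward crossing between idx-1 and idx."""
    if idx == 0:
        return t[0]
    t1, t2 = t[idx - 1], t[idx]
    v1, v2 = v[idx - 1], v[idx]
    if v1 == v2:
        return t2
    return t1 + (v1 - threshold) / (v1 - v2) * (t2 - t1)


def _upstroke(trace: APTrace):
    """Locate the upstroke of the beat following the trace's stimulus.

    Returns (i_onset, i_up, t_up, max_dvdt, resting_v).
    """
    t, v = trace.times, trace.voltages
    i_onset = int(np.searchsorted(t, trace.stimulus_onset - 1e-9))
    resting_v = float(v[i_onset]) if i_onset < v.size else float(v[-1])
    fd = np.diff(v[i_onset:]) / np.diff(t[i_onset:])
    if fd.size == 0:
        raise NoActionPotentialError("trace too short after stimulus onset")
    if trace.dvdt is not None:
        inst = trace.dvdt[i_onset:-1]
        max_dvdt = float(np.max(inst[: fd.size])) if inst.size else float(np.max(fd))
    else:
        max_dvdt = float(np.max(fd))
    if max_dvdt < UPSTROKE_THRESHOLD:
        raise NoActionPotentialError(
            f"no action potential: max dV/dt {max_dvdt:.3g} mV/ms"
        )
    i_up = i_onset + int(np.argmax(fd))
    return i_onset, i_up, float(t[i_up]), max_dvdt, resting_v


def _dome(trace: APTrace, i_up: int, t_up: float, peak_v: float, resting_v: float) -> float:
    """Plateau dome: maximum V between (upstroke + 20 ms) and the
    provisional (peak-referenced) 50% repolarisation crossing."""
    t, v = trace.times, trace.voltages
    thr = peak_v - 0.5 * (peak_v - resting_v)
    i_peak = i_up + int(np.argmax(v[i_up:]))
    after = np.nonzero(v[i_peak:] < thr)[0]
    t_end = _interp_crossing(t, v, i_peak + after[0], thr) if after.size else t[-1]
    window = (t >= t_up + DOME_OFFSET) & (t <= t_end)
    if not np.any(window):
        return peak_v
    return float(np.max(v[window]))


def measure_apd(trace: APTrace, fraction: float, reference: str = "dome") -> float:
    """Action-potential duration to a given repolarisation fraction (ms).

    Measured from the time of maximum dV/dt to the first subsequent
    downward crossing of ``ref - fraction*(ref - rest)`` with linear
    interpolation between samples, where ``ref`` is the plateau dome
    (default) or the spike peak.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if reference not in ("dome", "peak"):
        raise ValueError("reference must be 'dome' or 'peak'")
    t, v = trace.times, trace.voltages
    _, i_up, t_up, _, resting_v = _upstroke(trace)
    peak_v = float(np.max(v[i_up:]))
    ref = peak_v if reference == "peak" else _dome(trace, i_up, t_up, peak_v, resting_v)
    threshold = ref - fraction * (ref - resting_v)
    i_peak = i_up + int(np.argmax(v[i_up:]))
    below = np.nonzero(v[i_peak:] < threshold)[0]
    if below.size == 0:
        raise CensoredMeasurementError(
            f"repolarisation to fraction {fraction} not reached before trace end"
        )
    t_cross = _interp_crossing(t, v, i_peak + below[0], threshold)
    return float(t_cross - t_up)


def extract_ap_biomarkers(trace: APTrace) -> Biomarkers:
    """The six direct biomarkers of a single stimulated beat.

    Raises :class:`NoActionPotentialError` when the beat was not elicited
    and :class:`CensoredMeasurementError` when it does not repolarise
    within the trace.
    """
    t, v = trace.times, trace.voltages
    _, i_up, t_up, max_dvdt, resting_v = _upstroke(trace)
    peak_v = float(np.max(v[i_up:]))
    dome_v = _dome(trace, i_up, t_up, peak_v, resting_v)
    apd90 = measure_apd(trace, 0.9)
    apd50 = measure_apd(trace, 0.5)
    return Biomarkers(
        max_dvdt=max_dvdt, peak_v=peak_v, dome_v=dome_v,
        apd90=apd90, resting_v=resting_v, apd50=apd50,
    )


def _s2_apd90(s1_trace: APTrace, g: Conductances, coupling: float,
              p: StimulusProtocol, method: str) -> Optional[float]:
    """APD90 of the S2 beat at a given coupling, or None if not captured."""
    try:
        tr = run_s2(s1_trace.final_state, g, coupling, p, method=method)
        apd90 = measure_apd(tr, 0.9)
    except (NoActionPotentialError, CensoredMeasurementError):
        return None
    return apd90 if apd90 > CAPTURE_APD90 else None


def restitution_protocol(
    g: Conductances,
    p: StimulusProtocol = StimulusProtocol(),
    scan: CouplingScan = CouplingScan(),
    s1_trace: Optional[APTrace] = None,
    method: str = "rl",
) -> RestitutionCurve:
    """Build the APD-restitution curve by an S1-S2 coupling scan.

    S2 stimuli are delivered at couplings starting from the S1 cycle
    length and shortened in ``scan.decrement`` steps until a beat fails
    the APD90 > 100 ms capture criterion; the failure edge is then
    refined in ``scan.refine`` steps.  Each point contributes
    DI = coupling - APD90(steady S1 beat).  Points with non-positive DI
    are discarded.
    """
    if s1_trace is None:
        s1_trace = run_s1_protocol(g, p, method=method)
    apd90_s1 = measure_apd(s1_trace, 0.9)

    points = []

    def try_coupling(c: float) -> bool:
        apd90 = _s2_apd90(s1_trace, g, c, p, method)
        di = c - apd90_s1
        if apd90 is None or di <= 0.0:
            return False
        points.append((di, apd90))
        return True

    coupling = p.s1_cycle_length
    last_success = None
    while coupling > 0:
        if try_coupling(coupling):
            last_success = coupling
            coupling -= scan.decrement
        else:
            break
    if last_success is not None and scan.refine < scan.decrement:
        c = last_success - scan.refine
        floor = last_success - scan.decrement
        while c > floor and try_coupling(c):
            c -= scan.refine
    if len(points) < 4:
        raise InsufficientCurveError(
            f"only {len(points)} restitution points captured; need >= 4"
        )
    min_di = min(di for di, _ in points)
    return RestitutionCurve(points=sorted(points), min_di=min_di)


def max_restitution_slope(fit, di_min: float) -> float:
    """Slope dAPD/dDI of the exponential restitution curve at DI = di_min.

    For APD(DI) = a - b*exp(-DI/c) the derivative is (b/c)*exp(-di_min/c).
    """
    b, c = (fit.b, fit.c) if isinstance(fit, RestitutionFit) else (fit[1], fit[2])
    if c <= 0:
        raise ValueError("time constant c must be positive")
    return float(b / c * math.exp(-di_min / c))


def fit_restitution(curve: RestitutionCurve) -> RestitutionFit:
    """Least-squares fit of APD(DI) = a - b*exp(-DI/c) by Nelder-Mead.

    Derivative-free simplex search with restarts; the reported
    ``max_slope`` is the fitted curve's slope at the curve's minimum DI.
    """
    di, apd = curve.as_arrays()
    if np.unique(di).size < 4:
        raise InsufficientCurveError("need >= 4 distinct DI values")

    def ssr(params):
        a, b, c = params
        if c <= 0:
            return 1e300
        r = apd - (a - b * np.exp(-di / c))
        return float(r @ r)

    span = float(np.max(apd) - np.min(apd))
    starts = [
        np.array([np.max(apd), max(span, 1.0), 50.0]),
        np.array([np.max(apd), max(span, 1.0), 20.0]),
        np.array([np.max(apd) + span, 2.0 * max(span, 1.0), 100.0]),
    ]
    best = None
    for x0 in starts:
        res = minimize(ssr, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        # polish from the incumbent to guard against premature collapse
        res = minimize(ssr, res.x, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)) or best.x[2] <= 0:
        raise RestitutionFitError(f"restitution fit failed: {best}")
    a, b, c = map(float, best.x)
    return RestitutionFit(a=a, b=b, c=c,
                          max_slope=max_restitution_slope((a, b, c), curve.min_di))
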