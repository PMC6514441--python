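"""Electrophysiological feature extraction from current-clamp traces.

The definitions mirror standard patch-clamp analysis practice for this
cell type: passive properties from a mono-exponential fit to the
response to a long hyperpolarizing step; spike threshold from a dV/dt
criterion; AP amplitude as peak minus threshold; fast AHP measured
against the steady-state step voltage (single-spike traces only); slow
AHP measured against the pre-step baseline after step offset; firing
rates from interspike intervals, with the sustained rate defined over
the last three intervals provided they fall in the final half of the
step.  Absolute voltages can be corrected for the liquid junction
potential with a fixed -10 mV adjustment; relative quantities
(amplitudes, deflections) are never corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import DetectionError, FitError, NotExcitableError, ParameterError
from .model import Trace

#: fixed liquid-junction-potential adjustment applied to absolute voltages
LJP_MV = -10.0


def ljp_correct(values):
    """Apply the fixed liquid-junction correction to absolute voltages (mV)."""
    return np.asarray(values, dtype=float) + LJP_MV if np.ndim(values) \
        else float(values) + LJP_MV


def detect_spikes(v: np.ndarray, dt: float, threshold: float = 0.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Spike peak sample indices: upward crossings of ``threshold``.

    A refractory lockout suppresses double counting on noisy peaks; the
    default 0 mV crossing is robust for full-height model spikes and is
    configurable for stunted ones.
    """
    v = np.asarray(v, dtype=float)
    above = v >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    lockout = int(round(refractory_ms / dt))
    peaks = []
    last = -10 ** 9
    for c in crossings:
        if c - last < lockout:
            continue
        end = c
        while end < v.size and v[end] >= threshold:
            end += 1
        peaks.append(c + int(np.argmax(v[c:end])))
        last = c
    return np.asarray(peaks, dtype=int)


def _smooth(v: np.ndarray, width: int = 5) -> np.ndarray:
    if width <= 1:
        return v
    kernel = np.ones(width) / width
    return np.convolve(v, kernel, mode="same")


@dataclass
class PassiveFit:
    """Passive membrane properties from a hyperpolarizing step response."""

    delta_v: float   # mV, fitted maximal deflection
    tau_m: float     # ms
    r_in: float      # MOhm
    c_m: float       # pF (= tau_m / r_in, unit-consistent)
    v_hold: float    # mV
    residual: float  # mV rms of the fit


def fit_passive(trace: Trace, step_window: tuple[int, int] | None = None,
                i_inj: float | None = None) -> PassiveFit:
    """Fit  V(t) = dV*exp(-t/tau_m) + (V_hold - dV)  over the step.

    ``i_inj`` is the step amplitude in pA (non-zero); R_in = dV/I_inj
    and C_m = tau_m/R_in follow from the fit.  Nonlinear least squares
    (Levenberg-Marquardt).
    """
    if step_window is None:
        step_window = trace.meta["step_window"]
    if i_inj is None:
        i_inj = trace.meta["step_pa"]
    if i_inj == 0:
        raise ParameterError("i_inj must be non-zero")
    a, b = step_window
    seg = trace.v[a:b]
    t = np.arange(seg.size) * trace.dt

    def model(t, dv, tau, vh):
        return dv * np.exp(-t / tau) + (vh - dv)

    v_hold0 = float(seg[0])
    v_ss0 = float(seg[-max(1, seg.size // 10):].mean())
    p0 = (v_hold0 - v_ss0, max(trace.dt, (b - a) * trace.dt / 10.0), v_hold0)
    try:
        popt, _ = curve_fit(model, t, seg, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"passive fit did not converge: {exc}") from exc
    dv, tau, vh = map(float, popt)
    if tau <= 0:
        raise FitError(f"non-physical fitted time constant {tau:.3g} ms")
    resid = float(np.sqrt(np.mean((model(t, *popt) - seg) ** 2)))
    r_in = dv / (-i_inj) * 1000.0 if i_inj < 0 else -dv / i_inj * 1000.0
    if r_in <= 0:
        raise FitError("fitted deflection opposes the injected current")
    return PassiveFit(delta_v=dv, tau_m=tau, r_in=r_in,
                      c_m=tau / (r_in / 1000.0), v_hold=vh, residual=resid)


def detect_threshold(trace: Trace, spike_peak: int, criterion: float = 5.0,
                     smooth_width: int = 5) -> float:
    """Spike threshold (mV): where dV/dt last rises through ``criterion``.

    The derivative is computed on a lightly smoothed copy; the returned
    voltage is read from the raw trace.  Raises DetectionError if the
    criterion is never crossed before the peak.
    """
    if spike_peak <= 1 or spike_peak >= trace.v.size:
        raise DetectionError("spike index outside trace")
    dvdt = np.gradient(_smooth(trace.v, smooth_width), trace.dt)
    seg = dvdt[:spike_peak + 1]
    below = seg < criterion
    idx = np.flatnonzero(below[:-1] & ~below[1:]) + 1
    if idx.size == 0:
        raise DetectionError(
            f"dV/dt never crossed {criterion} mV/ms before the peak")
    return float(trace.v[idx[-1]])


def calculated_rheobase(v_th: float, v_hold: float, r_in: float) -> float:
    """Ohmic rheobase estimate (V_th - V_hold)/R_in in pA (R_in in MOhm)."""
    if r_in <= 0:
        raise ParameterError("r_in must be positive")
    return (v_th - v_hold) / r_in * 1000.0


def measured_rheobase_from_steps(step_currents, spike_counts) -> float:
    """Measured rheobase from an incrementing family of step responses.

    The smallest step that elicited exactly one spike; if the increment
    jumped from zero spikes straight to several, the mean of the adjacent
    sub- and suprathreshold step currents.
    """
    currents = np.asarray(step_currents, dtype=float)
    counts = np.asarray(spike_counts, dtype=int)
    if currents.size != counts.size or np.any(np.diff(currents) <= 0):
        raise ParameterError("need matched, strictly increasing steps")
    firing = np.flatnonzero(counts >= 1)
    if firing.size == 0:
        raise NotExcitableError("no step elicited a spike")
    k = firing[0]
    if counts[k] == 1 or k == 0:
        return float(currents[k])
    return float(0.5 * (currents[k - 1] + currents[k]))


@dataclass
class APMetrics:
    """Shape metrics of a single action potential."""

    v_threshold: float  # mV, absolute
    peak: float         # mV
    amplitude: float    # mV, peak - threshold
    half_width: float   # ms at half amplitude
    rise_slope: float   # mV/ms, max dV/dt on the upstroke


def ap_metrics(trace: Trace, spike_peak: int,
               criterion: float = 5.0) -> APMetrics:
    v = trace.v
    v_th = detect_threshold(trace, spike_peak, criterion=criterion)
    peak = float(v[spike_peak])
    amp = peak - v_th
    if amp <= 0:
        raise DetectionError("non-positive AP amplitude")
    half = v_th + amp / 2.0

    def _cross(i, j, direction):
        # linear interpolation of the half-amplitude crossing in [i, j)
        idx = np.flatnonzero((v[i:j - 1] < half) != (v[i + 1:j] < half))
        if idx.size == 0:
            raise DetectionError("half-amplitude level never crossed")
        k = (i + idx[0]) if direction > 0 else (i + idx[-1])
        frac = (half - v[k]) / (v[k + 1] - v[k])
        return (k + frac) * trace.dt

    left = _cross(max(0, spike_peak - int(50 / trace.dt)), spike_peak + 1, +1)
    right_end = min(v.size, spike_peak + int(50 / trace.dt))
    right = _cross(spike_peak, right_end, -1)
    dvdt = np.gradient(v, trace.dt)
    up0 = max(0, spike_peak - int(20 / trace.dt))
    rise = float(dvdt[up0:spike_peak + 1].max())
    return APMetrics(v_threshold=v_th, peak=peak, amplitude=amp,
                     half_width=float(right - left), rise_slope=rise)


@dataclass
class AHPMetrics:
    """Afterhyperpolarization amplitude and decay metrics."""

    kind: str          # "fAHP" | "sAHP"
    amplitude: float   # mV (> 0)
    half_decay: float  # ms
    duration: float | None = None  # ms, fAHP only


def fahp_metrics(trace: Trace, step_window: tuple[int, int] | None = None,
                 baseline_tol: float = 0.5) -> AHPMetrics | None:
    """Fast AHP after the single spike of a minimal suprathreshold step.

    Amplitude is measured against the steady-state voltage late in the
    step; returns None (feature absent) unless the step elicited exactly
    one spike.
    """
    if step_window is None:
        step_window = trace.meta["step_window"]
    a, b = step_window
    peaks = detect_spikes(trace.v, trace.dt)
    peaks = peaks[(peaks >= a) & (peaks < b)]
    if peaks.size != 1:
        return None
    p = peaks[0]
    tail = max(1, (b - a) // 10)
    v_ss = float(trace.v[b - tail:b].mean())
    seg = trace.v[p:b]
    k_min = int(np.argmin(seg))
    v_min = float(seg[k_min])
    amp = v_ss - v_min
    if amp <= 0:
        return None
    half_level = v_min + amp / 2.0
    after = seg[k_min:]
    above = np.flatnonzero(after >= half_level)
    if above.size == 0:
        return None
    half_decay = above[0] * trace.dt
    v_th = detect_threshold(trace, p)
    onset_idx = np.flatnonzero(trace.v[a:p] < v_th)
    onset = (a + onset_idx[-1]) if onset_idx.size else p
    back = np.flatnonzero(after >= v_ss - baseline_tol)
    duration = (p - onset + k_min + back[0]) * trace.dt if back.size else None
    return AHPMetrics(kind="fAHP", amplitude=amp,
                      half_decay=float(half_decay), duration=duration)


def sahp_metrics(trace: Trace, step_window: tuple[int, int] | None = None
                 ) -> AHPMetrics | None:
    """Slow AHP after step offset, measured against the holding baseline."""
    if step_window is None:
        step_window = trace.meta["step_window"]
    a, b = step_window
    if b >= trace.v.size - 10:
        return None
    pre = max(1, int(round(100.0 / trace.dt)))
    baseline = float(trace.v[a - pre:a].mean())
    seg = trace.v[b:]
    k_min = int(np.argmin(seg))
    v_min = float(seg[k_min])
    amp = baseline - v_min
    if amp <= 0:
        return None
    half_level = v_min + amp / 2.0
    above = np.flatnonzero(seg[k_min:] >= half_level)
    if above.size == 0:
        return None
    return AHPMetrics(kind="sAHP", amplitude=amp,
                      half_decay=float(above[0] * trace.dt))


@dataclass
class FiringRates:
    """Instantaneous firing-rate summary over one step."""

    ifr: np.ndarray                 # Hz, one per interspike interval
    ifr_times: np.ndarray           # ms, time of each interval's end spike
    maximal_rate: float | None      # Hz, first-interval rate
    sustained_rate: float | None    # Hz, mean of last three qualifying ISIs
    sra_ratio: float | None         # maximal / sustained


def firing_rates(spike_times_ms, step_window_ms) -> FiringRates:
    """Rates from spike times (ms) within a step (window in ms).

    The sustained rate requires at least four spikes whose last three
    interspike intervals lie entirely within the final half of the step.
    """
    t = np.asarray(spike_times_ms, dtype=float)
    a, b = step_window_ms
    isi = np.diff(t)
    ifr = 1000.0 / isi if isi.size else np.asarray([])
    if isi.size == 0:
        return FiringRates(ifr, t[1:], None, None, None)
    maximal = float(ifr[0])
    sustained = None
    if isi.size >= 3:
        mid = a + (b - a) / 2.0
        if np.all(t[-3:] >= mid):  # last three intervals end in the last half
            sustained = float(ifr[-3:].mean())
    ratio = (maximal / sustained) if sustained else None
    return FiringRates(ifr, t[1:], maximal, sustained, ratio)


def detect_sag(trace: Trace, step_window: tuple[int, int] | None = None,
               criterion: float = 1.0) -> tuple[bool, float]:
    """Depolarizing sag during a hyperpolarizing step: (present, amplitude).

    Sag amplitude is the steady-state voltage minus the early minimum;
    present when the relaxation exceeds ``criterion`` mV and the minimum
    falls in the first half of the step.
    """
    if step_window is None:
        step_window = trace.meta["step_window"]
    a, b = step_window
    pre = max(1, int(round(100.0 / trace.dt)))
    baseline = float(trace.v[a - pre:a].mean())
    seg = trace.v[a:b]
    k_min = int(np.argmin(seg))
    v_min = float(seg[k_min])
    if v_min >= baseline:
        raise DetectionError("step did not hyperpolarize the membrane")
    tail = max(1, seg.size // 10)
    v_ss = float(seg[-tail:].mean())
    amp = v_ss - v_min
    present = bool(amp > criterion and k_min < seg.size // 2)
    return present, amp


def detect_rebound(trace: Trace, step_window: tuple[int, int] | None = None,
                   window_ms: float = 500.0) -> bool:
    """Spike within ``window_ms`` after the offset of a hyperpolarizing step."""
    if step_window is None:
        step_window = trace.meta["step_window"]
    _, b = step_window
    end = min(trace.v.size, b + int(round(window_ms / trace.dt)))
    peaks = detect_spikes(trace.v, trace.dt)
    return bool(np.any((peaks >= b) & (peaks < end)))


def detect_notch(trace: Trace, step_window: tuple[int, int] | None = None,
                 criterion: float = 1.0) -> bool:
    """Transient dip of the charging trajectory below its exponential fit.

    The pre-spike voltage trajectory of a depolarizing step is fitted
    with a mono-exponential charge curve; a notch is a negative residual
    excursion larger than ``criterion`` mV before the first spike.
    """
    if step_window is None:
        step_window = trace.meta["step_window"]
    a, b = step_window
    peaks = detect_spikes(trace.v, trace.dt)
    peaks = peaks[(peaks >= a) & (peaks < b)]
    if peaks.size:
        stop = int(peaks[0] - round(2.0 / trace.dt))
    else:
        stop = b
    if stop - a < 20:
        raise DetectionError("pre-spike segment too short for a notch fit")
    seg = trace.v[a:stop]
    if seg[-1] < seg[0]:
        raise DetectionError("step did not depolarize the membrane")
    t = np.arange(seg.size) * trace.dt

    def charge(t, v0, vss, tau):
        return vss + (v0 - vss) * np.exp(-t / tau)

    p0 = (float(seg[0]), float(seg[-1]), max(trace.dt, seg.size * trace.dt / 5))
    try:
        popt, _ = curve_fit(charge, t, seg, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"charging fit did not converge: {exc}") from exc
    resid = seg - charge(t, *popt)
    return bool(resid.min() < -criterion)


def detect_usahp(traces: list, e_k: float = -90.0,
                 criterion: float = 2.0) -> bool:
    """Ultra-slow AHP flag over a family of repeated depolarizing steps.

    True when the pre-step baseline hyperpolarizes progressively from
    trace to trace by more than ``criterion`` mV overall and ends up
    below the potassium reversal potential.  Detection only — no
    mechanism (e.g. an electrogenic pump) is modelled.
    """
    if len(traces) < 3:
        raise ParameterError("need at least three repeated steps")
    baselines = []
    for tr in traces:
        a, _ = tr.meta["step_window"]
        pre = max(1, int(round(100.0 / tr.dt)))
        baselines.append(float(tr.v[max(0, a - pre):a].mean()))
    drops = np.diff(baselines)
    progressive = np.all(drops < 0.5) and (baselines[0] - baselines[-1]
                                           > criterion)
    return bool(progressive and min(baselines) < e_k)


@dataclass
class FeatureSet:
    """Extracted features of one cell's step-protocol family.

    Fields are None when their defining preconditions fail (for example
    the fast AHP is only defined when the minimal suprathreshold step
    fired a single spike).
    """

    passive: PassiveFit | None = None
    rheobase_measured: float | None = None
    rheobase_calculated: float | None = None
    ap: APMetrics | None = None
    fahp: AHPMetrics | None = None
    sahp: AHPMetrics | None = None
    max_rate: float | None = None
    sustained_rate: float | None = None
    fi_slope_max: float | None = None
    fi_slope_sustained: float | None = None
    sra_ratio: float | None = None
    sag: bool | None = None
    rebound: bool | None = None
    notch: bool | None = None
    meta: dict = field(default_factory=dict)


def extract_features(hyper_trace: Trace | None,
                     step_traces: list[Trace]) -> FeatureSet:
    """Assemble a FeatureSet from one hyperpolarizing and several
    depolarizing step traces (each carrying its step metadata).

    Depolarizing traces must share the holding potential and be ordered
    by increasing step current.  The SRA ratio is evaluated at twice the
    minimal suprathreshold current (nearest available step).
    """
    fs = FeatureSet()
    if hyper_trace is not None:
        fs.passive = fit_passive(hyper_trace)
    steps = sorted(step_traces, key=lambda tr: tr.meta["step_pa"])
    currents, counts, rate_list = [], [], []
    for tr in steps:
        a, b = tr.meta["step_window"]
        peaks = detect_spikes(tr.v, tr.dt)
        peaks = peaks[(peaks >= a) & (peaks < b)]
        currents.append(tr.meta["step_pa"])
        counts.append(peaks.size)
        rate_list.append(firing_rates(peaks * tr.dt, (a * tr.dt, b * tr.dt)))
    currents = np.asarray(currents)
    counts = np.asarray(counts)
    try:
        fs.rheobase_measured = measured_rheobase_from_steps(currents, counts)
    except NotExcitableError:
        return fs
    k_min = int(np.flatnonzero(counts >= 1)[0])
    tr_min = steps[k_min]
    a, b = tr_min.meta["step_window"]
    peaks = detect_spikes(tr_min.v, tr_min.dt)
    peaks = peaks[(peaks >= a) & (peaks < b)]
    fs.ap = ap_metrics(tr_min, int(peaks[0]))
    if fs.passive is not None:
        fs.rheobase_calculated = calculated_rheobase(
            fs.ap.v_threshold, tr_min.meta["hold_v"], fs.passive.r_in)
    fs.fahp = fahp_metrics(tr_min)
    fs.sahp = sahp_metrics(steps[-1])
    fmax = np.array([r.maximal_rate if r.maximal_rate is not None else np.nan
                     for r in rate_list])
    fsus = np.array([r.sustained_rate if r.sustained_rate is not None
                     else np.nan for r in rate_list])
    from scipy import stats as _st
    for y, attr in ((fmax, "fi_slope_max"), (fsus, "fi_slope_sustained")):
        ok = np.isfinite(y)
        if ok.sum() >= 2:
            setattr(fs, attr,
                    float(_st.linregress(currents[ok], y[ok]).slope))
    ok = np.isfinite(fmax)
    if ok.any():
        fs.max_rate = float(np.nanmax(fmax))
    ok = np.isfinite(fsus)
    if ok.any():
        fs.sustained_rate = float(fsus[ok][-1])
    target = 2.0 * currents[k_min]
    k2 = int(np.argmin(np.abs(currents - target)))
    fs.sra_ratio = rate_list[k2].sra_ratio
    fs.meta["minimal_suprathreshold_pa"] = float(currents[k_min])
    fs.meta["sra_current_pa"] = float(currents[k2])
    return fs
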