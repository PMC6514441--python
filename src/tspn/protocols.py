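"""Virtual current-clamp experiments on model cells.

Every protocol follows the same shape as the bench experiments the model
is meant to mirror: the cell is held at a target potential by a constant
bias current, allowed to settle, then probed with rectangular current
steps.  Threshold-type quantities (rheobase, firing-type boundaries) are
located by bisection on the step current; all searches are deterministic
given parameters and tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import BracketingError, NotExcitableError, ParameterError
from .features import detect_spikes, firing_rates
from .model import NeuronParams, Trace, integrate, steady_state_init, \
    total_steady_current
from .presets import with_impalement
from .stimuli import StepProtocol

#: firing-class labels
NON_FIRING = "N"
PHASIC = "P"
REPETITIVE = "R"


def run_step(params: NeuronParams, step: StepProtocol,
             dt: float = 0.1) -> Trace:
    """Simulate one holding+step protocol from the settled holding state."""
    init = steady_state_init(params, step.hold_v)
    tr = integrate(params, step.current(dt), init=init, dt=dt)
    a, b = step.step_window(dt)
    tr.meta.update(hold_v=step.hold_v, bias_pa=step.bias_pa,
                   step_pa=step.step_pa, onset_ms=step.onset,
                   step_dur_ms=step.step_dur_ms, step_window=(a, b))
    return tr


def find_bias_current(params: NeuronParams, v_target: float,
                      tol: float = 0.1, settle_ms: float = 4000.0,
                      dt: float = 0.1, bracket_pa: float = 2000.0) -> float:
    """Constant current that settles the membrane at ``v_target`` (pA).

    Solved by bisection on the current, reading out the mean voltage over
    the final 100 ms of a ``settle_ms`` integration.  The analytic
    steady-state current balance seeds the bracket.
    """
    if not -120.0 <= v_target <= 0.0:
        raise ParameterError("v_target outside physiological range")
    n = int(round(settle_ms / dt))
    tail = max(1, int(round(100.0 / dt)))

    def settled_v(i_bias: float) -> float:
        init = steady_state_init(params, v_target)
        tr = integrate(params, float(i_bias), init=init, dt=dt, n_steps=n)
        return float(tr.v[-tail:].mean())

    i0 = total_steady_current(params, v_target)
    lo, hi = i0 - 1.0, i0 + 1.0
    # expand around the analytic estimate until the target is straddled
    for _ in range(16):
        if settled_v(lo) < v_target:
            break
        lo = i0 - 2 * (i0 - lo)
        if i0 - lo > bracket_pa:
            raise BracketingError("no sign change below analytic estimate")
    else:
        raise BracketingError("bias bracket expansion failed (low side)")
    for _ in range(16):
        if settled_v(hi) > v_target:
            break
        hi = i0 + 2 * (hi - i0)
        if hi - i0 > bracket_pa:
            raise BracketingError("no sign change above analytic estimate")
    else:
        raise BracketingError("bias bracket expansion failed (high side)")

    for _ in range(60):
        mid = 0.5 * (lo + hi)
        v = settled_v(mid)
        if abs(v - v_target) <= tol:
            return mid
        if v < v_target:
            lo = mid
        else:
            hi = mid
    raise BracketingError("bias bisection did not converge")


def classify_firing(trace: Trace, step_window: tuple[int, int] | None = None,
                    spike_threshold: float = 0.0) -> str:
    """Classify a single-step response as N (non-firing), P (phasic) or R.

    Phasic means the cell fires but falls silent before the final half of
    the step; repetitive means at least two spikes with at least one in
    the final half.  A lone spike in the late step counts as phasic.
    """
    if step_window is None:
        step_window = trace.meta["step_window"]
    a, b = step_window
    peaks = detect_spikes(trace.v, trace.dt, threshold=spike_threshold)
    peaks = peaks[(peaks >= a) & (peaks < b)]
    if peaks.size == 0:
        return NON_FIRING
    mid = a + (b - a) // 2
    late = peaks[peaks >= mid]
    if peaks.size >= 2 and late.size >= 1:
        return REPETITIVE
    return PHASIC


def _spike_count(params, hold_v, bias, step_pa, step_dur, dt,
                 post_ms=0.0, count_post=False) -> int:
    step = StepProtocol(hold_v=hold_v, bias_pa=bias, settle_ms=500.0,
                        step_dur_ms=step_dur, step_pa=step_pa,
                        post_ms=max(post_ms, 100.0))
    tr = run_step(params, step, dt=dt)
    a, b = tr.meta["step_window"]
    if count_post:
        b = min(tr.v.size, b + int(round(post_ms / dt)))
    peaks = detect_spikes(tr.v, dt)
    return int(np.sum((peaks >= a) & (peaks < b)))


def _min_spiking_current(params, hold_v, step_dur, tol, i_max, dt, bias,
                         post_ms=0.0) -> float:
    count_post = post_ms > 0
    if _spike_count(params, hold_v, bias, i_max, step_dur, dt,
                    post_ms, count_post) < 1:
        raise NotExcitableError(
            f"no spike at {i_max} pA for a {step_dur:.0f} ms step")
    lo, hi = 0.0, float(i_max)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _spike_count(params, hold_v, bias, mid, step_dur, dt,
                        post_ms, count_post) >= 1:
            hi = mid
        else:
            lo = mid
    return hi


def measure_rheobase(params: NeuronParams, hold_v: float = -70.0,
                     step_dur: float = 3000.0, tol: float = 0.5,
                     i_max: float = 1000.0, dt: float = 0.1,
                     bias_pa: float | None = None) -> float:
    """Minimal long-step current eliciting at least one spike (pA).

    Located by binary search on [0, i_max] to within ``tol``; the cell is
    held at ``hold_v`` by a bias current resolved beforehand.
    """
    if step_dur < 1500.0:
        raise ParameterError("rheobase steps must last at least 1.5 s")
    bias = find_bias_current(params, hold_v) if bias_pa is None else bias_pa
    return _min_spiking_current(params, hold_v, step_dur, tol, i_max, dt, bias)


def strength_duration(params: NeuronParams, durations, hold_v: float = -70.0,
                      tol: float = 0.5, i_max: float = 5000.0,
                      dt: float = 0.1) -> np.ndarray:
    """Threshold current (pA) for each pulse duration (ms), shortest first.

    Spikes peaking within 100 ms after brief pulses still count as
    elicited by the pulse.
    """
    durations = np.asarray(durations, dtype=float)
    if np.any(durations <= 0) or np.any(np.diff(durations) < 0):
        raise ParameterError("durations must be positive and sorted")
    bias = find_bias_current(params, hold_v)
    return np.array([
        _min_spiking_current(params, hold_v, float(d), tol, i_max, dt, bias,
                             post_ms=100.0)
        for d in durations])


@dataclass
class FICurve:
    """Firing rate versus injected current, with regression slopes."""

    currents: np.ndarray        # pA
    maximal_rate: np.ndarray    # Hz (nan where < 2 spikes)
    sustained_rate: np.ndarray  # Hz (nan where undefined)
    slope_maximal: float        # Hz/pA
    slope_sustained: float      # Hz/pA


def fi_curve(params: NeuronParams, currents, hold_v: float = -70.0,
             step_dur: float = 3000.0, dt: float = 0.1,
             bias_pa: float | None = None) -> FICurve:
    """Maximal (first-interval) and sustained firing rate per step current."""
    currents = np.asarray(currents, dtype=float)
    if np.any(np.diff(currents) < 0):
        raise ParameterError("currents must be sorted")
    bias = find_bias_current(params, hold_v) if bias_pa is None else bias_pa
    fmax = np.full(currents.size, np.nan)
    fsus = np.full(currents.size, np.nan)
    for k, i_pa in enumerate(currents):
        step = StepProtocol(hold_v=hold_v, bias_pa=bias, settle_ms=500.0,
                            step_dur_ms=step_dur, step_pa=float(i_pa))
        tr = run_step(params, step, dt=dt)
        a, b = tr.meta["step_window"]
        peaks = detect_spikes(tr.v, dt)
        peaks = peaks[(peaks >= a) & (peaks < b)]
        rates = firing_rates(peaks * dt, (a * dt, b * dt))
        if rates.maximal_rate is not None:
            fmax[k] = rates.maximal_rate
        if rates.sustained_rate is not None:
            fsus[k] = rates.sustained_rate

    def _slope(y):
        ok = np.isfinite(y)
        if ok.sum() < 2:
            return float("nan")
        return float(stats.linregress(currents[ok], y[ok]).slope)

    return FICurve(currents, fmax, fsus, _slope(fmax), _slope(fsus))


@dataclass
class PhaseDiagram:
    """Firing-type boundary currents over the impalement-conductance axis.

    For each impalement conductance, ``n_to_p``/``n_to_r`` is the current
    at which the cell starts firing (phasically or repetitively) and
    ``p_to_r`` the current at which phasic turns repetitive; NaN marks a
    transition whose regions are absent.
    """

    g_imp: np.ndarray   # nS
    n_to_p: np.ndarray  # pA
    n_to_r: np.ndarray  # pA
    p_to_r: np.ndarray  # pA
    tol: float          # pA search tolerance


def _classify_at(params, hold_v, bias, i_pa, step_dur, dt) -> str:
    step = StepProtocol(hold_v=hold_v, bias_pa=bias, settle_ms=500.0,
                        step_dur_ms=step_dur, step_pa=float(i_pa))
    tr = run_step(params, step, dt=dt)
    return classify_firing(tr)


def _bisect_class(classify, lo, hi, predicate, tol):
    """Smallest current in (lo, hi] whose class satisfies ``predicate``."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(classify(mid)):
            hi = mid
        else:
            lo = mid
    return hi


def phase_boundaries(params: NeuronParams, g_imp_values,
                     i_max: float = 600.0, tol: float = 0.5,
                     hold_v: float = -70.0, step_dur: float = 3000.0,
                     dt: float = 0.1) -> PhaseDiagram:
    """Locate the N/P/R firing-type boundaries for each impalement leak."""
    g_imp_values = np.asarray(g_imp_values, dtype=float)
    n_to_p = np.full(g_imp_values.size, np.nan)
    n_to_r = np.full(g_imp_values.size, np.nan)
    p_to_r = np.full(g_imp_values.size, np.nan)
    for k, g in enumerate(g_imp_values):
        cell = with_impalement(params, float(g))
        bias = find_bias_current(cell, hold_v)

        def classify(i_pa, _cell=cell, _bias=bias):
            return _classify_at(_cell, hold_v, _bias, i_pa, step_dur, dt)

        top = classify(i_max)
        if classify(0.0) != NON_FIRING:
            raise BracketingError("cell fires with no injected current")
        if top == NON_FIRING:
            continue  # never fires within i_max
        onset = _bisect_class(classify, 0.0, i_max,
                              lambda c: c != NON_FIRING, tol)
        first = classify(onset)
        if first == REPETITIVE:
            n_to_r[k] = onset
        else:
            n_to_p[k] = onset
            if top == REPETITIVE:
                p_to_r[k] = _bisect_class(classify, onset, i_max,
                                          lambda c: c == REPETITIVE, tol)
                if p_to_r[k] - onset <= tol:
                    # phasic band narrower than the search resolution:
                    # at the stated tolerance this is a direct N->R step
                    n_to_r[k] = onset
                    n_to_p[k] = np.nan
                    p_to_r[k] = np.nan
    return PhaseDiagram(g_imp_values, n_to_p, n_to_r, p_to_r, tol)


def knockout(params: NeuronParams, names) -> NeuronParams:
    """Copy of the cell with the named maximal conductances zeroed."""
    if isinstance(names, str):
        names = [names]
    return params.with_conductances(**{n: 0.0 for n in names})


def model_input_resistance(params: NeuronParams, hold_v: float = -70.0,
                           probe_pa: float = -10.0, dt: float = 0.1,
                           step_dur: float = 3000.0,
                           bias_pa: float | None = None) -> float:
    """Input resistance (MOhm) from a small hyperpolarizing probe step."""
    bias = find_bias_current(params, hold_v) if bias_pa is None else bias_pa
    step = StepProtocol(hold_v=hold_v, bias_pa=bias, settle_ms=1000.0,
                        step_dur_ms=step_dur, step_pa=probe_pa)
    tr = run_step(params, step, dt=dt)
    a, b = tr.meta["step_window"]
    tail = int(round(200.0 / dt))
    v_base = tr.v[a - tail:a].mean()
    v_ss = tr.v[b - tail:b].mean()
    return float((v_ss - v_base) / probe_pa * 1000.0)
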