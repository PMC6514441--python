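"""Injected-current step protocols and synaptic conductance drives.

Synaptic events follow a difference-of-exponentials conductance

    g_syn(t) = s * (exp(-t/tau_d) - exp(-t/tau_r)),

with the scale factor ``s`` chosen in closed form so the kernel peaks at
exactly 1 nS before per-event amplitude scaling.  The synaptic current is
I_syn = A * g_syn * (V - E_syn).  Event trains are Poisson-distributed in
time with configurable per-event amplitudes; events are summed into a
dense conductance waveform before integration, so the integrator remains
a single fixed-step loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class StepProtocol:
    """A holding period followed by one rectangular current step.

    The bias current that holds the cell at ``hold_v`` is resolved
    separately (see :func:`tspn.protocols.find_bias_current`); this class
    only describes timing and step magnitude.
    """

    hold_v: float = -70.0      # mV, target holding potential
    bias_pa: float = 0.0       # pA, resolved holding current
    settle_ms: float = 500.0
    step_onset_ms: float | None = None  # defaults to settle_ms
    step_dur_ms: float = 3000.0
    step_pa: float = 0.0
    post_ms: float = 500.0

    def __post_init__(self):
        if self.settle_ms < 0 or self.step_dur_ms <= 0 or self.post_ms < 0:
            raise ParameterError("durations must be positive")

    @property
    def onset(self) -> float:
        return self.settle_ms if self.step_onset_ms is None else self.step_onset_ms

    def current(self, dt: float) -> np.ndarray:
        """Per-sample injected current (pA) for the whole protocol."""
        n_total = int(round((self.onset + self.step_dur_ms + self.post_ms) / dt))
        i = np.full(n_total, self.bias_pa)
        a = int(round(self.onset / dt))
        b = int(round((self.onset + self.step_dur_ms) / dt))
        i[a:b] += self.step_pa
        return i

    def step_window(self, dt: float) -> tuple[int, int]:
        """(start, stop) sample indices of the step."""
        return (int(round(self.onset / dt)),
                int(round((self.onset + self.step_dur_ms) / dt)))


def synaptic_kernel(tau_rise: float = 1.0, tau_decay: float = 15.0,
                    dt: float = 0.1, duration: float | None = None) -> np.ndarray:
    """Unit-peak difference-of-exponentials conductance waveform (nS).

    The peak occurs at t_peak = ln(tau_d/tau_r) * tau_r*tau_d/(tau_d-tau_r)
    and the normalization s = 1 / (exp(-t_peak/tau_d) - exp(-t_peak/tau_r))
    is computed in closed form.
    """
    if not tau_decay > tau_rise > 0:
        raise ParameterError("need tau_decay > tau_rise > 0")
    if duration is None:
        duration = 8.0 * tau_decay
    t_peak = math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (
        tau_decay - tau_rise)
    s = 1.0 / (math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise))
    t = np.arange(int(round(duration / dt))) * dt
    return s * (np.exp(-t / tau_decay) - np.exp(-t / tau_rise))


def synaptic_current(g_syn, amplitude: float, v, e_syn: float = 0.0):
    """I_syn = A * g_syn * (V - E_syn), pA (inward negative)."""
    g = np.asarray(g_syn, dtype=float)
    if np.any(g < 0):
        raise ParameterError("g_syn must be >= 0")
    out = amplitude * g * (np.asarray(v, dtype=float) - e_syn)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SynapticEventTrain:
    """Poisson event times with per-event conductance amplitudes."""

    event_times: tuple[float, ...]  # ms
    amplitudes: tuple[float, ...]   # nS (peak conductance per event)
    tau_rise: float = 1.0
    tau_decay: float = 15.0
    e_syn: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not self.tau_decay > self.tau_rise > 0:
            raise ParameterError("need tau_decay > tau_rise > 0")
        if len(self.event_times) != len(self.amplitudes):
            raise ParameterError("event_times and amplitudes must pair up")
        if any(a < 0 for a in self.amplitudes):
            raise ParameterError("amplitudes must be >= 0")


def poisson_train(rate_hz: float, duration_ms: float, seed: int,
                  amp_median: float = 1.2, amp_sigma: float = 1.0,
                  tau_rise: float = 1.0, tau_decay: float = 15.0,
                  e_syn: float = 0.0) -> SynapticEventTrain:
    """Sample a Poisson event train with log-normal event amplitudes.

    ``amp_median`` is the median peak conductance (nS) and ``amp_sigma``
    the log-normal shape parameter; the heavy right tail mimics the wide
    amplitude range of spontaneous synaptic events, in which occasional
    large events ride on a background of small ones.
    """
    if rate_hz < 0 or duration_ms <= 0:
        raise ParameterError("need rate >= 0 and duration > 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    times = np.sort(rng.uniform(0.0, duration_ms, size=n))
    amps = amp_median * np.exp(amp_sigma * rng.standard_normal(n))
    return SynapticEventTrain(tuple(times), tuple(amps), tau_rise=tau_rise,
                              tau_decay=tau_decay, e_syn=e_syn, seed=seed)


def generate_synaptic_conductance(train: SynapticEventTrain, dt: float,
                                  duration: float) -> np.ndarray:
    """Dense conductance waveform (nS): superposed amplitude-scaled kernels."""
    n = int(round(duration / dt))
    g = np.zeros(n)
    kernel = synaptic_kernel(train.tau_rise, train.tau_decay, dt=dt)
    for t0, amp in zip(train.event_times, train.amplitudes):
        i0 = int(round(t0 / dt))
        if i0 >= n:
            continue
        seg = min(kernel.size, n - i0)
        g[i0:i0 + seg] += amp * kernel[:seg]
    return g
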