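"""Single-compartment conductance-based membrane model of a thoracic
sympathetic postganglionic neuron (tSPN).

The cell is modelled as one isopotential compartment,

    C_m dV/dt = -sum_i I_i - I_syn + I_inj ,

where each membrane current follows a Hodgkin-Huxley description

    I_i = G_i * m^p * h^q * (V - E_i) ,

with gating variables relaxing first-order towards voltage-dependent
steady states,

    dx/dt = (x_inf(V) - x) / tau_x(V) .

Intracellular calcium, which drives the calcium-activated potassium
current, follows first-order removal kinetics fed by the persistent
calcium current:

    d[Ca]/dt = lambda * (-alpha * I_CaL - k_CaS * [Ca]) .

Injected current uses the electrophysiology convention: positive
injected current is depolarizing.  Membrane currents are positive
outward.  Units throughout: mV, ms, nS, pA, pF, uM (note nS*mV = pA and
pA/pF = mV/ms, so no unit conversion factors appear in the equations).

Integration uses the exponential-Euler scheme with a fixed time step
(default 0.1 ms): gating variables are advanced by the exact exponential
update for a frozen voltage, and the voltage itself decays exponentially
towards the instantaneous conductance-weighted reversal potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Mapping

import numpy as np

from .errors import DomainError, IntegrationDivergedError, ParameterError
from ._engine import run_steps

# CODATA constants
GAS_CONSTANT = 8.31446261815324  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: Default temperature for equilibrium-potential calculations.  Recordings
#: that motivated the standard parameter set were made at room temperature.
DEFAULT_TEMPERATURE_K = 295.0


def nernst(valence: int, conc_in: float, conc_out: float,
           temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Nernst equilibrium potential in mV.

    Parameters
    ----------
    valence : signed ionic charge (e.g. +1 for K+, -1 for Cl-).
    conc_in, conc_out : intracellular / extracellular concentration, mM.
    temperature : absolute temperature, K.
    """
    if valence == 0:
        raise DomainError("valence must be non-zero")
    if conc_in <= 0 or conc_out <= 0:
        raise DomainError("concentrations must be strictly positive")
    return (1000.0 * GAS_CONSTANT * temperature / (valence * FARADAY)
            * math.log(conc_out / conc_in))


def ghk_reversal(perm: Mapping[str, float],
                 conc_in: Mapping[str, float],
                 conc_out: Mapping[str, float],
                 temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Goldman-Hodgkin-Katz voltage for the three major ionic species.

    ``perm`` maps ion name ("Na", "K", "Cl") to relative permeability.
    Chloride, being an anion, has its inside/outside concentrations
    swapped relative to the cations.  Returns mV.
    """
    ions = {"Na", "K", "Cl"}
    if set(perm) - ions or not ions <= (set(conc_in) & set(conc_out)):
        raise DomainError("ions must be Na, K and Cl")
    p = {ion: float(perm.get(ion, 0.0)) for ion in ions}
    if any(v < 0 for v in p.values()) or all(v == 0 for v in p.values()):
        raise DomainError("permeabilities must be >= 0 and not all zero")
    num = (p["Na"] * conc_out["Na"] + p["K"] * conc_out["K"]
           + p["Cl"] * conc_in["Cl"])
    den = (p["Na"] * conc_in["Na"] + p["K"] * conc_in["K"]
           + p["Cl"] * conc_out["Cl"])
    if num <= 0 or den <= 0:
        raise DomainError("GHK numerator/denominator must be positive")
    return 1000.0 * GAS_CONSTANT * temperature / FARADAY * math.log(num / den)


@dataclass(frozen=True)
class GatingSpec:
    """Steady state and relaxation time of one gating variable.

    Voltage-dependent gates use a Boltzmann steady state

        x_inf(V) = 1 / (1 + exp((V - v_half) / slope))

    (``slope`` < 0 for a variable that opens with depolarization) and a
    generalized bell-shaped time constant

        tau_x(V) = tau_min + tau_amp / (exp((V-tau_v1)/tau_k1)
                                        + exp(-(V-tau_v2)/tau_k2)) ,

    which degenerates to a constant when ``tau_amp`` is zero.  A
    calcium-dependent gate (``kind="calcium"``) instead follows the
    instantaneous Hill activation  ca^n / (ca^n + ca_half^n).
    """

    v_half: float = 0.0
    slope: float = -1.0
    exponent: int = 1
    tau_min: float = 1.0
    tau_amp: float = 0.0
    tau_v1: float = 0.0
    tau_k1: float = 10.0
    tau_v2: float = 0.0
    tau_k2: float = 10.0
    kind: str = "voltage"
    ca_half: float = 0.5  # uM, calcium gates only
    hill: int = 2         # calcium gates only

    def __post_init__(self):
        if self.kind not in ("voltage", "calcium"):
            raise ParameterError(f"unknown gate kind {self.kind!r}")
        if self.exponent < 0:
            raise ParameterError("gate exponent must be non-negative")
        if self.tau_min <= 0 or self.tau_amp < 0:
            raise ParameterError("time constants must be positive")
        if self.kind == "calcium" and self.ca_half <= 0:
            raise ParameterError("ca_half must be positive")

    def steady_state(self, v: float, ca: float = 0.0) -> float:
        if self.kind == "calcium":
            if ca <= 0.0:
                return 0.0
            r = (ca / self.ca_half) ** self.hill
            return r / (1.0 + r)
        return 1.0 / (1.0 + np.exp((v - self.v_half) / self.slope))

    def time_constant(self, v: float) -> float:
        if self.tau_amp == 0.0:
            return self.tau_min
        return self.tau_min + self.tau_amp / (
            np.exp((v - self.tau_v1) / self.tau_k1)
            + np.exp(-(v - self.tau_v2) / self.tau_k2))


@dataclass(frozen=True)
class ChannelSpec:
    """One membrane conductance: maximal conductance, reversal, gating."""

    name: str
    g_max: float  # nS
    e_rev: float  # mV
    activation: GatingSpec | None = None
    inactivation: GatingSpec | None = None
    calcium_dependent: bool = False

    def __post_init__(self):
        if self.g_max < 0:
            raise ParameterError(f"{self.name}: g_max must be >= 0")
        if self.calcium_dependent:
            if self.activation is None or self.activation.kind != "calcium":
                raise ParameterError(
                    f"{self.name}: calcium-dependent channel needs a "
                    "calcium-kind activation gate")


@dataclass(frozen=True)
class CalciumParams:
    """Somatic calcium-handling constants.

    lambda_free : dimensionless ratio of free to bound calcium.
    alpha_conv  : uM ms^-1 pA^-1 conversion from calcium current to
                  concentration change.
    k_removal   : ms^-1 somatic removal rate.
    """

    lambda_free: float = 0.01
    alpha_conv: float = 0.002
    k_removal: float = 0.024

    def __post_init__(self):
        if min(self.lambda_free, self.alpha_conv, self.k_removal) <= 0:
            raise ParameterError("calcium parameters must be strictly positive")


@dataclass(frozen=True)
class NeuronParams:
    """Full parameterization of one model cell."""

    c_m: float = 100.0  # pF
    channels: tuple[ChannelSpec, ...] = ()
    calcium: CalciumParams = field(default_factory=CalciumParams)

    def __post_init__(self):
        if self.c_m <= 0:
            raise ParameterError("c_m must be positive")
        names = [ch.name for ch in self.channels]
        if len(names) != len(set(names)):
            raise ParameterError("channel names must be unique")

    def channel(self, name: str) -> ChannelSpec:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise ParameterError(f"no channel named {name!r}")

    def channel_names(self) -> tuple[str, ...]:
        return tuple(ch.name for ch in self.channels)

    def with_conductances(self, **g_max: float) -> "NeuronParams":
        """Copy of the cell with the named maximal conductances replaced."""
        known = set(self.channel_names())
        unknown = set(g_max) - known
        if unknown:
            raise ParameterError(f"unknown channels: {sorted(unknown)}")
        new = tuple(replace(ch, g_max=float(g_max[ch.name]))
                    if ch.name in g_max else ch for ch in self.channels)
        return replace(self, channels=new)


@dataclass
class NeuronState:
    """Instantaneous model state."""

    v: float  # mV
    gates: dict[str, tuple[float, float]]  # channel -> (m, h); 1.0 if absent
    ca: float  # uM
    t: float = 0.0  # ms


@dataclass
class Trace:
    """Uniformly sampled voltage/current time series with metadata."""

    dt: float  # ms
    v: np.ndarray  # mV
    i_inj: np.ndarray  # pA
    g_syn: np.ndarray | None = None  # nS
    ca: np.ndarray | None = None  # uM
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        self.i_inj = np.asarray(self.i_inj, dtype=float)
        if self.dt <= 0:
            raise ParameterError("dt must be positive")
        if self.v.shape != self.i_inj.shape:
            raise ParameterError("v and i_inj must have equal length")
        if self.g_syn is not None:
            self.g_syn = np.asarray(self.g_syn, dtype=float)

    @property
    def t(self) -> np.ndarray:
        """Sample times in ms."""
        return np.arange(self.v.size) * self.dt

    @property
    def duration(self) -> float:
        return self.v.size * self.dt


# ---------------------------------------------------------------------------
# currents and derivatives (reference implementations, used directly by the
# protocol layer for steady-state reasoning; the integrator has its own
# compiled inner loop that these definitions must agree with)
# ---------------------------------------------------------------------------

def _gate_product(ch: ChannelSpec, m: float, h: float) -> float:
    g = ch.g_max
    if ch.activation is not None:
        g *= m ** ch.activation.exponent
    if ch.inactivation is not None:
        g *= h ** ch.inactivation.exponent
    return g


def channel_current(ch: ChannelSpec, state: NeuronState) -> float:
    """Current through one channel at the given state, pA (outward positive)."""
    m, h = state.gates.get(ch.name, (1.0, 1.0))
    return _gate_product(ch, m, h) * (state.v - ch.e_rev)


def total_steady_current(params: NeuronParams, v: float) -> float:
    """Sum of all channel currents with every gate at steady state, pA.

    The calcium concentration is taken at its own fixed point for this
    voltage, so this is the exact current a settled cell passes at ``v``.
    """
    st = steady_state_init(params, v)
    return sum(channel_current(ch, st) for ch in params.channels)


def membrane_derivative(params: NeuronParams, state: NeuronState,
                        i_inj: float = 0.0, g_syn: float = 0.0,
                        e_syn: float = 0.0) -> tuple[float, float]:
    """Instantaneous (dV/dt in mV/ms, dCa/dt in uM/ms)."""
    i_total = sum(channel_current(ch, state) for ch in params.channels)
    i_syn = g_syn * (state.v - e_syn)
    dv = (-i_total - i_syn + i_inj) / params.c_m
    i_cal = 0.0
    for ch in params.channels:
        if ch.name == "CaL":
            i_cal = channel_current(ch, state)
    cap = params.calcium
    dca = cap.lambda_free * (-cap.alpha_conv * i_cal
                             - cap.k_removal * state.ca)
    return dv, dca


def steady_state_init(params: NeuronParams, v0: float) -> NeuronState:
    """State with every gate at x_inf(v0) and calcium at its fixed point."""
    gates: dict[str, tuple[float, float]] = {}
    i_cal = 0.0
    for ch in params.channels:
        if ch.calcium_dependent:
            continue  # needs ca, filled below
        m = (ch.activation.steady_state(v0)
             if ch.activation is not None else 1.0)
        h = (ch.inactivation.steady_state(v0)
             if ch.inactivation is not None else 1.0)
        gates[ch.name] = (m, h)
        if ch.name == "CaL":
            i_cal = _gate_product(ch, m, h) * (v0 - ch.e_rev)
    cap = params.calcium
    ca = max(0.0, -cap.alpha_conv * i_cal / cap.k_removal)
    for ch in params.channels:
        if ch.calcium_dependent:
            gates[ch.name] = (ch.activation.steady_state(v0, ca), 1.0)
    return NeuronState(v=v0, gates=gates, ca=ca, t=0.0)


# ---------------------------------------------------------------------------
# packing for the compiled inner loop
# ---------------------------------------------------------------------------

_GATE_COLS = 11  # kind, v_half, slope, exponent, tau_min, tau_amp,
                 # tau_v1, tau_k1, tau_v2, tau_k2, ca_half(+hill packed)


def _pack_gate(g: GatingSpec | None) -> np.ndarray:
    row = np.zeros(12)
    if g is None:
        row[0] = 0.0  # absent
        return row
    row[0] = 2.0 if g.kind == "calcium" else 1.0
    row[1:10] = (g.v_half, g.slope, g.exponent, g.tau_min, g.tau_amp,
                 g.tau_v1, g.tau_k1, g.tau_v2, g.tau_k2)
    row[10] = g.ca_half
    row[11] = g.hill
    return row


@lru_cache(maxsize=256)
def _pack_params(params: NeuronParams):
    nch = len(params.channels)
    g_max = np.array([ch.g_max for ch in params.channels])
    e_rev = np.array([ch.e_rev for ch in params.channels])
    act = np.vstack([_pack_gate(ch.activation) for ch in params.channels]) \
        if nch else np.zeros((0, 12))
    inact = np.vstack([_pack_gate(ch.inactivation) for ch in params.channels]) \
        if nch else np.zeros((0, 12))
    cal_idx = -1
    for i, ch in enumerate(params.channels):
        if ch.name == "CaL":
            cal_idx = i
    return g_max, e_rev, act, inact, cal_idx


def _state_arrays(params: NeuronParams, state: NeuronState):
    m = np.ones(len(params.channels))
    h = np.ones(len(params.channels))
    for i, ch in enumerate(params.channels):
        gm, gh = state.gates.get(ch.name, (1.0, 1.0))
        m[i], h[i] = gm, gh
    return m, h


def integrate(params: NeuronParams,
              i_inj: np.ndarray | float,
              g_syn: np.ndarray | None = None,
              init: NeuronState | None = None,
              dt: float = 0.1,
              e_syn: float = 0.0,
              n_steps: int | None = None,
              meta: dict | None = None,
              record_ca: bool = False) -> Trace:
    """Integrate the model under an injected-current / synaptic drive.

    ``i_inj`` may be a per-sample array (pA) or a scalar applied for
    ``n_steps`` steps.  ``g_syn`` is an optional per-sample synaptic
    conductance (nS, already amplitude-scaled) with reversal ``e_syn``.
    Gating variables are advanced by the exact exponential update
    x <- x_inf + (x - x_inf) exp(-dt/tau); voltage and calcium by
    exponential Euler.  Raises :class:`IntegrationDivergedError` naming
    the offending step if the state leaves the physical range.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if np.isscalar(i_inj):
        if n_steps is None:
            raise ParameterError("scalar i_inj requires n_steps")
        i_inj = np.full(int(n_steps), float(i_inj))
    i_inj = np.ascontiguousarray(i_inj, dtype=np.float64)
    n = i_inj.size
    if g_syn is None:
        g_syn_arr = np.zeros(0)
    else:
        g_syn_arr = np.ascontiguousarray(g_syn, dtype=np.float64)
        if g_syn_arr.size != n:
            raise ParameterError("g_syn length must match i_inj")
    if init is None:
        init = steady_state_init(params, -65.0)
    for name, (gm, gh) in init.gates.items():
        if not (0.0 <= gm <= 1.0 and 0.0 <= gh <= 1.0):
            raise ParameterError(f"initial gate {name} outside [0, 1]")

    g_max, e_rev, act, inact, cal_idx = _pack_params(params)
    m, h = _state_arrays(params, init)
    v_out = np.empty(n)
    ca_out = np.empty(n)
    cap = params.calcium
    status, v_end, ca_end = run_steps(
        init.v, m, h, init.ca, g_max, e_rev, act, inact,
        params.c_m, cap.lambda_free, cap.alpha_conv, cap.k_removal,
        cal_idx, i_inj, g_syn_arr, e_syn, dt, v_out, ca_out)
    if status >= 0:
        raise IntegrationDivergedError(int(status), float(status) * dt)

    gates = {ch.name: (float(m[i]), float(h[i]))
             for i, ch in enumerate(params.channels)}
    final = NeuronState(v=float(v_end), gates=gates, ca=float(ca_end),
                        t=init.t + n * dt)
    tr = Trace(dt=dt, v=v_out, i_inj=i_inj,
               g_syn=g_syn if g_syn is None else g_syn_arr,
               ca=ca_out if record_ca else None,
               meta=dict(meta or {}))
    tr.meta.setdefault("dt", dt)
    tr.meta["final_state"] = final
    return tr
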