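"""Synthetic heterogeneous cell populations and correlation statistics.

Real samples of this cell type are strikingly heterogeneous: input
resistance spans roughly an order of magnitude (hundreds of MOhm to over
2 GOhm) while capacitance varies only ~3-fold.  The generator emulates
that structure by sampling maximal conductances log-normally (positive,
right-skewed, as the published min/max spreads imply) and capacitance
from a truncated normal, around the standard-cell values.

Correlations between extracted features use Pearson's r with two-tailed
t-test p values and a Sidak-corrected significance level, computed
pairwise-complete so optional features with per-cell availability keep
their own n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .model import NeuronParams, integrate, steady_state_init
from .presets import standard_cell


@dataclass(frozen=True)
class LogNormalSpec:
    median: float
    sigma: float  # log-space SD


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling plan for a synthetic population of model cells."""

    n: int = 30
    seed: int = 0
    conductances: dict = field(default_factory=lambda: {
        "leak": LogNormalSpec(0.7, 1.0),
        "M": LogNormalSpec(30.0, 0.5),
        "KCa": LogNormalSpec(50.0, 0.5),
        "A": LogNormalSpec(50.0, 0.5),
        "Na": LogNormalSpec(300.0, 0.3),
        "Kd": LogNormalSpec(2000.0, 0.3),
        "H": LogNormalSpec(1.0, 0.5),
        "CaL": LogNormalSpec(1.2, 0.3),
    })
    c_m_mean: float = 89.0
    c_m_sd: float = 27.0
    c_m_bounds: tuple[float, float] = (45.0, 170.0)
    #: acceptable input-resistance window (MOhm), mirroring the observed
    #: spread of the recorded population; draws outside are rejected
    r_in_bounds: tuple[float, float] = (250.0, 2350.0)

    def __post_init__(self):
        if self.n < 0:
            raise ParameterError("n must be >= 0")


def _slope_r_in(params: NeuronParams, v: float = -70.0) -> float:
    """Analytic steady-state input resistance (MOhm) from the slope of the
    total steady current around ``v``."""
    from .model import total_steady_current
    g = (total_steady_current(params, v + 0.5)
         - total_steady_current(params, v - 0.5))  # nS
    return 1000.0 / g


def _viable(params: NeuronParams) -> bool:
    """Cell must integrate stably and sit quietly at a plausible rest."""
    try:
        init = steady_state_init(params, -65.0)
        tr = integrate(params, 0.0, init=init, dt=0.1, n_steps=5000)
    except Exception:
        return False
    v_end = tr.v[-500:].mean()
    return bool(np.all(np.isfinite(tr.v)) and -90.0 < v_end < -40.0
                and tr.v[-5000:].max() < -30.0)


def sample_population(spec: PopulationSpec,
                      base: NeuronParams | None = None,
                      max_draw_factor: int = 20) -> list[NeuronParams]:
    """Draw ``spec.n`` viable model cells; reproducible given the seed."""
    if base is None:
        base = standard_cell()
    rng = np.random.default_rng(spec.seed)
    cells: list[NeuronParams] = []
    attempts = 0
    cap = max(1, spec.n) * max_draw_factor
    while len(cells) < spec.n:
        if attempts >= cap:
            raise ParameterError(
                f"could not draw {spec.n} viable cells in {cap} attempts")
        attempts += 1
        g = {name: ln.median * math.exp(ln.sigma * rng.standard_normal())
             for name, ln in spec.conductances.items()}
        lo, hi = spec.c_m_bounds
        a, b = (lo - spec.c_m_mean) / spec.c_m_sd, (hi - spec.c_m_mean) / spec.c_m_sd
        c_m = float(stats.truncnorm.rvs(a, b, loc=spec.c_m_mean,
                                        scale=spec.c_m_sd, random_state=rng))
        cell = base.with_conductances(**g)
        cell = NeuronParams(c_m=c_m, channels=cell.channels,
                            calcium=cell.calcium)
        lo_r, hi_r = spec.r_in_bounds
        if not lo_r <= _slope_r_in(cell) <= hi_r:
            continue
        if _viable(cell):
            cells.append(cell)
    return cells


def sidak_alpha(alpha: float, m_comparisons: int) -> float:
    """Per-comparison significance level controlling family-wise error."""
    if not 0 < alpha < 1 or m_comparisons < 1:
        raise ParameterError("need 0 < alpha < 1 and m >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m_comparisons)


def correlate(features: pd.DataFrame, pairs: list[tuple[str, str]],
              alpha: float = 0.05,
              m_comparisons: int | None = None) -> pd.DataFrame:
    """Pearson correlations over feature pairs, pairwise-complete.

    Returns a table with r, R^2, n, two-tailed p (from
    t = r*sqrt((n-2)/(1-r^2))) and a significance flag at the
    Sidak-corrected level.  Pairs with fewer than 3 complete
    observations or zero variance get NaN statistics (undefined
    correlation) and are never flagged significant.
    """
    if m_comparisons is None:
        m_comparisons = len(pairs)
    a_corr = sidak_alpha(alpha, m_comparisons)
    rows = []
    for x, y in pairs:
        sub = features[[x, y]].dropna()
        n = len(sub)
        r = p = float("nan")
        if n >= 3 and sub[x].std() > 0 and sub[y].std() > 0:
            r, p = stats.pearsonr(sub[x], sub[y])
        sig = bool(np.isfinite(p) and p < a_corr)
        rows.append({"x": x, "y": y, "r": r, "r2": r * r, "n": n,
                     "p": p, "significant": sig})
    out = pd.DataFrame(rows)
    out.attrs["alpha_corrected"] = a_corr
    return out
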