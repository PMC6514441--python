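import numpy as np
import pytest

import tspn
from tspn import protocols
from tspn.model import Trace
from tspn.stimuli import StepProtocol


@pytest.fixture(scope="session")
def standard_cell():
    return tspn.standard_cell()


@pytest.fixture(scope="session")
def impaled_cell(standard_cell):
    return tspn.with_impalement(standard_cell, 7.0)


@pytest.fixture(scope="session")
def rc_cell(standard_cell):
    """Leak-only passive cell: 1 nS leak at -55 mV, 100 pF."""
    zeros = {name: 0.0 for name in standard_cell.channel_names()
             if name != "leak"}
    return standard_cell.with_conductances(**zeros)


@pytest.fixture(scope="session")
def standard_bias(standard_cell):
    return protocols.find_bias_current(standard_cell, -70.0)


def run_step(cell, bias, step_pa, step_dur=3000.0, hold_v=-70.0, dt=0.1):
    step = StepProtocol(hold_v=hold_v, bias_pa=bias, settle_ms=500.0,
                        step_dur_ms=step_dur, step_pa=step_pa)
    return protocols.run_step(cell, step, dt=dt)


def synthetic_trace(v, dt=0.1, step_pa=0.0, hold_v=-70.0,
                    step_window=None) -> Trace:
    v = np.asarray(v, dtype=float)
    tr = Trace(dt=dt, v=v, i_inj=np.full(v.size, step_pa))
    tr.meta.update(step_pa=step_pa, hold_v=hold_v,
                   step_window=step_window or (0, v.size))
    return tr
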