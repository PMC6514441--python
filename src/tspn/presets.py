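"""Construction of model cells from the versioned kinetics configuration.

The standard cell's conductance complement and gating kinetics live in
``data/standard_kinetics.yaml``; named presets (conductance overrides for
the reference reproductions) live in ``data/presets.yaml``.  Both are
plain data so alternative parameterizations can be swapped in without
touching any code.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .errors import ParameterError
from .model import CalciumParams, ChannelSpec, GatingSpec, NeuronParams


def _load_yaml(name: str) -> dict:
    with resources.files("tspn.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def _gate(d: dict | None) -> GatingSpec | None:
    if d is None:
        return None
    return GatingSpec(**d)


@lru_cache(maxsize=8)
def _standard_config() -> dict:
    return _load_yaml("standard_kinetics.yaml")


def standard_cell() -> NeuronParams:
    """The standard model cell (impalement leak present but set to 0 nS)."""
    cfg = _standard_config()
    channels = tuple(
        ChannelSpec(
            name=name,
            g_max=float(spec["g_max"]),
            e_rev=float(spec["e_rev"]),
            activation=_gate(spec.get("activation")),
            inactivation=_gate(spec.get("inactivation")),
            calcium_dependent=bool(spec.get("calcium_dependent", False)),
        )
        for name, spec in cfg["channels"].items()
    )
    return NeuronParams(
        c_m=float(cfg["c_m"]),
        channels=channels,
        calcium=CalciumParams(**cfg["calcium"]),
    )


def preset_names() -> tuple[str, ...]:
    return tuple(_load_yaml("presets.yaml"))


def preset(name: str) -> NeuronParams:
    """A named parameterization: standard cell + conductance overrides."""
    table = _load_yaml("presets.yaml")
    if name not in table:
        raise ParameterError(
            f"unknown preset {name!r}; available: {', '.join(sorted(table))}")
    overrides = table[name] or {}
    return standard_cell().with_conductances(**overrides)


def with_impalement(params: NeuronParams, g_imp: float) -> NeuronParams:
    """Copy of the cell with the impalement leak set to ``g_imp`` nS."""
    if g_imp < 0:
        raise ParameterError("g_imp must be >= 0")
    return params.with_conductances(imp=g_imp)
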