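"""Parameter sweeps of whole-cell moduli from virtual aspiration.

Elastic parameters (cytoskeleton spring k_s, bond density rho, membrane
persistence length p) are swept with pressure-ramp aspiration and the
Theret elastic fit; viscous parameters (KV damper k_v, membrane
viscosity gamma) with constant-pressure creep and the Theret viscous
fit.  Runs are deterministic (noise-free quasi-static instrument), so
sweep orderings reflect the model response, not sampling noise.

The standard sweep cell is 6.6 um across (642 outer-membrane vertices at
the default bond length), the smallest resolution at which the network
response is smooth under eligibility re-clustering.
"""

from __future__ import annotations

import dataclasses

from .builder import build_cell
from .cytoskeleton import TopologySpec
from .experiments import PipetteProtocol, run_aspiration
from .rheology import theret_elastic, theret_viscous

__all__ = ["modulus_sweep", "RAMP_PROTOCOL", "CREEP_PROTOCOL"]

RAMP_PROTOCOL = PipetteProtocol(
    r_p=1.3, max_pressure=150.0, n_levels=6, hold_time=15.0, dt=0.005
)
CREEP_PROTOCOL = PipetteProtocol(
    r_p=1.3, creep_pressure=100.0, creep_time=4.0, hold_time=10.0,
    drag=0.2, sample_every=1, dt=0.005,
)

_ELASTIC = {"k_s", "rho", "p"}
_VISCOUS = {"k_v", "gamma"}


def _build(parameter: str, value: float, diameter: float, seed: int):
    kw = {}
    topo = TopologySpec(seed=seed)
    if parameter == "k_s":
        kw["k_s"] = value
    elif parameter == "rho":
        topo = TopologySpec(rho=value, seed=seed)
    elif parameter == "k_v":
        kw["k_v_damp"] = value
    cell = build_cell(diameter, topology=topo, **kw)
    if parameter in ("p", "gamma"):
        for name in ("outer_params", "nucleus_params"):
            cur = getattr(cell, name)
            setattr(cell, name, dataclasses.replace(cur, **{
                "p" if parameter == "p" else "gamma": value
            }))
    return cell


def modulus_sweep(
    parameter: str,
    values,
    *,
    diameter: float = 6.6,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """(value, fitted modulus) pairs; elastic or viscous by parameter."""
    if parameter in _ELASTIC:
        mode, protocol = "ramp", RAMP_PROTOCOL
    elif parameter in _VISCOUS:
        mode, protocol = "creep", CREEP_PROTOCOL
    else:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; "
            f"choose from {sorted(_ELASTIC | _VISCOUS)}"
        )
    rows = []
    for v in values:
        cell = _build(parameter, float(v), diameter, seed)
        trace = run_aspiration(cell, protocol, mode, seed=seed)
        if mode == "ramp":
            est = theret_elastic(trace, window=None)
            rows.append((float(v), float(est.elastic_modulus)))
        else:
            est = theret_viscous(trace)
            rows.append((float(v), float(est.viscous_modulus)))
    return rows
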