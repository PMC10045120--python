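"""One-at-a-time finite-difference parameter sensitivity.

Each rate constant is perturbed up and down by a fraction delta (default
10%), the model is re-integrated to the 2 h endpoint, and the effect on each
readout (cytosolic H2O2 and the NADPH:NADP+, Trx-SH:Trx-SS and GSH:GSSG
ratios) is reported in two forms:

raw         S = (x_pert - x_base) / (k_pert - k_base), the one-sided
            finite-difference estimate of dx/dk (units of x per units of k)
normalized  S = ((x_pert - x_base) / x_base) / (+-delta), the dimensionless
            relative change per relative change, comparable across
            parameters and readouts

A negative sensitivity means the readout moves opposite to the parameter.
Perturbed runs that go numerically unstable are flagged in the report rather
than contributing numbers.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from redoxcell.kinetic_model import (
    OUTPUT_NAMES,
    ConfigurationError,
    EvaluationError,
    ReactionNetwork,
    SolverSettings,
    endpoint_outputs,
    simulate,
)

logger = logging.getLogger(__name__)

__all__ = ["run_sensitivity", "sensitivity_table"]


def _extract_outputs(
    net: ReactionNetwork, state: np.ndarray, names: Sequence[str]
) -> dict[str, float]:
    """Endpoint readouts by name: the canonical redox readouts where the
    model defines them, otherwise plain species concentrations (toy models)."""
    try:
        canonical = endpoint_outputs(net, state)
    except ConfigurationError:
        canonical = {}
    out = {}
    for name in names:
        if name in canonical:
            out[name] = canonical[name]
        else:
            out[name] = float(state[net.species_index(name)])
    return out


def _subsystem_of(net: ReactionNetwork) -> dict[str, str]:
    """Parameter -> subsystem label (from the reactions using it)."""
    out: dict[str, str] = {}
    for rx in net.reactions:
        out.setdefault(rx.rate_law.k_name, rx.subsystem)
    return out


def run_sensitivity(
    net: ReactionNetwork,
    initial_state: Mapping[str, float] | np.ndarray | None = None,
    parameters: Sequence[str] | None = None,
    outputs: Sequence[str] = OUTPUT_NAMES,
    delta: float = 0.10,
    settings: SolverSettings | None = None,
) -> pd.DataFrame:
    """Finite-difference sensitivity of the endpoint readouts.

    Returns a tidy frame with one row per (parameter, output, direction):
    columns parameter, subsystem, output, direction (+delta/-delta as signed
    float), k_base, raw_S, norm_S, stable.  ``norm_S`` is NaN where the
    baseline output is zero (the raw form is still emitted) or where the
    perturbed run was unstable.

    Only rate constants are perturbed, one at a time; initial conditions are
    left untouched.  The baseline simulation must be stable.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    settings = settings or net.solver
    params = list(parameters) if parameters is not None else sorted(net.parameters)
    for p in params:
        if p not in net.parameters:
            raise KeyError(f"unknown parameter {p!r}")

    base_traj = simulate(net, initial_state, settings)
    if not base_traj.stable:
        raise EvaluationError(f"baseline simulation unstable: {base_traj.message}")
    base_out = _extract_outputs(net, base_traj.endpoint(), outputs)

    subsystems = _subsystem_of(net)
    rows = []
    for p in params:
        k_base = net.parameters[p]
        for sign in (+1.0, -1.0):
            pert_net = net.scaled({p: 1.0 + sign * delta})
            traj = simulate(pert_net, initial_state, settings)
            stable = traj.stable
            if not stable:
                logger.warning("perturbed run unstable: %s %+g%%", p, sign * delta * 100)
                pert_out = {name: np.nan for name in outputs}
            else:
                pert_out = _extract_outputs(pert_net, traj.endpoint(), outputs)
            dk = k_base * sign * delta
            for name in outputs:
                x0, x1 = base_out[name], pert_out[name]
                raw = (x1 - x0) / dk if stable and dk != 0 else np.nan
                norm = (
                    ((x1 - x0) / x0) / (sign * delta)
                    if stable and x0 != 0
                    else np.nan
                )
                rows.append(
                    {
                        "parameter": p,
                        "subsystem": subsystems.get(p, "other"),
                        "output": name,
                        "direction": sign * delta,
                        "k_base": k_base,
                        "raw_S": raw,
                        "norm_S": norm,
                        "stable": stable,
                    }
                )
    return pd.DataFrame(rows)


def sensitivity_table(report: pd.DataFrame, output: str = "H2O2") -> pd.Series:
    """Mean |normalized sensitivity| per parameter for one readout, sorted
    descending — the bar-chart ordering of a sensitivity figure."""
    sub = report[(report["output"] == output) & report["stable"]]
    return (
        sub.groupby("parameter")["norm_S"]
        .apply(lambda s: float(np.mean(np.abs(s))))
        .sort_values(ascending=False)
    )
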