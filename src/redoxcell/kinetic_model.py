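"""Compartmental ODE model of quinone-cycling drug metabolism and H2O2 clearance.

The model couples a cytosolic antioxidant network (peroxiredoxin/thioredoxin/
thioredoxin-reductase/sulfiredoxin, glutathione peroxidase/glutathione/
glutathione reductase, catalase, free protein thiols, NADPH regeneration)
to the redox cycling of an NQO1-bioactivatable ortho-quinone drug
(beta-lapachone): two-electron reduction to the hydroquinone, one-electron
steps through the semiquinone radical, O2-driven reoxidation producing
superoxide, dismutation to H2O2, glutathione conjugation and export.

Networks are declarative: species, reactions (rate-law templates plus integer
stoichiometry) and parameters come from a YAML config, so the base antioxidant
reactions and the drug reactions are data, not code.  Units are molar, seconds
and liters throughout; permeation rate terms are divided by the respective
compartment volumes so that cross-compartment transport conserves moles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "EvaluationError",
    "CompartmentGeometry",
    "Species",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "SolverSettings",
    "TrajectoryResult",
    "RATE_TEMPLATES",
    "build_network",
    "load_network",
    "default_network",
    "evaluate_rates",
    "assemble_derivatives",
    "simulate",
    "equilibrate",
    "endpoint_outputs",
    "moiety_totals",
    "trajectory_to_frame",
    "OUTPUT_NAMES",
]

#: rate-law templates understood by the evaluator
RATE_TEMPLATES = (
    "mass_action",
    "second_order_self",
    "gradient_permeation",
    "unidirectional_permeation",
)

#: the four endpoint readouts reported for every simulation
OUTPUT_NAMES = ("H2O2", "NADPH:NADP", "TrxSH:TrxSS", "GSH:GSSG")


class ConfigurationError(ValueError):
    """Raised when a network config is internally inconsistent."""


class EvaluationError(ValueError):
    """Raised when a state vector is invalid for rate evaluation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompartmentGeometry:
    """Compartment volumes (liters) and the membrane area scale A."""

    volume_extracellular: float
    volume_cytosol: float
    membrane_area_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in ("volume_extracellular", "volume_cytosol", "membrane_area_factor"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be strictly positive")

    def volume(self, compartment: str) -> float:
        if compartment == "extracellular":
            return self.volume_extracellular
        if compartment == "cytosol":
            return self.volume_cytosol
        raise ConfigurationError(f"unknown compartment {compartment!r}")


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str
    initial: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.initial < 0:
            raise ConfigurationError(f"initial concentration of {self.name} is negative")
        if self.compartment not in ("extracellular", "cytosol"):
            raise ConfigurationError(
                f"species {self.name}: unknown compartment {self.compartment!r}"
            )


@dataclass(frozen=True)
class RateLaw:
    """One rate-law template instance.

    ``species`` holds the concentrations entering the rate expression:
    a list of species names for ``mass_action`` (empty list = zeroth order,
    repetition = higher order), a single name for ``second_order_self`` and
    ``unidirectional_permeation``, and ``(outside, inside)`` for
    ``gradient_permeation``.
    """

    template: str
    k_name: str
    species: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.template not in RATE_TEMPLATES:
            raise ConfigurationError(f"unknown rate-law template {self.template!r}")
        if self.template == "second_order_self" and len(self.species) != 1:
            raise ConfigurationError("second_order_self takes exactly one species")
        if self.template == "gradient_permeation" and len(self.species) != 2:
            raise ConfigurationError(
                "gradient_permeation takes (outside, inside) species"
            )
        if self.template == "unidirectional_permeation" and len(self.species) != 1:
            raise ConfigurationError("unidirectional_permeation takes one species")


@dataclass(frozen=True)
class Reaction:
    name: str
    rate_law: RateLaw
    stoichiometry: Mapping[str, int]
    subsystem: str = "other"


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-integrator settings; defaults are 2 h, max step 1 s, abstol 1e-8."""

    t_end: float = 7200.0
    max_step: float | None = 1.0
    atol: float = 1e-8
    rtol: float = 1e-6
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if not self.t_end > 0:
            raise ConfigurationError("t_end must be positive")
        if self.max_step is not None and not self.max_step > 0:
            raise ConfigurationError("max_step must be positive or None")
        if not (self.atol > 0 and self.rtol > 0):
            raise ConfigurationError("tolerances must be positive")


@dataclass
class TrajectoryResult:
    """Time-resolved concentrations plus a stability verdict.

    ``status`` is "stable" when the integrator succeeded, produced finite
    values and no concentration fell below -abstol at any accepted step;
    otherwise "unstable" with the reason in ``message``.
    """

    time: np.ndarray
    concentrations: np.ndarray  # (n_time, n_species)
    species_names: tuple[str, ...]
    status: str
    message: str = ""

    @property
    def stable(self) -> bool:
        return self.status == "stable"

    def endpoint(self) -> np.ndarray:
        return self.concentrations[-1]

    def series(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.species_names.index(name)]


@dataclass(frozen=True)
class ReactionNetwork:
    """Validated reaction network: species, reactions, geometry, parameters."""

    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    geometry: CompartmentGeometry
    parameters: Mapping[str, float]
    solver: SolverSettings = field(default_factory=SolverSettings)
    moieties: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown species {name!r}") from None

    def initial_state(self, overrides: Mapping[str, float] | None = None) -> np.ndarray:
        y0 = np.array([s.initial for s in self.species], dtype=float)
        for name, value in (overrides or {}).items():
            if value < 0:
                raise ConfigurationError(f"initial override for {name} is negative")
            y0[self.species_index(name)] = value
        return y0

    # -- derived networks ---------------------------------------------------

    def scaled(
        self,
        k_multipliers: Mapping[str, float] | None = None,
        initial_overrides: Mapping[str, float] | None = None,
    ) -> "ReactionNetwork":
        """Return a copy with rate constants multiplied and/or initials replaced."""
        params = dict(self.parameters)
        for k, mult in (k_multipliers or {}).items():
            if k not in params:
                raise ConfigurationError(f"unknown parameter {k!r}")
            if mult < 0:
                raise ConfigurationError(f"multiplier for {k} is negative")
            params[k] = params[k] * mult
        species = list(self.species)
        for name, value in (initial_overrides or {}).items():
            i = self.species_index(name)
            species[i] = replace(species[i], initial=float(value))
        return replace(self, parameters=params, species=tuple(species))

    def with_solver(self, **kwargs) -> "ReactionNetwork":
        return replace(self, solver=replace(self.solver, **kwargs))


# ---------------------------------------------------------------------------
# construction and validation
# ---------------------------------------------------------------------------


def _parse_rate_law(entry: Mapping) -> RateLaw:
    template = entry["template"]
    raw = entry.get("species", [])
    if template == "gradient_permeation":
        if isinstance(raw, Mapping):
            names = (raw["outside"], raw["inside"])
        else:
            names = tuple(raw)
    elif isinstance(raw, str):
        names = (raw,)
    else:
        names = tuple(raw)
    return RateLaw(template=template, k_name=entry["k"], species=names)


def build_network(config: Mapping, geometry: CompartmentGeometry | None = None) -> ReactionNetwork:
    """Build and validate a :class:`ReactionNetwork` from a config mapping.

    The config supplies ``compartments``, ``species``, ``parameters``,
    ``reactions`` and optionally ``solver`` and ``moieties`` blocks.  Every
    rate constant referenced by a reaction must be present in ``parameters``
    and every species referenced anywhere must be declared — violations raise
    :class:`ConfigurationError` naming the offender.
    """
    if geometry is None:
        comp = config.get("compartments")
        if not comp:
            raise ConfigurationError("config must define compartments")
        geometry = CompartmentGeometry(
            volume_extracellular=float(comp["extracellular"]),
            volume_cytosol=float(comp["cytosol"]),
            membrane_area_factor=float(config.get("membrane_area_factor", 1.0)),
        )

    species = tuple(
        Species(
            name=s["name"],
            compartment=s["compartment"],
            initial=float(s.get("initial", 0.0)),
            clamped=bool(s.get("clamped", False)),
        )
        for s in config["species"]
    )
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate species: {dup}")
    known = set(names)

    parameters = {str(k): float(v) for k, v in config.get("parameters", {}).items()}
    for k, v in parameters.items():
        if not math.isfinite(v):
            raise ConfigurationError(f"parameter {k} is not finite")

    reactions = []
    for entry in config["reactions"]:
        law = _parse_rate_law(entry)
        if law.k_name not in parameters:
            raise ConfigurationError(
                f"reaction {entry['name']!r}: missing parameter {law.k_name!r}"
            )
        for sp in law.species:
            if sp not in known:
                raise ConfigurationError(
                    f"reaction {entry['name']!r}: unknown species {sp!r} in rate law"
                )
        stoich = {str(k): int(v) for k, v in entry.get("stoichiometry", {}).items()}
        for sp in stoich:
            if sp not in known:
                raise ConfigurationError(
                    f"reaction {entry['name']!r}: unknown species {sp!r} in stoichiometry"
                )
        if law.template == "mass_action":
            comps = {next(s for s in species if s.name == n).compartment for n in law.species}
            comps |= {next(s for s in species if s.name == n).compartment for n in stoich}
            if len(comps) > 1:
                raise ConfigurationError(
                    f"reaction {entry['name']!r}: mass-action species span compartments; "
                    "use a permeation template for transport"
                )
        reactions.append(
            Reaction(
                name=entry["name"],
                rate_law=law,
                stoichiometry=stoich,
                subsystem=entry.get("subsystem", "other"),
            )
        )

    solver_cfg = config.get("solver", {})
    solver = SolverSettings(
        t_end=float(solver_cfg.get("t_end", 7200.0)),
        max_step=(None if solver_cfg.get("max_step", 1.0) in (None, "none")
                  else float(solver_cfg.get("max_step", 1.0))),
        atol=float(solver_cfg.get("atol", 1e-8)),
        rtol=float(solver_cfg.get("rtol", 1e-6)),
        method=str(solver_cfg.get("method", "LSODA")),
    )

    moieties = {
        str(name): {str(sp): float(w) for sp, w in members.items()}
        for name, members in config.get("moieties", {}).items()
    }
    for name, members in moieties.items():
        for sp in members:
            if sp not in known:
                raise ConfigurationError(f"moiety {name!r}: unknown species {sp!r}")

    return ReactionNetwork(
        species=species,
        reactions=tuple(reactions),
        geometry=geometry,
        parameters=parameters,
        solver=solver,
        moieties=moieties,
    )


def load_network(path) -> ReactionNetwork:
    """Load a network from a YAML config file."""
    with open(path) as fh:
        return build_network(yaml.safe_load(fh))


def default_network() -> ReactionNetwork:
    """The packaged default model: base antioxidant network plus the nine
    drug reactions (k29–k36)."""
    text = resources.files("redoxcell.data").joinpath("default_model.yaml").read_text()
    return build_network(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# rate evaluation and derivative assembly
# ---------------------------------------------------------------------------


class _Compiled:
    """Precomputed index arrays for fast rate/derivative evaluation."""

    def __init__(self, net: ReactionNetwork):
        n_sp = len(net.species)
        n_rx = len(net.reactions)
        geo = net.geometry
        A = geo.membrane_area_factor
        comp_volume = np.array([geo.volume(s.compartment) for s in net.species])

        self.k = np.array([net.parameters[r.rate_law.k_name] for r in net.reactions])
        # factor pairs (reaction, species) for mass-action products; a
        # second_order_self law contributes its species twice
        pairs_r, pairs_s = [], []
        self.grad = []  # (reaction, outside idx, inside idx)
        self.uni = []   # (reaction, source idx)
        self.area = A
        for r_i, rx in enumerate(net.reactions):
            law = rx.rate_law
            idx = [net.species_index(n) for n in law.species]
            if law.template == "mass_action":
                for s_i in idx:
                    pairs_r.append(r_i)
                    pairs_s.append(s_i)
            elif law.template == "second_order_self":
                pairs_r.extend([r_i, r_i])
                pairs_s.extend([idx[0], idx[0]])
            elif law.template == "gradient_permeation":
                self.grad.append((r_i, idx[0], idx[1]))
            else:
                self.uni.append((r_i, idx[0]))
        self.pairs_r = np.array(pairs_r, dtype=np.intp)
        self.pairs_s = np.array(pairs_s, dtype=np.intp)

        perm_kinds = ("gradient_permeation", "unidirectional_permeation")
        # stoichiometry matrix mapping fluxes to concentration derivatives;
        # permeation rates are molar fluxes (mol/s) and are divided by each
        # receiving species' compartment volume
        M = np.zeros((n_sp, n_rx))
        for r_i, rx in enumerate(net.reactions):
            is_perm = rx.rate_law.template in perm_kinds
            for sp, coeff in rx.stoichiometry.items():
                s_i = net.species_index(sp)
                M[s_i, r_i] = coeff / comp_volume[s_i] if is_perm else coeff
        clamped = np.array([s.clamped for s in net.species])
        M[clamped, :] = 0.0
        self.M = M
        self.comp_volume = comp_volume

        # reporting volumes: permeation rate terms are divided by the
        # respective compartment volume (destination for gradient terms,
        # source for unidirectional export)
        self.report_volume = np.ones(n_rx)
        for r_i, _out, inn in self.grad:
            self.report_volume[r_i] = comp_volume[inn]
        for r_i, src in self.uni:
            self.report_volume[r_i] = comp_volume[src]

    def fluxes(self, y: np.ndarray, clip: bool = False) -> np.ndarray:
        """Per-reaction rates: M/s for same-compartment reactions, mol/s for
        permeation (before the per-compartment volume division).

        ``clip=True`` evaluates mass-action products at max(y, 0): stiff
        solvers probe slightly negative states, and unguarded products of
        negative concentrations can turn a benign overshoot into runaway
        positive feedback.  Gradient terms stay signed.
        """
        if clip:
            y = np.maximum(y, 0.0)
        rates = self.k.copy()
        if self.pairs_r.size:
            np.multiply.at(rates, self.pairs_r, y[self.pairs_s])
        for r_i, out, inn in self.grad:
            rates[r_i] = self.k[r_i] * self.area * (y[out] - y[inn])
        for r_i, src in self.uni:
            rates[r_i] = self.k[r_i] * self.area * y[src]
        return rates


def _compiled(net: ReactionNetwork) -> _Compiled:
    # frozen dataclass: cache via object.__setattr__
    cache = getattr(net, "_compiled_cache", None)
    if cache is None:
        cache = _Compiled(net)
        object.__setattr__(net, "_compiled_cache", cache)
    return cache


def evaluate_rates(
    net: ReactionNetwork,
    state: Mapping[str, float] | Sequence[float] | np.ndarray,
    negative_tolerance: float = 1e-8,
) -> pd.Series:
    """Evaluate every reaction's rate at a state.

    Mass-action rates are returned in M/s; permeation rates are returned
    already divided by the respective compartment volume (destination for
    gradient terms, source for unidirectional terms).  Concentrations below
    ``-negative_tolerance`` raise :class:`EvaluationError`.
    """
    if isinstance(state, Mapping):
        missing = set(net.species_names) - set(state)
        if missing:
            raise EvaluationError(f"state missing species: {sorted(missing)}")
        y = np.array([state[n] for n in net.species_names], dtype=float)
    else:
        y = np.asarray(state, dtype=float)
        if y.shape != (len(net.species),):
            raise EvaluationError(
                f"state has shape {y.shape}, expected ({len(net.species)},)"
            )
    if np.min(y) < -negative_tolerance:
        bad = net.species_names[int(np.argmin(y))]
        raise EvaluationError(f"negative concentration for {bad}: {y.min():.3g}")
    c = _compiled(net)
    rates = c.fluxes(y) / c.report_volume
    return pd.Series(rates, index=[r.name for r in net.reactions], name="rate")


def assemble_derivatives(net: ReactionNetwork) -> Callable[[float, np.ndarray], np.ndarray]:
    """Return the ODE right-hand side f(t, y) = S · v(y).

    Clamped species get a zero derivative.  The function does not validate
    the state (stiff solvers probe slightly negative values); validation is
    the job of :func:`evaluate_rates` and the post-hoc stability check.
    """
    c = _compiled(net)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return c.M @ c.fluxes(y, clip=True)

    return rhs


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate(
    net: ReactionNetwork,
    initial_state: Mapping[str, float] | np.ndarray | None = None,
    settings: SolverSettings | None = None,
    t_eval: np.ndarray | None = None,
) -> TrajectoryResult:
    """Integrate the network to ``settings.t_end`` with a stiff solver.

    ``initial_state`` may be a full state vector, a mapping of per-species
    overrides on top of the config initials, or None for the config initials.
    An integrator failure, a non-finite value, or a concentration below
    -abstol at an accepted step yields ``status="unstable"`` (a flagged
    return, never an exception).
    """
    settings = settings or net.solver
    if isinstance(initial_state, Mapping) or initial_state is None:
        y0 = net.initial_state(initial_state)
    else:
        y0 = np.asarray(initial_state, dtype=float)
    if y0.min() < 0:
        raise EvaluationError("initial state has negative concentrations")

    rhs = assemble_derivatives(net)
    kwargs = dict(
        method=settings.method,
        atol=settings.atol,
        rtol=settings.rtol,
        t_eval=t_eval,
    )
    if settings.max_step is not None:
        kwargs["max_step"] = settings.max_step
    try:
        sol = solve_ivp(rhs, (0.0, settings.t_end), y0, **kwargs)
    except Exception as exc:  # numerical blow-up inside the solver
        return TrajectoryResult(
            time=np.array([0.0]),
            concentrations=y0[None, :],
            species_names=net.species_names,
            status="unstable",
            message=f"solver raised: {exc}",
        )

    conc = sol.y.T
    status, message = "stable", ""
    if not sol.success:
        status, message = "unstable", f"solver failed: {sol.message}"
    elif not np.all(np.isfinite(conc)):
        status, message = "unstable", "non-finite concentrations"
    elif conc.min() < -settings.atol:
        i = np.unravel_index(np.argmin(conc), conc.shape)[1]
        status = "unstable"
        message = (
            f"concentration of {net.species_names[int(i)]} fell below -abstol "
            f"({conc.min():.3g})"
        )
    return TrajectoryResult(
        time=sol.t,
        concentrations=conc,
        species_names=net.species_names,
        status=status,
        message=message,
    )


def equilibrate(
    net: ReactionNetwork,
    t_max: float = 1e6,
    settings: SolverSettings | None = None,
) -> np.ndarray:
    """Integrate the drug-free network to its resting steady state.

    Returns the state vector after ``t_max`` seconds (default ~11.5 days,
    long against the slowest relaxation mode, sulfiredoxin-mediated
    peroxiredoxin repair).  Raises if the relaxation run is unstable.
    """
    settings = settings or SolverSettings(
        t_end=t_max, max_step=None, atol=net.solver.atol, rtol=net.solver.rtol,
        method=net.solver.method,
    )
    settings = replace(settings, t_end=t_max, max_step=None)
    traj = simulate(net, settings=settings)
    if not traj.stable:
        raise EvaluationError(f"equilibration unstable: {traj.message}")
    return np.maximum(traj.endpoint(), 0.0)


# ---------------------------------------------------------------------------
# readouts and bookkeeping
# ---------------------------------------------------------------------------


def endpoint_outputs(net: ReactionNetwork, state: np.ndarray) -> dict[str, float]:
    """The four endpoint readouts: cytosolic [H2O2] and the NADPH:NADP+,
    Trx-SH:Trx-SS and GSH:GSSG redox ratios."""

    def conc(name: str) -> float:
        return float(state[net.species_index(name)])

    def ratio(a: str, b: str) -> float:
        denom = conc(b)
        return float("inf") if denom == 0 else conc(a) / denom

    return {
        "H2O2": conc("H2O2"),
        "NADPH:NADP": ratio("NADPH", "NADP"),
        "TrxSH:TrxSS": ratio("TrxSH", "TrxSS"),
        "GSH:GSSG": ratio("GSH", "GSSG"),
    }


def moiety_totals(net: ReactionNetwork, state: np.ndarray) -> dict[str, float]:
    """Volume-weighted totals (moles) of the conserved moieties declared in
    the config: NADP(H), thioredoxin, peroxiredoxin, glutathione and the
    drug moiety across all redox forms and both compartments."""
    geo = net.geometry
    out = {}
    for name, members in net.moieties.items():
        total = 0.0
        for sp, weight in members.items():
            i = net.species_index(sp)
            total += weight * geo.volume(net.species[i].compartment) * float(state[i])
        out[name] = total
    return out


def trajectory_to_frame(traj: TrajectoryResult, cell_id: str | None = None) -> pd.DataFrame:
    """Tidy (time, species, concentration[, cell_id]) long-format table."""
    frames = pd.DataFrame(traj.concentrations, columns=list(traj.species_names))
    frames.insert(0, "time", traj.time)
    long = frames.melt(id_vars="time", var_name="species", value_name="concentration")
    if cell_id is not None:
        long["cell_id"] = cell_id
    return long
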