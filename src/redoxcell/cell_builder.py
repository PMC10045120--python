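"""Per-cell model construction from single-cell expression profiles.

Each cell's ODE model is derived from the base network by (a) scaling a
configured set of rate constants by the cell's expression relative to the
cohort average (ratio form: an average cell gets multiplier 1) and (b)
resetting the initial abundances of a configured set of enzymes in
proportion to the cell's estimated protein level.  The default wiring:

rate-scaled      NQO1 -> k29, SOD1 -> k32, POR -> k33, GSR -> k_gsr,
                 TXNRD1 -> k_trxr, AQP3 -> aquaporin H2O2 permeation,
                 G6PD+GLUD1 (additive) -> NADPH regeneration
abundance-set    GPX1 -> GPX, CAT -> CAT, PRX1+PRX2 (additive) -> reduced
                 Prx pool, TXN -> reduced Trx, GLRX -> Grx

Gene groups joined with "+" act additively: the multiplier is the ratio of
summed levels.  Expression ratios are floored at a small epsilon so that
dropout zeros yield a near-null rather than exactly-null reaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from redoxcell.kinetic_model import ReactionNetwork
from redoxcell.protein_mapping import ProteinMapper, protein_equilibrium

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_EPSILON",
    "ExpressionProfile",
    "CellModelSpec",
    "MappingConfig",
    "load_mapping_config",
    "default_mapping_config",
    "cohort_means",
    "rate_multiplier",
    "additive_multiplier",
    "build_cell_model",
    "apply_cell_model",
]

#: floor for expression-ratio multipliers (guards against dropout zeros)
DEFAULT_EPSILON = 1e-3


@dataclass(frozen=True)
class ExpressionProfile:
    """One cell's annotated expression over the mapped genes."""

    cell_id: str
    patient_id: str
    malignant: bool
    expression: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [g for g, v in self.expression.items() if v < 0]
        if bad:
            raise ValueError(f"cell {self.cell_id}: negative expression for {bad}")

    def level(self, gene: str) -> float:
        try:
            return float(self.expression[gene])
        except KeyError:
            raise KeyError(f"cell {self.cell_id}: missing gene {gene!r}") from None


@dataclass(frozen=True)
class CellModelSpec:
    """Scaled rate constants and initial enzyme abundances for one cell."""

    cell_id: str
    k_multipliers: Mapping[str, float]
    initial_concentrations: Mapping[str, float]  # molar
    cohort_means: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.k_multipliers.values()):
            raise ValueError("rate multipliers must be nonnegative")
        if any(v < 0 for v in self.initial_concentrations.values()):
            raise ValueError("initial concentrations must be nonnegative")


@dataclass(frozen=True)
class MappingConfig:
    """Gene-to-parameter wiring.

    ``rate_scaled`` maps a gene group (genes joined by "+") to the parameter
    names it scales; ``abundance_set`` maps a gene group to the species whose
    initial abundance it sets.  ``abundance_mode`` chooses between the
    equilibrium protein model ("equilibrium") and direct proportional
    scaling of expression ("proportional") for the abundance multipliers.
    """

    rate_scaled: Mapping[str, tuple[str, ...]]
    abundance_set: Mapping[str, str]
    epsilon: float = DEFAULT_EPSILON
    abundance_mode: str = "equilibrium"

    def __post_init__(self) -> None:
        if self.abundance_mode not in ("equilibrium", "proportional"):
            raise ValueError(f"unknown abundance_mode {self.abundance_mode!r}")
        if not self.epsilon >= 0:
            raise ValueError("epsilon must be nonnegative")

    @property
    def genes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for group in list(self.rate_scaled) + list(self.abundance_set):
            for gene in group.split("+"):
                if gene not in seen:
                    seen.append(gene)
        return tuple(seen)


def _as_tuple(v) -> tuple[str, ...]:
    return (v,) if isinstance(v, str) else tuple(v)


def load_mapping_config(path_or_mapping) -> MappingConfig:
    """Load a mapping config from YAML (path) or a mapping."""
    if isinstance(path_or_mapping, Mapping):
        cfg = path_or_mapping
    else:
        with open(path_or_mapping) as fh:
            cfg = yaml.safe_load(fh)
    return MappingConfig(
        rate_scaled={g: _as_tuple(v) for g, v in cfg["rate_scaled"].items()},
        abundance_set={g: str(v) for g, v in cfg["abundance_set"].items()},
        epsilon=float(cfg.get("epsilon", DEFAULT_EPSILON)),
        abundance_mode=str(cfg.get("abundance_mode", "equilibrium")),
    )


def default_mapping_config() -> MappingConfig:
    text = resources.files("redoxcell.data").joinpath("default_mapping.yaml").read_text()
    return load_mapping_config(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# scaling primitives
# ---------------------------------------------------------------------------


def cohort_means(matrix: pd.DataFrame, genes: Sequence[str] | None = None) -> pd.Series:
    """Arithmetic per-gene mean over all retained cells (cells x genes)."""
    if matrix.shape[0] == 0:
        raise ValueError("expression matrix has no cells")
    if genes is not None:
        missing = set(genes) - set(matrix.columns)
        if missing:
            raise KeyError(f"matrix missing genes: {sorted(missing)}")
        matrix = matrix[list(genes)]
    return matrix.mean(axis=0)


def rate_multiplier(expr: float, mean_expr: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Expression ratio to the cohort average, floored at epsilon."""
    if not mean_expr > 0:
        raise ValueError("cohort mean expression must be positive")
    return max(expr / mean_expr, epsilon)


def additive_multiplier(
    expr_pair: Sequence[float],
    mean_pair: Sequence[float],
    epsilon: float = DEFAULT_EPSILON,
) -> float:
    """Ratio of summed expression for additive gene groups (G6PD+GLUD1,
    PRX1+PRX2)."""
    mean_sum = float(np.sum(mean_pair))
    if not mean_sum > 0:
        raise ValueError("cohort mean expression sum must be positive")
    return max(float(np.sum(expr_pair)) / mean_sum, epsilon)


# ---------------------------------------------------------------------------
# the builder
# ---------------------------------------------------------------------------


def _group_multiplier(
    group: str,
    profile: ExpressionProfile,
    means: Mapping[str, float],
    epsilon: float,
    weight=None,
) -> float:
    """Ratio-to-mean multiplier for a gene group, optionally weighting each
    gene's level (used for the equilibrium-protein abundance route)."""
    genes = group.split("+")
    w = weight or (lambda g, x: x)
    expr = [w(g, profile.level(g)) for g in genes]
    mean = [w(g, float(means[g])) for g in genes]
    mult = additive_multiplier(expr, mean, epsilon)
    if mult == epsilon:
        logger.info(
            "cell %s: %s multiplier floored at epsilon=%g", profile.cell_id, group, epsilon
        )
    return mult


def build_cell_model(
    profile: ExpressionProfile,
    means: Mapping[str, float],
    network: ReactionNetwork,
    mapping: MappingConfig | None = None,
    protein_mapper: ProteinMapper | None = None,
) -> CellModelSpec:
    """Derive one cell's :class:`CellModelSpec` from its expression profile.

    Rate constants get the expression ratio-to-mean as multiplier; initial
    enzyme abundances are the base network's initial concentration scaled by
    the cell's protein-level ratio (equilibrium synthesis/degradation model
    when rate constants are available, raw expression ratio otherwise).  A
    profile sitting exactly at the cohort average reproduces the base
    parameterization.
    """
    mapping = mapping or default_mapping_config()
    eps = mapping.epsilon

    for gene in mapping.genes:
        if gene not in profile.expression:
            raise KeyError(f"cell {profile.cell_id}: missing gene {gene!r}")
        if gene not in means:
            raise KeyError(f"cohort means missing gene {gene!r}")

    k_multipliers: dict[str, float] = {}
    for group, params in mapping.rate_scaled.items():
        mult = _group_multiplier(group, profile, means, eps)
        for param in params:
            if param not in network.parameters:
                raise KeyError(f"mapping targets unknown parameter {param!r}")
            k_multipliers[param] = mult

    weight = None
    if mapping.abundance_mode == "equilibrium" and protein_mapper is not None:
        def weight(gene, level):  # noqa: E306
            if gene in protein_mapper.rate_constants:
                return protein_equilibrium(
                    level * protein_mapper.rna_scale, protein_mapper.rate_constants[gene]
                )
            return level  # proportional fallback for unmapped genes

    initial: dict[str, float] = {}
    for group, species in mapping.abundance_set.items():
        mult = _group_multiplier(group, profile, means, eps, weight=weight)
        base = network.species[network.species_index(species)].initial
        initial[species] = base * mult

    return CellModelSpec(
        cell_id=profile.cell_id,
        k_multipliers=k_multipliers,
        initial_concentrations=initial,
        cohort_means={g: float(means[g]) for g in mapping.genes},
    )


def apply_cell_model(network: ReactionNetwork, spec: CellModelSpec) -> ReactionNetwork:
    """The base network specialized to one cell."""
    return network.scaled(
        k_multipliers=spec.k_multipliers,
        initial_overrides=spec.initial_concentrations,
    )
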