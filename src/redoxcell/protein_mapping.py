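"""RNA-to-protein abundance estimation.

Protein copy numbers are estimated from mRNA levels through the equilibrium
of a linear synthesis/degradation model: with translation rate ``k_sp``
(protein per mRNA per hour) and protein degradation rate ``k_dp`` (per hour),
``dP/dt = k_sp * R - k_dp * P`` has the fixed point ``P* = k_sp * R / k_dp``.
Genes without published rate constants (AQP3 in the default wiring) fall back
to a linear RNA-protein regression.  A unit bridge converts copy numbers to
molar concentrations for the ODE model.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "GeneRateConstants",
    "LinearMap",
    "ProteinMapper",
    "protein_equilibrium",
    "protein_linear",
    "copies_to_molar",
    "molar_to_copies",
    "fit_linear_map",
    "load_rate_constants",
    "load_linear_maps",
    "default_rate_constants",
    "default_linear_maps",
]

AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class GeneRateConstants:
    """Synthesis/degradation rate constants for one gene (per hour)."""

    gene: str
    k_sp: float  # translation rate, protein * mRNA^-1 * h^-1
    k_dp: float  # protein degradation rate, h^-1
    k_sr: float | None = None  # mRNA synthesis rate, h^-1 (optional)
    k_dr: float | None = None  # mRNA degradation rate, h^-1 (optional)

    def __post_init__(self) -> None:
        if not self.k_dp > 0:
            raise ValueError(f"{self.gene}: protein degradation rate must be > 0")
        if self.k_dr is not None and not self.k_dr > 0:
            raise ValueError(f"{self.gene}: mRNA degradation rate must be > 0")


@dataclass(frozen=True)
class LinearMap:
    """Linear RNA-to-protein map (protein copies per RNA unit)."""

    slope: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise ValueError("slope must be finite")


def protein_equilibrium(mrna_copies: float, constants: GeneRateConstants) -> float:
    """Equilibrium protein copies: k_sp * R / k_dp."""
    if mrna_copies < 0:
        raise ValueError("mRNA level must be nonnegative")
    return constants.k_sp * mrna_copies / constants.k_dp


def protein_linear(rna_level: float, mapping: LinearMap) -> float:
    """Linear-regression protein estimate, floored at zero."""
    if rna_level < 0:
        raise ValueError("RNA level must be nonnegative")
    return max(mapping.slope * rna_level + mapping.intercept, 0.0)


def copies_to_molar(copies: float, volume_liters: float) -> float:
    """Copies per compartment -> molar concentration."""
    if not volume_liters > 0:
        raise ValueError("volume must be positive")
    return copies / (AVOGADRO * volume_liters)


def molar_to_copies(concentration: float, volume_liters: float) -> float:
    """Inverse of :func:`copies_to_molar`."""
    if not volume_liters > 0:
        raise ValueError("volume must be positive")
    return concentration * AVOGADRO * volume_liters


def fit_linear_map(rna: np.ndarray, protein: np.ndarray) -> LinearMap:
    """Least-squares fit of protein on RNA (the AQP3-style fallback)."""
    rna = np.asarray(rna, dtype=float)
    protein = np.asarray(protein, dtype=float)
    slope, intercept = np.polyfit(rna, protein, 1)
    return LinearMap(slope=float(slope), intercept=float(intercept))


# ---------------------------------------------------------------------------
# tables and the combined mapper
# ---------------------------------------------------------------------------


def load_rate_constants(path_or_buf) -> dict[str, GeneRateConstants]:
    """Read a TSV of per-gene rate constants (gene, k_sp, k_dp[, k_sr, k_dr])."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    out = {}
    for _, row in df.iterrows():
        out[row["gene"]] = GeneRateConstants(
            gene=row["gene"],
            k_sp=float(row["k_sp"]),
            k_dp=float(row["k_dp"]),
            k_sr=float(row["k_sr"]) if pd.notna(row.get("k_sr")) else None,
            k_dr=float(row["k_dr"]) if pd.notna(row.get("k_dr")) else None,
        )
    return out


def load_linear_maps(path_or_buf) -> dict[str, LinearMap]:
    """Read a TSV of per-gene linear maps (gene, slope, intercept)."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#")
    return {
        row["gene"]: LinearMap(slope=float(row["slope"]), intercept=float(row["intercept"]))
        for _, row in df.iterrows()
    }


def default_rate_constants() -> dict[str, GeneRateConstants]:
    """Packaged synthetic stand-in rate-constant table (see file header)."""
    with resources.files("redoxcell.data").joinpath("synthetic_rate_constants.tsv").open() as fh:
        return load_rate_constants(fh)


def default_linear_maps() -> dict[str, LinearMap]:
    with resources.files("redoxcell.data").joinpath("default_linear_maps.tsv").open() as fh:
        return load_linear_maps(fh)


class ProteinMapper:
    """Maps per-gene RNA levels to protein copies and molar concentrations.

    Uses the equilibrium synthesis/degradation model where rate constants are
    available and the linear fallback otherwise; a gene with neither is an
    error.  ``rna_scale`` converts normalized single-cell expression units to
    mRNA copies (counts in scRNA-seq are relative; default scale 1).
    """

    def __init__(
        self,
        rate_constants: Mapping[str, GeneRateConstants] | None = None,
        linear_maps: Mapping[str, LinearMap] | None = None,
        rna_scale: float = 1.0,
    ):
        self.rate_constants = dict(rate_constants or {})
        self.linear_maps = dict(linear_maps or {})
        if not rna_scale > 0:
            raise ValueError("rna_scale must be positive")
        self.rna_scale = rna_scale

    def protein_copies(self, gene: str, expression: float) -> float:
        rna = expression * self.rna_scale
        if gene in self.rate_constants:
            return protein_equilibrium(rna, self.rate_constants[gene])
        if gene in self.linear_maps:
            return protein_linear(rna, self.linear_maps[gene])
        raise KeyError(f"no rate constants or linear map for gene {gene!r}")

    def protein_molar(self, gene: str, expression: float, volume_liters: float) -> float:
        return copies_to_molar(self.protein_copies(gene, expression), volume_liters)

    def profile_to_molar(
        self, expression: Mapping[str, float], volume_liters: float
    ) -> dict[str, float]:
        """Molar protein concentration for every gene in a profile."""
        return {
            gene: self.protein_molar(gene, level, volume_liters)
            for gene, level in expression.items()
        }
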