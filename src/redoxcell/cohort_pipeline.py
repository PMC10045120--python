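"""Cohort simulation and malignant vs non-malignant comparison.

Builds one ODE model per cell from its expression profile, simulates the
2 h response to an extracellular quinone-drug dose, collects the endpoint
readouts (cytosolic H2O2 and the NADPH, thioredoxin and glutathione redox
ratios), filters numerically unstable runs, and compares malignant against
non-malignant cells within each patient with a two-tailed Welch's t-test
(unequal variances, Welch-Satterthwaite degrees of freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from redoxcell.cell_builder import (
    ExpressionProfile,
    MappingConfig,
    apply_cell_model,
    build_cell_model,
    cohort_means,
    default_mapping_config,
)
from redoxcell.kinetic_model import (
    ReactionNetwork,
    SolverSettings,
    endpoint_outputs,
    simulate,
)
from redoxcell.protein_mapping import (
    ProteinMapper,
    default_linear_maps,
    default_rate_constants,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PatientComparison",
    "default_protein_mapper",
    "cohort_solver_settings",
    "run_cohort",
    "cell_protein_table",
    "welch_test",
    "patient_report",
    "box_stats",
]

#: endpoint columns produced for every stable cell
ENDPOINT_COLUMNS = ("H2O2", "NADPH:NADP", "TrxSH:TrxSS", "GSH:GSSG")


@dataclass(frozen=True)
class PatientComparison:
    """Welch's t-test of one patient's malignant vs non-malignant cells."""

    patient_id: str
    n_malignant: int
    n_non_malignant: int
    mean_malignant: float
    mean_non_malignant: float
    t_statistic: float
    df: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.df > 0:
            raise ValueError("degrees of freedom must be positive")
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value out of [0, 1]")


def default_protein_mapper(rna_scale: float = 1.0) -> ProteinMapper:
    """Mapper over the packaged (synthetic stand-in) constant tables."""
    return ProteinMapper(
        rate_constants=default_rate_constants(),
        linear_maps=default_linear_maps(),
        rna_scale=rna_scale,
    )


def cohort_solver_settings(net: ReactionNetwork) -> SolverSettings:
    """Throughput settings for per-cell runs: same end time as the network's
    defaults, adaptive step size (no 1 s cap), and a tight absolute tolerance
    so that trace species (superoxide, oxidized enzyme forms) near zero are
    resolved rather than flagged as spurious negative excursions."""
    s = net.solver
    return SolverSettings(
        t_end=s.t_end, max_step=None, atol=1e-12, rtol=s.rtol, method=s.method
    )


def _profiles_from_anndata(adata: ad.AnnData, genes) -> list[ExpressionProfile]:
    X = pd.DataFrame(
        np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
    )
    profiles = []
    for cell_id in sorted(adata.obs_names):
        row = adata.obs.loc[cell_id]
        profiles.append(
            ExpressionProfile(
                cell_id=str(cell_id),
                patient_id=str(row["patient_id"]),
                malignant=bool(int(row["malignant"])),
                expression={g: float(X.at[cell_id, g]) for g in genes},
            )
        )
    return profiles


def run_cohort(
    adata: ad.AnnData,
    network: ReactionNetwork,
    mapping: MappingConfig | None = None,
    protein_mapper: ProteinMapper | None = None,
    dose: float = 1e-5,
    settings: SolverSettings | None = None,
    baseline_state: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate every cell and return the endpoint table.

    ``adata`` is a cells x genes expression matrix whose ``obs`` carries
    ``patient_id`` and ``malignant``.  ``dose`` is the initial extracellular
    drug concentration (molar).  Cells are processed in sorted cell-id order
    so the output is reproducible regardless of input order.  Unstable runs
    are retained with status="unstable" and NaN endpoints; downstream
    statistics exclude them.
    """
    mapping = mapping or default_mapping_config()
    protein_mapper = protein_mapper or default_protein_mapper()
    settings = settings or cohort_solver_settings(network)
    if dose < 0:
        raise ValueError("dose must be nonnegative")

    missing = set(mapping.genes) - set(map(str, adata.var_names))
    if missing:
        raise KeyError(f"expression matrix missing mapped genes: {sorted(missing)}")
    need = {"patient_id", "malignant"}
    if not need <= set(adata.obs.columns):
        raise KeyError(f"annotations must include {sorted(need)}")

    X = pd.DataFrame(
        np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
    )
    means = cohort_means(X, mapping.genes)
    profiles = _profiles_from_anndata(adata, mapping.genes)

    rows = []
    n_unstable = 0
    for profile in profiles:
        spec = build_cell_model(profile, means, network, mapping, protein_mapper)
        cell_net = apply_cell_model(network, spec)
        y0 = cell_net.initial_state({"blap_ext": dose})
        if baseline_state is not None:
            y0 = baseline_state.copy()
            for name, value in spec.initial_concentrations.items():
                y0[network.species_index(name)] = value
            y0[network.species_index("blap_ext")] = dose
        traj = simulate(cell_net, y0, settings)
        row = {
            "cell_id": profile.cell_id,
            "patient_id": profile.patient_id,
            "malignant": int(profile.malignant),
            "status": traj.status,
        }
        if traj.stable:
            row.update(endpoint_outputs(cell_net, traj.endpoint()))
        else:
            n_unstable += 1
            row.update({c: np.nan for c in ENDPOINT_COLUMNS})
        rows.append(row)
    if n_unstable:
        logger.warning("cohort run: %d unstable cells excluded from statistics", n_unstable)
    return pd.DataFrame(rows)


def cell_protein_table(
    adata: ad.AnnData,
    genes,
    protein_mapper: ProteinMapper | None = None,
    volume_liters: float = 2e-12,
) -> pd.DataFrame:
    """Per-cell molar protein concentrations for the mapped genes — the X
    block of the downstream PLSR."""
    protein_mapper = protein_mapper or default_protein_mapper()
    X = pd.DataFrame(
        np.asarray(adata.X), index=adata.obs_names, columns=adata.var_names
    )
    out = {
        g: [
            protein_mapper.protein_molar(g, float(v), volume_liters)
            for v in X[g]
        ]
        for g in genes
    }
    return pd.DataFrame(out, index=adata.obs_names).loc[sorted(adata.obs_names)]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def welch_test(values_a, values_b, patient_id: str = "") -> PatientComparison:
    """Two-tailed Welch's t-test (unequal variances).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with the
    Welch-Satterthwaite degrees of freedom and a two-sided p-value from the
    t distribution.  Each group needs >= 2 values and nonzero variance in at
    least one group.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    for name, g in (("a", a), ("b", b)):
        if g.size < 2:
            raise ValueError(f"group {name} needs at least 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {name} contains non-finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            # identical degenerate groups: no evidence of difference
            return PatientComparison(
                patient_id=patient_id,
                n_malignant=a.size, n_non_malignant=b.size,
                mean_malignant=float(a.mean()), mean_non_malignant=float(b.mean()),
                t_statistic=0.0, df=float(a.size + b.size - 2), p_value=1.0,
            )
        raise ValueError("both groups have zero variance with different means")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = float((a.mean() - b.mean()) / np.sqrt(se2))
    df = float(se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PatientComparison(
        patient_id=patient_id,
        n_malignant=na, n_non_malignant=nb,
        mean_malignant=float(a.mean()), mean_non_malignant=float(b.mean()),
        t_statistic=t, df=df, p_value=p,
    )


def box_stats(values) -> dict[str, float]:
    """IQR box with 1.5*IQR whiskers (clipped to the data range) and the
    group mean as the center line."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {
        "mean": float(v.mean()),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(lo),
        "whisker_high": float(hi),
        "n_outliers": int(np.sum((v < lo) | (v > hi))),
    }


def patient_report(
    endpoints: pd.DataFrame, value: str = "H2O2", alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient Welch comparison of malignant vs non-malignant endpoints.

    Returns (comparisons, box_table): one Welch's t row per patient with both
    classes represented among stable cells (single-class patients are
    excluded with a warning), plus a tidy per-(patient, class) table of
    box/whisker statistics for plotting.
    """
    stable = endpoints[endpoints["status"] == "stable"].dropna(subset=[value])
    if stable.empty:
        raise ValueError("no stable cells to compare")
    comps, boxes = [], []
    for patient, grp in stable.groupby("patient_id", sort=True):
        mal = grp.loc[grp["malignant"] == 1, value].to_numpy()
        non = grp.loc[grp["malignant"] == 0, value].to_numpy()
        for cls, vals in (("malignant", mal), ("non_malignant", non)):
            if vals.size:
                boxes.append({"patient_id": patient, "group": cls, **box_stats(vals)})
        if mal.size < 2 or non.size < 2:
            logger.warning("patient %s: single-class or too few cells; skipped", patient)
            continue
        c = welch_test(mal, non, patient_id=str(patient))
        comps.append(
            {
                "patient_id": c.patient_id,
                "n_malignant": c.n_malignant,
                "n_non_malignant": c.n_non_malignant,
                "mean_malignant": c.mean_malignant,
                "mean_non_malignant": c.mean_non_malignant,
                "t_statistic": c.t_statistic,
                "df": c.df,
                "p_value": c.p_value,
                "significant": c.p_value < alpha,
            }
        )
    return pd.DataFrame(comps), pd.DataFrame(boxes)
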