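"""Patient-structured synthetic single-cell expression cohorts.

Emulates the structure of a multi-patient tumor scRNA-seq dataset restricted
to a redox gene panel: ~10 patients, hundreds of cells each, malignant and
non-malignant classes, nonnegative normalized expression with dropout zeros,
patient-level shifts (cells cluster by patient) and class-level fold changes
on chosen genes.  The generative model is lognormal with additive log-scale
effects:

    expression = exp(log base mean + patient offset + malignant * LFC + noise)

followed by Bernoulli zero-inflation (dropout).  The pre-dropout matrix,
patient offsets and implanted fold changes are kept as ground truth so every
downstream stage can be tested against known structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "REDOX_GENES",
    "MAPPED_GENES",
    "CohortDesign",
    "GroundTruth",
    "nqo1_dominant_design",
    "generate_cohort",
    "generate_rate_constant_table",
    "write_cohort",
    "read_cohort",
]

#: the 14 genes wired into the kinetic model
MAPPED_GENES = (
    "NQO1", "GLUD1", "G6PD", "POR", "SOD1", "GSR", "TXNRD1", "AQP3",
    "GPX1", "CAT", "PRDX1", "PRDX2", "TXN", "GLRX",
)

#: 35-gene redox panel: the mapped genes plus other antioxidant-pathway
#: members carried along as in real tumor panels (not wired into the model)
REDOX_GENES = MAPPED_GENES + (
    "SOD2", "SOD3", "PRDX3", "PRDX4", "PRDX5", "PRDX6",
    "GPX2", "GPX3", "GPX4", "GPX7", "TXN2", "TXNRD2", "TXNRD3",
    "GSS", "GCLC", "GCLM", "GLRX2", "SRXN1", "NFE2L2", "KEAP1", "IDH1",
)


#: genes HNSCC tumors express with pronounced cell-to-cell heterogeneity;
#: they get elevated cell-level dispersion in the default design
HIGH_DISPERSION_GENES = ("NQO1", "GLUD1", "TXN", "TXNRD1")


@dataclass(frozen=True)
class CohortDesign:
    """Generative design for one synthetic cohort.

    Defaults emulate the structure and scale of multi-patient HNSCC
    single-cell datasets: 10 patients with
    hundreds of cells each (two classes), a 35-gene redox panel, lognormal
    cell-level noise with elevated dispersion for the genes the tumors are
    known to express heterogeneously (NQO1, GLUD1, TXN, TXNRD1), patient
    offsets strong enough that cells cluster by patient, a malignant
    two-fold NQO1 up-shift, and 30% dropout.
    """

    n_patients: int = 10
    cells_per_patient_per_class: int = 200
    genes: tuple[str, ...] = REDOX_GENES
    base_mean: Mapping[str, float] = field(default_factory=dict)  # default 5.0
    dispersion: float | Mapping[str, float] = field(
        default_factory=lambda: {g: 0.8 for g in HIGH_DISPERSION_GENES}
    )                                # cell-level log-normal SD (natural log)
    patient_sd: float = 0.3          # patient offset SD (log scale)
    malignant_lfc: Mapping[str, float] = field(
        default_factory=lambda: {"NQO1": float(np.log(2.0))}
    )
    dropout: float = 0.3             # zero-inflation probability
    seed: int = 0
    base_dispersion: float = 0.4     # dispersion for genes not listed

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.cells_per_patient_per_class < 1:
            raise ValueError("cohort counts must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout probability must be in [0, 1)")
        if min(self.dispersion_vector()) < 0 or self.patient_sd < 0:
            raise ValueError("dispersions must be nonnegative")
        missing = set(self.malignant_lfc) - set(self.genes)
        if missing:
            raise ValueError(f"LFC genes not in panel: {sorted(missing)}")

    def gene_base_mean(self, gene: str) -> float:
        return float(self.base_mean.get(gene, 5.0))

    def dispersion_vector(self) -> np.ndarray:
        """Per-gene cell-level lognormal SD, in panel order."""
        if isinstance(self.dispersion, Mapping):
            return np.array(
                [float(self.dispersion.get(g, self.base_dispersion)) for g in self.genes]
            )
        return np.full(len(self.genes), float(self.dispersion))


def nqo1_dominant_design(**overrides) -> CohortDesign:
    """A cohort design with a dominant NQO1 expression effect.

    NQO1 carries elevated cell-level dispersion while every other gene sits
    at the base dispersion, on top of the malignant NQO1 up-shift — the
    condition under which the drug-activating enzyme, rather than the NADPH
    supply, dominates the endpoint NADPH ratio.  Used by the VIP-ranking
    replicate checks.
    """
    kwargs = dict(dispersion={"NQO1": 0.8})
    kwargs.update(overrides)
    return CohortDesign(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually drew, pre-dropout."""

    pre_dropout: pd.DataFrame            # cells x genes
    patient_offsets: pd.DataFrame        # patients x genes (log scale)
    malignant_lfc: Mapping[str, float]   # implanted class log-fold-changes


def generate_cohort(
    design: CohortDesign, seed: int | None = None
) -> tuple[ad.AnnData, GroundTruth]:
    """Draw one cohort; deterministic given the design (and optional seed
    override).

    Returns an :class:`anndata.AnnData` (cells x genes, dropout applied)
    whose ``obs`` carries ``patient_id`` and ``malignant`` annotations and
    whose ``layers["pre_dropout"]`` holds the noise-free-of-dropout matrix,
    plus the :class:`GroundTruth`.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    genes = list(design.genes)
    n_genes = len(genes)
    log_base = np.log([design.gene_base_mean(g) for g in genes])
    lfc = np.array([design.malignant_lfc.get(g, 0.0) for g in genes])
    disp = design.dispersion_vector()

    patients = [f"P{p:02d}" for p in range(1, design.n_patients + 1)]
    offsets = rng.normal(0.0, design.patient_sd, size=(design.n_patients, n_genes))

    rows, obs_rows = [], []
    for p_i, patient in enumerate(patients):
        for malignant in (0, 1):
            n = design.cells_per_patient_per_class
            noise = rng.normal(0.0, disp, size=(n, n_genes))
            log_expr = log_base + offsets[p_i] + malignant * lfc + noise
            rows.append(np.exp(log_expr))
            for c in range(n):
                obs_rows.append(
                    {
                        "cell_id": f"{patient}_{'M' if malignant else 'N'}{c:04d}",
                        "patient_id": patient,
                        "malignant": malignant,
                    }
                )
    pre = np.vstack(rows)
    obs = pd.DataFrame(obs_rows).set_index("cell_id")
    obs.index.name = None

    keep = rng.random(pre.shape) >= design.dropout
    observed = pre * keep

    adata = ad.AnnData(
        X=observed.astype(np.float64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name=None)),
    )
    adata.layers["pre_dropout"] = pre
    adata.uns["design"] = {
        "n_patients": design.n_patients,
        "cells_per_patient_per_class": design.cells_per_patient_per_class,
        "dispersion": {g: float(d) for g, d in zip(genes, disp)},
        "patient_sd": design.patient_sd,
        "dropout": design.dropout,
        "malignant_lfc": dict(design.malignant_lfc),
        "seed": design.seed if seed is None else seed,
    }
    truth = GroundTruth(
        pre_dropout=pd.DataFrame(pre, index=obs.index, columns=genes),
        patient_offsets=pd.DataFrame(offsets, index=patients, columns=genes),
        malignant_lfc=dict(design.malignant_lfc),
    )
    return adata, truth


def generate_rate_constant_table(
    genes: Sequence[str], seed: int = 0
) -> pd.DataFrame:
    """Synthetic per-gene synthesis/degradation rate constants for testing.

    Translation rates are drawn log-uniformly in 1-100 protein mRNA^-1 h^-1
    and protein half-lives log-uniformly in 1-100 h, the ranges spanned by
    genome-wide pulse-labeling surveys.
    """
    rng = np.random.default_rng(seed)
    k_sp = 10 ** rng.uniform(0, 2, size=len(genes))
    half_life = 10 ** rng.uniform(0, 2, size=len(genes))
    return pd.DataFrame(
        {
            "gene": list(genes),
            "k_sp": k_sp,
            "k_dp": np.log(2.0) / half_life,
        }
    )


# ---------------------------------------------------------------------------
# on-disk dialect: MatrixMarket + genes/barcodes TSVs + annotations TSV
# ---------------------------------------------------------------------------


def write_cohort(adata: ad.AnnData, outdir) -> None:
    """Write matrix.mtx, genes.tsv, barcodes.tsv and annotations.tsv."""
    import os

    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    os.makedirs(outdir, exist_ok=True)
    # genes x cells, the conventional MTX orientation
    mmwrite(os.path.join(outdir, "matrix.mtx"), csr_matrix(np.asarray(adata.X).T))
    pd.Series(adata.var_names).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    ann = adata.obs.reset_index(names="cell_id")[["cell_id", "patient_id", "malignant"]]
    ann.to_csv(os.path.join(outdir, "annotations.tsv"), sep="\t", index=False)


def read_cohort(indir, annotations=None) -> ad.AnnData:
    """Read a cohort written by :func:`write_cohort`.

    ``annotations`` optionally points at a TSV (cell_id, patient_id,
    malignant) elsewhere than ``indir/annotations.tsv``.
    """
    import os

    from scipy.io import mmread

    X = np.asarray(mmread(os.path.join(indir, "matrix.mtx")).todense()).T
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t", header=None)[0]
    barcodes = pd.read_csv(os.path.join(indir, "barcodes.tsv"), sep="\t", header=None)[0]
    ann_path = annotations or os.path.join(indir, "annotations.tsv")
    ann = pd.read_csv(ann_path, sep="\t").set_index("cell_id")
    obs = ann.loc[barcodes]
    obs.index.name = None
    return ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes.tolist(), name=None))
    )
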