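# redoxcell

Single-cell kinetic modeling of quinone-cycling drug metabolism and
hydrogen peroxide clearance.

Tumor cells survive chronic oxidative stress by over-expressing antioxidant
systems, and NQO1-bioactivatable quinones such as β-lapachone exploit this:
NQO1 reduces the quinone to a hydroquinone that O₂ re-oxidizes through the
semiquinone radical, so each catalytic cycle consumes NADPH and delivers
superoxide → H₂O₂ without consuming drug.  Whether a given cell drowns in
H₂O₂ or shrugs the treatment off depends on the joint expression of the
drug-activating, NADPH-supplying and H₂O₂-clearing enzymes — which varies
strongly from cell to cell and from patient to patient.

`redoxcell` turns single-cell RNA-seq profiles into per-cell kinetic
models and asks that question quantitatively.  It is aimed at systems
biologists studying redox-directed chemotherapy and at anyone who wants a
clean, testable reference implementation of expression-parameterized ODE
cohorts.

## What it does

1. **Kinetic model** (`kinetic_model`) — a declarative compartmental
   mass-action ODE system: the quinone futile cycle (rate terms
   k₂₉·[β-lapQ]·[NADPH], k₃₂·[O₂•⁻]², k₃₄·A·([β-lap`ext`]−[β-lapQ])/V, …)
   coupled to the peroxiredoxin/thioredoxin, glutathione, catalase,
   protein-thiol and NADPH-regeneration systems.  Stiff integration
   (LSODA; 2 h, max step 1 s, abstol 10⁻⁸ by default), conservation
   audits, stability flagging.
2. **Protein mapping** (`protein_mapping`) — equilibrium
   synthesis/degradation estimates P\* = k_sp·R/k_dp per gene (linear
   regression fallback), copies → molar conversion.
3. **Cell builder** (`cell_builder`) — scales rate constants by each
   cell's expression relative to the cohort mean (NQO1→k₂₉, SOD1→k₃₂,
   POR→k₃₃, G6PD+GLUD1→NADPH supply, …) and sets initial enzyme abundances
   (GPX1, CAT, PRDX1+PRDX2, TXN, GLRX).
4. **Sensitivity** (`sensitivity`) — ±10% one-at-a-time finite differences
   of the 2 h endpoints, raw and normalized.
5. **Cohort pipeline** (`cohort_pipeline`) — one simulation per cell,
   stability filtering, per-patient Welch's t comparison of malignant vs
   non-malignant endpoint H₂O₂, box/whisker summaries.
6. **Multivariate** (`multivariate`) — NIPALS PLSR of the endpoint
   NADPH:NADP⁺ ratio on the 14 model proteins with cross-validated Q² and
   VIP scores.
7. **Synthetic data** (`synthetic_data`) — patient-structured lognormal
   expression cohorts with dropout and known ground truth, plus MTX/TSV
   writers, so the whole pipeline is testable without external data.

## Worked example

```python
import numpy as np
from redoxcell import kinetic_model as km
from redoxcell import synthetic_data as sd, cohort_pipeline as cp

net = km.default_network()           # packaged base model + drug reactions
rest = km.equilibrate(net)           # drug-free steady state

# average cell, 10 uM extracellular drug, 2 h
dosed = rest.copy()
dosed[net.species_index("blap_ext")] = 1e-5
traj = km.simulate(net, dosed, km.SolverSettings(t_end=7200, max_step=None,
                                                 atol=1e-12, rtol=1e-6))
print(km.endpoint_outputs(net, rest))
print(km.endpoint_outputs(net, traj.endpoint()))
```

prints (resting vs treated):

```
{'H2O2': 1.4378e-09, 'NADPH:NADP': 125.49, 'TrxSH:TrxSS': 1394.1, 'GSH:GSSG': 209910.0}
{'H2O2': 2.1404e-08, 'NADPH:NADP': 2.45,  'TrxSH:TrxSS': 66.7,   'GSH:GSSG': 5874.0}
```

— the drug raises cytosolic H₂O₂ ~15-fold and collapses the NADPH:NADP⁺
ratio ~50-fold while the thiol pools oxidize, the signature of quinone
futile cycling.  A full cohort:

```python
adata, truth = sd.generate_cohort(sd.CohortDesign(seed=0))   # 10 patients x 400 cells
endpoints = cp.run_cohort(adata, net, baseline_state=rest)   # ~1 min
comparisons, boxes = cp.patient_report(endpoints)
print(comparisons[["patient_id", "t_statistic", "p_value"]].head(3))
```

```
  patient_id  t_statistic   p_value
0        P01     2.243861  0.025418
1        P02     3.061692  0.002363
2        P03     2.274468  0.023475
```

With the default design (malignant cells carry a two-fold NQO1 up-shift),
all 10 patients show higher mean malignant H₂O₂ and 7 of 10 reach Welch
p < 0.05 — the pattern that motivates selecting patients for this class of
therapy by their redox profile.

The same pipeline is scriptable from a shell:

```bash
redoxcell synth --seed 0 --out cohort/
redoxcell cohort --matrix cohort/ --dose 10 --out results/
redoxcell sensitivity --out sens.csv
```

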