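# emtkit

Combinatorial-perturbation analysis of the TGF-β/ZEB1 circuit controlling the
epithelial-to-mesenchymal transition (EMT), packaged as a tested, reusable
pipeline that runs end to end on synthetic data with planted structure.

## Who this is for

Systems biologists studying EMT regulatory logic, and computational
biologists who need a reference implementation of the analysis chain that
goes from eight-contrast differential-expression tables to regulatory-gate
calls and a mechanistic ODE circuit:

1. **Responder divergence** — call per-contrast responders (q ≤ 0.05,
   |logFC| threshold) and quantify how much less coherently M-genes respond
   than E-genes, via Jaccard indices J = |A∩B| / |A∪B| over all 28 pairs of
   contrasts, with a one-sample t-test on the per-pair differences J_E − J_M.
2. **Semi-supervised SOM classification** — row-scale logFC profiles, train
   a 10 × 10 hexagonal self-organizing map (data presented 1000 times,
   learning rate declining linearly 0.05 → 0.01), label nodes where one
   curated annotation dominates 2:1, propagate labels to unannotated genes,
   and hierarchically cluster the codebooks of M-dominant nodes
   (within-cluster-sum-of-squares elbow picks the cluster count).
   A plain two-cluster hierarchical baseline is included for comparison.
3. **Gate inference** — formalize each M-cluster's regulatory logic from its
   contrast medians and Mann–Whitney dependence tests: AND (needs TGF-β and
   ZEB1 jointly), OR (either factor), ZEB1-only, or repressed-E.
4. **Enrichment and survival statistics** — Fisher's exact term enrichment
   with Benjamini–Hochberg correction; per-cluster aggregation of
   survival-month differences.
5. **Motility metrics** — per-track mean instantaneous velocity
   v = √(v_x² + v_y²), scaled displacement |x(t_end) − x(t_start)|/Δt,
   straightness index (net over path length), neighbors within a 30 µm
   radius; Mann–Whitney comparisons across conditions and Spearman
   correlation with expression.
6. **Circuit model** — a six-node sigmoidal ODE network
   dX_i/dt = γ_i (F(σ_i W_i) − X_i) with
   W_i = ω⁰_i + Σ_j ω_{j→i} X_j, F(u) = 1/(1+e^(−u)), wiring T ↔ Z mutual
   activation, Z ⊣ E ⊣ Z mutual inhibition, M1 = AND(T, Z), M2 = OR(T, Z),
   M3 = f(Z); steady states, bifurcation diagrams along exogenous TGF-β or
   ZEB1, the EMT-spectrum score M1 + M2 + M3 − E, and reversibility
   classification of perturbation protocols.

A synthetic-data module generates every input the pipeline needs — expression
tables whose class templates carry the characteristic cluster medians (e.g.
M1 TGF-β response 0.83 collapsing to 0.14 without ZEB1), persistent-random-walk
trajectories, term annotations with planted enrichment, and survival tables
with a planted M3 shift — so the whole analysis is exercisable and testable
without any external data.

## Worked example

```python
import numpy as np
import pandas as pd
from emtkit import (GeneratorConfig, SOMClassifier, cluster_m_nodes,
                    generate_expression_profiles)
from emtkit.cluster_stats import infer_gates

ds = generate_expression_profiles(GeneratorConfig(seed=1))   # 500 genes
emt = ds.emt_subset()                                        # 400 EMT genes
som = SOMClassifier(random_state=1).fit(emt.logfc.to_numpy(),
                                        emt.annotation.to_numpy())
print(som.propagation_report_["correct_frac"])     # 1.0
truth_em = np.where(emt.class_truth == "E", "E", "M")
print((som.labels_ == truth_em).mean())            # 0.9825

res = cluster_m_nodes(som)                         # elbow picks k = 3
clusters = pd.Series(res.gene_clusters, index=emt.gene_ids)
gates = infer_gates(emt, clusters)
print({c: g.gate for c, g in sorted(gates.items())})
# {'M1': 'OR', 'M2': 'ZEB1_only', 'M3': 'AND'}   (names ordered by size,
#  so each discovered cluster carries the gate of the template it recovered)
```

All 242 annotated genes are propagated correctly (the hierarchical baseline
also reaches 0% error at this noise), 98.25% of all 400 EMT genes receive
their true E/M call, and the three planted gate logics — AND, OR and
ZEB1-only — are each recovered on the discovered clusters.

Run the whole pipeline into one report directory (deterministic per seed):

```bash
emtkit run-all --seed 1 --out report/
```

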