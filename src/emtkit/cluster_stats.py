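"""Statistical characterisation of gene clusters and regulatory-gate inference.

Each M-gene cluster is compared across the key perturbation contrasts
(Mann–Whitney U on logFC distributions), and the pattern of median responses
is formalised into a regulatory logic gate: AND (needs both TGF-β and ZEB1),
OR (either factor suffices), ZEB1-only, or repressed-E.  PCA loadings,
classification metrics and the survival-difference aggregation used for the
prognosis analysis live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, confusion_matrix

from .contrasts import GATE_CONTRASTS
from .dataset import ExpressionDataset
from .stats import MannWhitneyResult, TTestResult, mann_whitney, one_sample_t


def contrast_comparison(
    data: ExpressionDataset, genes, contrast_a: str, contrast_b: str
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U between a gene set's logFC under two contrasts."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty cluster")
    logfc = data.logfc.loc[genes]
    return mann_whitney(logfc[contrast_a].to_numpy(), logfc[contrast_b].to_numpy())


GATES = ("AND", "OR", "ZEB1_only", "repressed_E", "indeterminate")


@dataclass
class GateCall:
    cluster: str
    gate: str
    medians: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)


def infer_gate(
    data: ExpressionDataset,
    genes,
    cluster: str = "",
    effect_min: float = 0.3,
    alpha: float = 0.05,
) -> GateCall:
    """Classify a cluster's regulatory logic from its contrast medians.

    Using the medians of logFC under TGF-β induction (m_t), ZEB1 induction
    (m_z), TGF-β induction without ZEB1 (m_t_nz) and ZEB1 induction without
    TGF-β (m_z_nt):

    - AND: responds to TGF-β (m_t ≥ effect_min) but the response is lost
      without ZEB1 (m_t_nz < effect_min) and ZEB1 alone is insufficient
      (m_z < effect_min);
    - OR: responds to both factors and neither response depends on the other
      (Mann–Whitney between the paired contrasts non-significant);
    - ZEB1_only: responds to ZEB1 with or without TGF-β but not to the
      ZEB1-independent TGF-β pathway (m_t_nz < effect_min);
    - repressed_E: both inductions repress (medians ≤ −effect_min);
    - indeterminate otherwise.

    ``effect_min`` is this package's formalisation of "responds" on the logFC
    scale; the dependence tests are the study's own Mann–Whitney comparisons.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty cluster")
    logfc = data.logfc.loc[genes]
    c = GATE_CONTRASTS
    med = {k: float(logfc[v].median()) for k, v in c.items()}
    mw_t_dep = mann_whitney(logfc[c["tgfb"]], logfc[c["tgfb_no_zeb1"]])
    mw_z_dep = mann_whitney(logfc[c["zeb1"]], logfc[c["zeb1_no_tgfb"]])
    p = {"tgfb_dependence": mw_t_dep.p, "zeb1_dependence": mw_z_dep.p}

    m_t, m_z = med["tgfb"], med["zeb1"]
    m_t_nz, m_z_nt = med["tgfb_no_zeb1"], med["zeb1_no_tgfb"]
    if m_t >= effect_min and m_t_nz < effect_min and m_z < effect_min:
        gate = "AND"
    elif (
        m_t >= effect_min
        and m_z >= effect_min
        and mw_t_dep.p > alpha
        and mw_z_dep.p > alpha
    ):
        gate = "OR"
    elif m_z >= effect_min and m_z_nt >= effect_min and m_t_nz < effect_min:
        gate = "ZEB1_only"
    elif m_t <= -effect_min and m_z <= -effect_min:
        gate = "repressed_E"
    else:
        gate = "indeterminate"
    return GateCall(cluster=cluster, gate=gate, medians=med, p_values=p)


def infer_gates(
    data: ExpressionDataset,
    gene_clusters: pd.Series,
    effect_min: float = 0.3,
    alpha: float = 0.05,
    skip: tuple = ("other",),
) -> dict[str, GateCall]:
    """Gate call per cluster label (clusters in ``skip`` are not called)."""
    out = {}
    for cl in sorted(gene_clusters.unique()):
        if cl in skip:
            continue
        genes = gene_clusters.index[gene_clusters == cl]
        out[cl] = infer_gate(data, genes, cluster=cl, effect_min=effect_min, alpha=alpha)
    return out


def classification_metrics(predicted, truth) -> dict:
    """Accuracy, adjusted Rand index and confusion table of two labelings."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    labels = sorted(set(predicted) | set(truth))
    return {
        "accuracy": float(np.mean(predicted == truth)),
        "ari": float(adjusted_rand_score(truth, predicted)),
        "confusion": pd.DataFrame(
            confusion_matrix(truth, predicted, labels=labels),
            index=labels,
            columns=labels,
        ),
    }


def pca_loadings(logfc_matrix) -> dict:
    """Principal components of the genes × contrasts logFC matrix.

    Returns unit-norm loadings (components × contrasts), the explained
    variance ratios, and the gene scores.  Rank-deficient input simply yields
    trailing zero-variance components.
    """
    x = np.asarray(logfc_matrix, dtype=float)
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("PCA needs >= 2 genes and >= 2 contrasts")
    pca = PCA(n_components=min(x.shape))
    scores = pca.fit_transform(x)
    return {
        "loadings": pca.components_,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "scores": scores,
    }


def survival_aggregation(
    table: pd.DataFrame,
    discard_nonsignificant: bool = True,
) -> pd.DataFrame:
    """Aggregate per-gene survival-month differences within clusters.

    Expects columns ``cluster``, ``survival_diff_months`` and ``significant``
    (per-gene high-vs-low cohort difference and its significance flag).  Genes
    without a significant difference are discarded by default before the
    per-cluster one-sample t-test against 0; the fraction of genes with a
    significant positive difference is always computed over all genes of the
    cluster.
    """
    out = []
    for cl, grp in table.groupby("cluster", sort=True):
        sig = grp[grp["significant"]] if discard_nonsignificant else grp
        diffs = sig["survival_diff_months"].to_numpy(float)
        if diffs.size >= 2:
            tt = one_sample_t(diffs)
        else:
            tt = TTestResult(
                mean=float(diffs.mean()) if diffs.size else float("nan"),
                t=None, p=None, n=diffs.size, degenerate=True,
            )
        pos_sig = grp["significant"] & (grp["survival_diff_months"] > 0)
        out.append(
            {
                "cluster": cl,
                "n_genes": len(grp),
                "n_retained": diffs.size,
                "mean_diff_months": tt.mean,
                "t": tt.t,
                "p": tt.p,
                "degenerate": tt.degenerate,
                "pct_significant_positive": 100.0 * pos_sig.mean(),
            }
        )
    return pd.DataFrame(out).set_index("cluster")
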