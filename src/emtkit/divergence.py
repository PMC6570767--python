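"""Responder calling and E-vs-M divergence via Jaccard indices.

The study's first analysis: which genes respond (q and |logFC| thresholds) in
each of the eight contrasts, how strongly the per-contrast responder sets
overlap within the E-gene and M-gene annotations, and whether M-genes show
systematically lower overlap (higher divergence) than E-genes across the 28
unordered contrast pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .contrasts import CONTRASTS
from .dataset import ExpressionDataset
from .stats import TTestResult, one_sample_t

#: sentinel for a Jaccard index over an empty union
UNDEFINED = None


@dataclass
class ResponderSets:
    """Per-contrast up- and down-regulated gene-id sets with the thresholds used."""

    up: dict[str, set] = field(repr=False)
    down: dict[str, set] = field(repr=False)
    q_max: float = 0.05
    min_abs_logfc: float = 0.0

    def responders(self, contrast: str) -> set:
        """Direction-agnostic responder set (union of up and down)."""
        return self.up[contrast] | self.down[contrast]


def call_responders(
    data: ExpressionDataset, q_max: float = 0.05, min_abs_logfc: float = 0.0
) -> ResponderSets:
    """Gene is up in contrast c iff q_c ≤ q_max and logFC_c ≥ min_abs_logfc;
    down analogously with logFC_c ≤ −min_abs_logfc."""
    if q_max < 0 or min_abs_logfc < 0:
        raise ValueError("thresholds must be >= 0")
    logfc, q = data.logfc, data.q
    up, down = {}, {}
    for c in CONTRASTS:
        sig = q[c] <= q_max
        up[c] = set(data.gene_ids[sig & (logfc[c] >= min_abs_logfc)])
        down[c] = set(data.gene_ids[sig & (logfc[c] <= -min_abs_logfc)])
        if min_abs_logfc == 0.0:
            # a gene with logFC exactly 0 satisfies both signs; keep it out of
            # both so up ∩ down = ∅ holds
            zero = set(data.gene_ids[sig & (logfc[c] == 0.0)])
            up[c] -= zero
            down[c] -= zero
    return ResponderSets(up=up, down=down, q_max=q_max, min_abs_logfc=min_abs_logfc)


def jaccard_index(a: set, b: set) -> float | None:
    """|A∩B| / |A∪B|; ``None`` (undefined) when both sets are empty."""
    union = a | b
    if not union:
        return UNDEFINED
    return len(a & b) / len(union)


@dataclass
class DivergenceResult:
    """Per-pair Jaccard indices for E and M responders and their contrast."""

    pairs: pd.DataFrame = field(repr=False)  # pair_a, pair_b, j_e, j_m, diff
    ttest: TTestResult = None  # one-sample t of (J_E − J_M) against 0
    n_undefined: int = 0


def pairwise_jaccard_analysis(
    sets: ResponderSets, annotation: pd.Series
) -> DivergenceResult:
    """Jaccard overlap of E- and of M-annotated responders for all 28 contrast pairs.

    For each unordered pair of contrasts, the direction-agnostic responder
    sets are restricted to E-annotated genes (J_E) and to M-annotated genes
    (J_M); the per-pair differences J_E − J_M are tested against 0 with a
    two-sided one-sample t-test.  Pairs where either Jaccard is undefined
    (empty union) are flagged and excluded from the test.
    """
    if annotation is None:
        raise ValueError("annotation required")
    e_genes = set(annotation.index[annotation == "E"])
    m_genes = set(annotation.index[annotation == "M"])
    rows = []
    for ca, cb in combinations(CONTRASTS, 2):
        ra, rb = sets.responders(ca), sets.responders(cb)
        j_e = jaccard_index(ra & e_genes, rb & e_genes)
        j_m = jaccard_index(ra & m_genes, rb & m_genes)
        diff = None if (j_e is None or j_m is None) else j_e - j_m
        rows.append((ca, cb, j_e, j_m, diff))
    pairs = pd.DataFrame(rows, columns=["contrast_a", "contrast_b", "j_e", "j_m", "diff"])
    defined = pairs["diff"].dropna().astype(float)
    ttest = one_sample_t(defined.to_numpy()) if len(defined) else TTestResult(
        mean=float("nan"), t=None, p=None, n=0, degenerate=True
    )
    return DivergenceResult(
        pairs=pairs, ttest=ttest, n_undefined=int(pairs["diff"].isna().sum())
    )


@dataclass
class OverlapSummary:
    """Venn-style overlap of the TGF-β and ZEB1 induction responder sets."""

    per_class: pd.DataFrame = field(repr=False)


def overlap_summary(
    sets: ResponderSets,
    annotation: pd.Series,
    contrast_tgfb: str = "TGFb_vs_WT",
    contrast_zeb1: str = "DOX_vs_DMSO",
) -> OverlapSummary:
    """Per annotation class: unique/shared responder counts between the TGF-β
    and ZEB1 induction contrasts, the Jaccard of the two sets, and the
    fraction of responding genes down-/up-regulated under induction."""
    rows = []
    for cls in ("E", "M"):
        genes = set(annotation.index[annotation == cls])
        r_t = sets.responders(contrast_tgfb) & genes
        r_z = sets.responders(contrast_zeb1) & genes
        shared = r_t & r_z
        responding = r_t | r_z
        down = (sets.down[contrast_tgfb] | sets.down[contrast_zeb1]) & responding
        up = (sets.up[contrast_tgfb] | sets.up[contrast_zeb1]) & responding
        j = jaccard_index(r_t, r_z)
        rows.append(
            {
                "class": cls,
                "unique_tgfb": len(r_t - r_z),
                "unique_zeb1": len(r_z - r_t),
                "shared": len(shared),
                "jaccard": 0.0 if j is None else j,
                "frac_down": len(down) / len(responding) if responding else 0.0,
                "frac_up": len(up) / len(responding) if responding else 0.0,
            }
        )
    return OverlapSummary(per_class=pd.DataFrame(rows).set_index("class"))


def threshold_sweep(
    data: ExpressionDataset, q_grid, logfc_grid
) -> pd.DataFrame:
    """Re-run the pairwise Jaccard analysis across a grid of thresholds.

    Returns one row per (q_max, min_abs_logfc) with the mean J_E − J_M, its
    t-test p (None if degenerate) and the total responder count, for checking
    robustness of the divergence direction to threshold choice.
    """
    q_grid = list(q_grid)
    logfc_grid = list(logfc_grid)
    if not q_grid or not logfc_grid:
        raise ValueError("threshold grids must be nonempty")
    rows = []
    for q_max in q_grid:
        for lfc in logfc_grid:
            sets = call_responders(data, q_max=q_max, min_abs_logfc=lfc)
            res = pairwise_jaccard_analysis(sets, data.annotation)
            n_resp = sum(len(sets.responders(c)) for c in CONTRASTS)
            rows.append(
                {
                    "q_max": q_max,
                    "min_abs_logfc": lfc,
                    "mean_diff": res.ttest.mean,
                    "p": res.ttest.p,
                    "n_responders": n_resp,
                    "n_undefined_pairs": res.n_undefined,
                }
            )
    return pd.DataFrame(rows)
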