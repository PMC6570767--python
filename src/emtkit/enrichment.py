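"""Term enrichment of gene sets by Fisher's exact test with BH correction."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .stats import bh_adjust


def fisher_enrichment(
    gene_set,
    annotation: pd.DataFrame,
    universe=None,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-term over-representation of ``gene_set`` against a gene universe.

    ``annotation`` is a two-column (gene_id, term_id) table.  For each term
    the 2×2 contingency of set/background × annotated/not is tested with
    Fisher's exact test — one-sided toward enrichment by default, two-sided
    available via ``alternative='two-sided'``.  BH-adjusted q-values are
    computed over all tested terms.  The universe defaults to all genes in the
    annotation table.

    Returns a DataFrame indexed by term with columns k (annotated in set),
    K (annotated in universe), n (set size), N (universe size), odds_ratio,
    p, q, significant (p < alpha).
    """
    if universe is None:
        universe = set(annotation["gene_id"])
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    ann = annotation[annotation["gene_id"].isin(universe)]
    if gene_set == set() or ann.empty:
        return pd.DataFrame(
            columns=["k", "K", "n", "N", "odds_ratio", "p", "q", "significant"]
        )
    N = len(universe)
    n = len(gene_set)
    rows = []
    for term, grp in ann.groupby("term_id", sort=True):
        term_genes = set(grp["gene_id"])
        K = len(term_genes)
        k = len(term_genes & gene_set)
        table = [[k, n - k], [K - k, N - n - (K - k)]]
        odds, p = stats.fisher_exact(table, alternative=alternative)
        rows.append((term, k, K, n, N, odds, p))
    out = pd.DataFrame(
        rows, columns=["term_id", "k", "K", "n", "N", "odds_ratio", "p"]
    ).set_index("term_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p"] < alpha
    return out


def cluster_term_overlap(term_sets: dict[str, set]) -> dict:
    """Venn counts of significant terms shared by all clusters vs exclusive.

    Returns the terms found in every cluster, the terms exclusive to each
    cluster, and their counts.
    """
    if len(term_sets) < 2:
        raise ValueError("need >= 2 clusters")
    names = sorted(term_sets)
    shared = set.intersection(*(set(term_sets[n]) for n in names))
    exclusive = {
        n: set(term_sets[n]) - set().union(*(term_sets[m] for m in names if m != n))
        for n in names
    }
    return {
        "shared": shared,
        "n_shared": len(shared),
        "exclusive": exclusive,
        "n_exclusive": {n: len(v) for n, v in exclusive.items()},
    }
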