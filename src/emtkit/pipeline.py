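"""End-to-end pipeline: simulate → divergence → classify → characterize →
enrich → motility → model, writing one reproducible report directory."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    GeneratorConfig,
    MotilityConfig,
    SOMClassifier,
    call_responders,
    cluster_m_nodes,
    fisher_enrichment,
    generate_annotation_table,
    generate_expression_profiles,
    generate_survival_table,
    generate_trajectories,
    hclust_baseline,
    overlap_summary,
    pairwise_jaccard_analysis,
)
from .cluster_stats import (
    classification_metrics,
    infer_gates,
    pca_loadings,
    survival_aggregation,
)
from .io import write_expression_table, write_provenance, write_table, write_trajectories
from .model import DEFAULT_SPEC, behavior_suite, validate_gates
from . import motility as mot

DEFAULT_STAGES = (
    "simulate", "divergence", "classify", "characterize", "enrich", "motility", "model",
)


def run_all(config: dict | None = None, out_dir="report", seed: int = 0) -> Path:
    """Run the enabled pipeline stages in dependency order.

    ``config`` may override generator parameters (``generator`` /
    ``motility`` sections), thresholds (``q_max``, ``min_abs_logfc``) and the
    enabled ``stages``.  Outputs are plain TSV/JSON and byte-identical across
    reruns with the same seed and config.
    """
    config = dict(config or {})
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_provenance(out, seed, config)

    gen_cfg = GeneratorConfig(**config.get("generator", {}), seed=seed)
    ds = generate_expression_profiles(gen_cfg)
    if "simulate" in stages:
        write_expression_table(ds, out / "expression.tsv")

    if "divergence" in stages:
        sets = call_responders(
            ds, config.get("q_max", 0.05), config.get("min_abs_logfc", 0.0)
        )
        div = pairwise_jaccard_analysis(sets, ds.annotation)
        write_table(div.pairs, out / "divergence_pairs.tsv")
        summ = overlap_summary(sets, ds.annotation)
        write_table(summ.per_class.reset_index(), out / "overlap_summary.tsv")
        with open(out / "divergence.json", "w") as fh:
            json.dump(
                {
                    "mean_j_e_minus_j_m": div.ttest.mean,
                    "p": div.ttest.p,
                    "n_pairs": int(len(div.pairs)),
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")

    emt = ds.emt_subset()
    som = None
    clusters = None
    if "classify" in stages:
        som = SOMClassifier(random_state=seed).fit(
            emt.logfc.to_numpy(), emt.annotation.to_numpy()
        )
        k = config.get("k")  # None -> elbow
        mres = cluster_m_nodes(som, k=k)
        clusters = pd.Series(mres.gene_clusters, index=emt.gene_ids, name="m_cluster")
        lab = som.node_labeling_
        write_table(
            pd.DataFrame(
                {
                    "node": np.arange(lab.labels.size),
                    "row": np.arange(lab.labels.size) // som.n_cols,
                    "col": np.arange(lab.labels.size) % som.n_cols,
                    "label": lab.labels,
                    "n_e": lab.e_counts,
                    "n_m": lab.m_counts,
                    "n_genes": lab.n_genes,
                }
            ),
            out / "som_nodes.tsv",
        )
        write_table(
            pd.DataFrame(
                {
                    "gene_id": emt.gene_ids,
                    "node": som.assignment_,
                    "em_call": som.labels_,
                    "m_cluster": mres.gene_clusters,
                }
            ),
            out / "gene_clusters.tsv",
        )
        write_table(pd.DataFrame(som.codebook_), out / "codebooks.tsv")
        write_table(
            pd.DataFrame({"k": np.arange(1, mres.wss_curve.size + 1), "wss": mres.wss_curve}),
            out / "wss_curve.tsv",
        )
        _, baseline_rate = hclust_baseline(
            emt.logfc.to_numpy(), emt.annotation.to_numpy()
        )
        report = dict(som.propagation_report_)
        report["hclust_baseline_misclassification"] = baseline_rate
        report["chosen_k"] = int(mres.k)
        with open(out / "classification.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")

    if "characterize" in stages and clusters is not None:
        gates = infer_gates(emt, clusters)
        with open(out / "gates.json", "w") as fh:
            json.dump(
                {
                    cl: {"gate": g.gate, "medians": g.medians, "p_values": g.p_values}
                    for cl, g in gates.items()
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
        pca = pca_loadings(emt.logfc.to_numpy())
        write_table(pd.DataFrame(pca["loadings"], columns=emt.logfc.columns),
                    out / "pca_loadings.tsv")
        surv = generate_survival_table(
            config.get("survival_shift", {"E": 0.0, "M1": 0.0, "M2": 0.0, "M3": 10.0}),
            seed=seed,
        )
        write_table(survival_aggregation(surv).reset_index(), out / "survival.tsv")
        if emt.class_truth is not None:
            truth_em = np.where(emt.class_truth.to_numpy() == "E", "E", "M")
            metrics = classification_metrics(som.labels_, truth_em)
            with open(out / "classification_truth.json", "w") as fh:
                json.dump(
                    {"accuracy": metrics["accuracy"], "ari": metrics["ari"]},
                    fh, indent=2, sort_keys=True,
                )
                fh.write("\n")

    if "enrich" in stages and clusters is not None:
        target = list(clusters.index[clusters == "M1"])
        terms = generate_annotation_table(
            n_genes=0, n_terms=50, planted_terms=3,
            target_genes=target, all_genes=list(ds.gene_ids), seed=seed,
        )
        enr = fisher_enrichment(target, terms, universe=list(ds.gene_ids))
        write_table(enr.reset_index(), out / "enrichment_M1.tsv")

    if "motility" in stages:
        mcfg = MotilityConfig(**config.get("motility", {}), seed=seed)
        tset = generate_trajectories(mcfg)
        write_trajectories(tset, out / "trajectories.tsv")
        kept = mot.filter_trajectories(tset)
        metrics = mot.track_metrics(kept)
        write_table(metrics, out / "track_metrics.tsv")
        write_table(mot.compare_conditions(metrics), out / "motility_comparisons.tsv")

    if "model" in stages:
        violations = validate_gates(DEFAULT_SPEC)
        suite = behavior_suite(DEFAULT_SPEC, seed=seed)
        with open(out / "model_suite.json", "w") as fh:
            json.dump(
                {"gate_violations": violations, **{k: bool(v) for k, v in suite.items()}},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")
    return out
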