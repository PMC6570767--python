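"""Cell-trajectory motility metrics and cross-condition comparisons.

Metrics per track: mean instantaneous velocity (per-step speed averaged over
the track), scaled displacement (net displacement over total elapsed time),
straightness index (net displacement over integrated path length, in [0, 1])
and mean number of neighbors within a search radius.  Tracks must be longer
than 24 frames (6 h at 15-minute frames) to enter the analysis.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .dataset import TrajectorySet
from .stats import mann_whitney, one_sample_t, spearman

METRICS = ("velocity_um_min", "scaled_displacement_um_min", "straightness_index",
           "mean_neighbors")


def filter_trajectories(tset: TrajectorySet, min_frames: int = 24) -> TrajectorySet:
    """Keep tracks with strictly more than ``min_frames`` frames."""
    counts = tset.table.groupby(["condition", "track_id"])["frame"].transform("size")
    return TrajectorySet(
        tset.table[counts > min_frames].copy(), tset.frame_interval_min
    )


def _steps(track: pd.DataFrame, dt_min: float):
    xy = track[["x_um", "y_um"]].to_numpy(float)
    frames = track["frame"].to_numpy()
    if np.any(np.diff(frames) <= 0):
        raise ValueError("frame indices must be strictly increasing")
    d_xy = np.diff(xy, axis=0)
    d_t = np.diff(frames) * dt_min
    return xy, d_xy, d_t


def instantaneous_velocity(track: pd.DataFrame, dt_min: float = 15.0) -> float:
    """Mean per-step speed √(vx² + vy²) in µm/min."""
    if len(track) < 2:
        raise ValueError("need >= 2 frames")
    _, d_xy, d_t = _steps(track, dt_min)
    return float(np.mean(np.linalg.norm(d_xy, axis=1) / d_t))


def scaled_displacement(track: pd.DataFrame, dt_min: float = 15.0) -> float:
    """Net Euclidean displacement over total elapsed time, in µm/min."""
    if len(track) < 2:
        raise ValueError("need >= 2 frames")
    xy, _, d_t = _steps(track, dt_min)
    total_t = d_t.sum()
    if total_t <= 0:
        raise ValueError("zero track duration")
    return float(np.linalg.norm(xy[-1] - xy[0]) / total_t)


def straightness_index(track: pd.DataFrame) -> float | None:
    """Net displacement divided by integrated path length; None when the cell
    never moved (zero path length)."""
    xy = track[["x_um", "y_um"]].to_numpy(float)
    path = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
    if path == 0.0:
        return None
    return float(np.linalg.norm(xy[-1] - xy[0]) / path)


def mean_nearest_neighbors(
    tset: TrajectorySet, radius_um: float = 30.0
) -> pd.DataFrame:
    """Per track: mean count of other cells within ``radius_um`` per frame.

    Cells are compared within the same condition and frame; a cell at exactly
    the search radius counts as a neighbor.  The per-frame counts are summed
    over the track's frames and divided by its frame count.
    """
    rows = []
    for cond in tset.conditions:
        sub = tset.table[tset.table["condition"] == cond]
        neighbor_sum: dict = {}
        frame_count: dict = {}
        for _, frame_grp in sub.groupby("frame"):
            ids = frame_grp["track_id"].to_numpy()
            xy = frame_grp[["x_um", "y_um"]].to_numpy(float)
            d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
            counts = ((d <= radius_um).sum(axis=1) - 1)  # exclude self
            for tid, c in zip(ids, counts):
                neighbor_sum[tid] = neighbor_sum.get(tid, 0) + int(c)
                frame_count[tid] = frame_count.get(tid, 0) + 1
        for tid in sorted(neighbor_sum):
            rows.append((cond, tid, neighbor_sum[tid] / frame_count[tid]))
    return pd.DataFrame(rows, columns=["condition", "track_id", "mean_neighbors"])


def track_metrics(tset: TrajectorySet, radius_um: float = 30.0) -> pd.DataFrame:
    """All four motility metrics for every track, one row per track."""
    rows = []
    for cond, tid, track in tset.tracks():
        rows.append(
            {
                "condition": cond,
                "track_id": tid,
                "velocity_um_min": instantaneous_velocity(track, tset.frame_interval_min),
                "scaled_displacement_um_min": scaled_displacement(
                    track, tset.frame_interval_min
                ),
                "straightness_index": straightness_index(track),
            }
        )
    out = pd.DataFrame(rows)
    nn = mean_nearest_neighbors(tset, radius_um)
    return out.merge(nn, on=["condition", "track_id"], how="left")


def compare_conditions(
    metrics: pd.DataFrame, pairs=None, metric_names=METRICS
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per metric per condition pair + median fold change."""
    conditions = sorted(metrics["condition"].unique())
    if pairs is None:
        pairs = list(combinations(conditions, 2))
    rows = []
    for ca, cb in pairs:
        a = metrics[metrics["condition"] == ca]
        b = metrics[metrics["condition"] == cb]
        for m in metric_names:
            va = a[m].dropna().to_numpy(float)
            vb = b[m].dropna().to_numpy(float)
            if va.size < 2 or vb.size < 2:
                raise ValueError(f"need >= 2 tracks per condition for {m}")
            res = mann_whitney(va, vb)
            fold = res.median_a / res.median_b if res.median_b != 0 else np.inf
            rows.append(
                {
                    "condition_a": ca,
                    "condition_b": cb,
                    "metric": m,
                    "median_a": res.median_a,
                    "median_b": res.median_b,
                    "median_fold": fold,
                    "p": res.p,
                }
            )
    return pd.DataFrame(rows)


def condition_metric_summary(
    metrics: pd.DataFrame, how: str = "median"
) -> pd.DataFrame:
    """Per-condition summary (median by default, mean via ``how='mean'``)."""
    agg = metrics.groupby("condition")[list(METRICS)]
    return agg.median() if how == "median" else agg.mean()


def expression_motility_correlation(
    expression: pd.DataFrame, metric_summary: pd.DataFrame
) -> pd.DataFrame:
    """Spearman ρ between each gene's per-condition expression and each metric.

    ``expression`` is genes × conditions, ``metric_summary`` conditions ×
    metrics; the condition sets must match.  Genes or metrics constant across
    conditions yield NaN (undefined correlation, flagged rather than forced).
    """
    conds = list(metric_summary.index)
    if set(conds) != set(expression.columns):
        raise ValueError("expression columns must match summary conditions")
    expr = expression[conds]
    rows = []
    for gene, vec in expr.iterrows():
        for m in metric_summary.columns:
            rho = spearman(vec.to_numpy(float), metric_summary[m].to_numpy(float))
            rows.append((gene, m, np.nan if rho is None else rho))
    return pd.DataFrame(rows, columns=["gene_id", "metric", "rho"])


def cluster_correlation_tests(
    correlations: pd.DataFrame, gene_clusters: pd.Series
) -> pd.DataFrame:
    """Per-cluster one-sample t-test of the gene-level ρ distribution vs 0."""
    merged = correlations.merge(
        gene_clusters.rename("cluster"), left_on="gene_id", right_index=True
    )
    rows = []
    for (cl, m), grp in merged.groupby(["cluster", "metric"], sort=True):
        tt = one_sample_t(grp["rho"].dropna().to_numpy())
        rows.append(
            {"cluster": cl, "metric": m, "mean_rho": tt.mean, "p": tt.p, "n": tt.n}
        )
    return pd.DataFrame(rows)
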