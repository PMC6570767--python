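"""Trajectory metrics: closed-form fixtures, filters, geometry, comparisons."""

import numpy as np
import pandas as pd
import pytest

from emtkit import MotilityConfig, generate_trajectories
from emtkit.dataset import TrajectorySet
from emtkit.motility import (
    compare_conditions,
    condition_metric_summary,
    expression_motility_correlation,
    filter_trajectories,
    instantaneous_velocity,
    mean_nearest_neighbors,
    scaled_displacement,
    straightness_index,
    track_metrics,
)
from emtkit.stats import mann_whitney

from oracles import midrank_spearman


def make_track(points, track_id=0, condition="WT"):
    return pd.DataFrame(
        {
            "condition": condition,
            "track_id": track_id,
            "frame": range(len(points)),
            "x_um": [p[0] for p in points],
            "y_um": [p[1] for p in points],
        }
    )


def make_set(tracks):
    return TrajectorySet(pd.concat(tracks, ignore_index=True))


class TestFilter:
    @pytest.mark.parametrize("n_frames,kept", [(24, False), (25, True)])
    def test_strict_24_frame_boundary(self, n_frames, kept):
        tset = make_set([make_track([(i, 0) for i in range(n_frames)])])
        out = filter_trajectories(tset)
        assert (len(out) == 1) is kept

    def test_mixed_fixture_counts(self):
        tracks = [
            make_track([(i, 0) for i in range(n)], track_id=t)
            for t, n in enumerate(range(20, 30))
        ]
        out = filter_trajectories(make_set(tracks))
        assert len(out) == sum(1 for n in range(20, 30) if n > 24)


class TestVelocity:
    def test_stationary_track(self):
        assert instantaneous_velocity(make_track([(0, 0)] * 5)) == 0.0

    def test_one_um_per_min_along_x(self):
        track = make_track([(15.0 * i, 0.0) for i in range(5)])
        assert instantaneous_velocity(track) == pytest.approx(1.0)

    def test_diagonal_three_four_five(self):
        track = make_track([(0, 0), (3, 4), (6, 8)])
        assert instantaneous_velocity(track) == pytest.approx(5.0 / 15.0)

    def test_non_increasing_frames_rejected(self):
        track = make_track([(0, 0), (1, 0)])
        track.loc[1, "frame"] = 0
        with pytest.raises(ValueError):
            instantaneous_velocity(track)


class TestScaledDisplacement:
    def test_closed_loop_is_zero(self):
        track = make_track([(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)])
        assert scaled_displacement(track) == 0.0

    def test_straight_100_um_in_100_min(self):
        # frames every 15 min: 100 min is not a frame multiple, use 105 min (7 steps)
        track = make_track([(i * 15.0, 0.0) for i in range(8)])
        assert scaled_displacement(track) == pytest.approx(1.0)

    def test_never_exceeds_mean_velocity(self, rng):
        pts = np.cumsum(rng.normal(0, 5, (20, 2)), axis=0)
        track = make_track([tuple(p) for p in pts])
        assert scaled_displacement(track) <= instantaneous_velocity(track) + 1e-12


class TestStraightness:
    def test_straight_track(self):
        assert straightness_index(make_track([(0, 0), (1, 1), (2, 2)])) == pytest.approx(1.0)

    def test_out_and_back(self):
        assert straightness_index(make_track([(0, 0), (5, 0), (0, 0)])) == 0.0

    def test_l_shape_unit_steps(self):
        track = make_track([(0, 0), (1, 0), (1, 1)])
        assert straightness_index(track) == pytest.approx(np.sqrt(2) / 2)

    def test_zero_path_undefined(self):
        assert straightness_index(make_track([(0, 0), (0, 0)])) is None

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            pts = np.cumsum(rng.normal(0, 2, (10, 2)), axis=0)
            si = straightness_index(make_track([tuple(p) for p in pts]))
            assert 0.0 <= si <= 1.0


class TestNeighbors:
    def test_pair_within_radius(self):
        tset = make_set(
            [make_track([(0, 0)] * 3, 0), make_track([(20, 0)] * 3, 1)]
        )
        nn = mean_nearest_neighbors(tset)
        assert (nn["mean_neighbors"] == 1.0).all()

    def test_pair_outside_radius(self):
        tset = make_set(
            [make_track([(0, 0)] * 3, 0), make_track([(40, 0)] * 3, 1)]
        )
        nn = mean_nearest_neighbors(tset)
        assert (nn["mean_neighbors"] == 0.0).all()

    def test_collinear_triplet_at_25_um(self):
        tset = make_set(
            [make_track([(0, 0)] * 2, 0), make_track([(25, 0)] * 2, 1),
             make_track([(50, 0)] * 2, 2)]
        )
        nn = mean_nearest_neighbors(tset).set_index("track_id")["mean_neighbors"]
        assert nn[1] == 2.0 and nn[0] == 1.0 and nn[2] == 1.0


class TestComparisons:
    def test_shifted_distributions_strongly_significant(self):
        cfg = MotilityConfig(
            conditions={
                "WT": {"speed_um_min": 0.2, "persistence": 0.3, "n_cells": 100},
                "TGFb": {"speed_um_min": 1.0, "persistence": 0.3, "n_cells": 100},
            },
            n_frames=30,
            seed=0,
        )
        metrics = track_metrics(generate_trajectories(cfg))
        res = compare_conditions(metrics, metric_names=("velocity_um_min",))
        assert (res["p"] < 1e-6).all()

    def test_single_code_path_with_shared_mann_whitney(self):
        cfg = MotilityConfig(seed=1, n_frames=30)
        metrics = track_metrics(generate_trajectories(cfg))
        res = compare_conditions(metrics, metric_names=("straightness_index",))
        a = metrics[metrics["condition"] == "TGFb"]["straightness_index"].to_numpy()
        b = metrics[metrics["condition"] == "WT"]["straightness_index"].to_numpy()
        assert res["p"].iloc[0] == mann_whitney(a, b).p

    def test_higher_persistence_raises_straightness(self):
        cfg = MotilityConfig(
            conditions={
                "low": {"speed_um_min": 0.5, "persistence": 0.2, "n_cells": 100},
                "high": {"speed_um_min": 0.5, "persistence": 0.9, "n_cells": 100},
            },
            n_frames=40,
            seed=2,
        )
        metrics = track_metrics(generate_trajectories(cfg))
        med = metrics.groupby("condition")["straightness_index"].mean()
        assert med["high"] > med["low"]


class TestExpressionCorrelation:
    def test_monotone_and_reversed(self):
        conds = [f"c{i}" for i in range(8)]
        summary = pd.DataFrame(
            {"velocity_um_min": np.arange(8.0)}, index=pd.Index(conds, name="condition")
        )
        expr = pd.DataFrame(
            [np.arange(8.0), np.arange(8.0)[::-1]], index=["up", "down"], columns=conds
        )
        out = expression_motility_correlation(expr, summary).set_index("gene_id")
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        conds = [f"c{i}" for i in range(8)]
        metric = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0, 5.0])
        gene = np.array([2.0, 1.0, 1.0, 4.0, 5.0, 5.0, 6.0, 7.0])
        summary = pd.DataFrame({"m": metric}, index=pd.Index(conds, name="condition"))
        expr = pd.DataFrame([gene], index=["g"], columns=conds)
        out = expression_motility_correlation(expr, summary)
        assert out["rho"].iloc[0] == pytest.approx(midrank_spearman(gene, metric), abs=1e-12)

    def test_constant_gene_flagged_nan(self):
        conds = [f"c{i}" for i in range(8)]
        summary = pd.DataFrame({"m": np.arange(8.0)}, index=pd.Index(conds, name="condition"))
        expr = pd.DataFrame([[1.0] * 8], index=["g"], columns=conds)
        out = expression_motility_correlation(expr, summary)
        assert np.isnan(out["rho"].iloc[0])

    def test_condition_summary_median_vs_mean(self):
        cfg = MotilityConfig(seed=0, n_frames=26)
        metrics = track_metrics(generate_trajectories(cfg))
        med = condition_metric_summary(metrics, "median")
        mean = condition_metric_summary(metrics, "mean")
        assert set(med.index) == set(mean.index)
        assert not med.equals(mean)
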