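"""Core in-memory containers: the genes × contrasts expression table and trajectory sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrasts import CONTRASTS, LOGFC_COLUMNS, Q_COLUMNS

VALID_ANNOTATIONS = ("E", "M", "none")


class SchemaError(ValueError):
    """A table does not conform to the expected column schema."""


@dataclass
class ExpressionDataset:
    """Gene-level logFC and q-values over the eight perturbation contrasts.

    The central table of the pipeline.  ``table`` is indexed by unique
    ``gene_id`` and carries an ``annotation`` column (curated E / M label, or
    ``none`` for EMT genes without an explicit annotation), one
    ``logFC_<contrast>`` and one ``q_<contrast>`` column per contrast, and an
    optional ``class_truth`` column when the data are synthetic.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [
            c
            for c in ("annotation", *LOGFC_COLUMNS, *Q_COLUMNS)
            if c not in self.table.columns
        ]
        if missing:
            raise SchemaError(f"expression table is missing columns: {missing}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicated gene_id(s): {dups}")
        bad = set(self.table["annotation"]) - set(VALID_ANNOTATIONS)
        if bad:
            raise SchemaError(f"invalid annotation values: {sorted(bad)}")
        q = self.table[list(Q_COLUMNS)].to_numpy(float)
        if np.any((q < 0) | (q > 1)):
            raise SchemaError("q-values must lie in [0, 1]")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def logfc(self) -> pd.DataFrame:
        """genes × 8 logFC matrix with plain contrast names as columns."""
        out = self.table[list(LOGFC_COLUMNS)].copy()
        out.columns = list(CONTRASTS)
        return out

    @property
    def q(self) -> pd.DataFrame:
        out = self.table[list(Q_COLUMNS)].copy()
        out.columns = list(CONTRASTS)
        return out

    @property
    def annotation(self) -> pd.Series:
        return self.table["annotation"]

    @property
    def class_truth(self) -> pd.Series | None:
        return self.table.get("class_truth")

    def annotated(self) -> "ExpressionDataset":
        """Subset to genes carrying a curated E or M annotation."""
        return ExpressionDataset(self.table[self.table["annotation"] != "none"].copy())

    def emt_subset(self) -> "ExpressionDataset":
        """Subset to genes on the curated EMT list (the map is trained on these).

        Falls back to all genes when the table has no ``emt`` column (a table
        that only contains EMT genes needs no marker).
        """
        if "emt" not in self.table.columns:
            return self
        return ExpressionDataset(self.table[self.table["emt"].astype(bool)].copy())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TrajectorySet:
    """Per-cell 2-D trajectories across experimental conditions.

    Long-format table with columns ``condition``, ``track_id``, ``frame``,
    ``x_um``, ``y_um``; frames are acquired every ``frame_interval_min``
    minutes (15 by default).
    """

    table: pd.DataFrame = field(repr=False)
    frame_interval_min: float = 15.0

    REQUIRED = ("condition", "track_id", "frame", "x_um", "y_um")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"trajectory table is missing columns: {missing}")

    def tracks(self, condition: str | None = None):
        """Yield ``(condition, track_id, frame_sorted_dataframe)`` per track."""
        sub = self.table
        if condition is not None:
            sub = sub[sub["condition"] == condition]
        for (cond, tid), grp in sub.groupby(["condition", "track_id"], sort=True):
            yield cond, tid, grp.sort_values("frame")

    @property
    def conditions(self) -> list[str]:
        return sorted(self.table["condition"].unique())

    def __len__(self) -> int:
        return self.table.groupby(["condition", "track_id"]).ngroups
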