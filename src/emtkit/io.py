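"""Table readers/writers with schema validation, configuration and provenance.

TSV with header is the canonical exchange format (CSV is accepted on read);
contrast columns follow the fixed contrast order.  Every pipeline output
directory receives a provenance block (package version, seed, config hash)
sufficient to regenerate it exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .contrasts import LOGFC_COLUMNS, Q_COLUMNS
from .dataset import ExpressionDataset, SchemaError, TrajectorySet

#: fixed float format so identical runs produce byte-identical files
FLOAT_FORMAT = "%.10g"


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_expression_table(path) -> ExpressionDataset:
    """Read and validate a gene × contrasts logFC/q table (TSV or CSV)."""
    df = _read_table(path)
    if "gene_id" not in df.columns:
        raise SchemaError("expression table must have a gene_id column")
    missing = [c for c in ("annotation", *LOGFC_COLUMNS, *Q_COLUMNS) if c not in df.columns]
    if missing:
        raise SchemaError(f"expression table is missing columns: {missing}")
    return ExpressionDataset(df.set_index("gene_id"))


def write_expression_table(data: ExpressionDataset, path) -> None:
    data.table.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_trajectories(path, frame_interval_min: float = 15.0) -> TrajectorySet:
    return TrajectorySet(_read_table(path), frame_interval_min=frame_interval_min)


def write_trajectories(tset: TrajectorySet, path) -> None:
    tset.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_term_table(path) -> pd.DataFrame:
    """Two-column gene_id / term_id annotation table."""
    df = _read_table(path)
    missing = [c for c in ("gene_id", "term_id") if c not in df.columns]
    if missing:
        raise SchemaError(f"term table is missing columns: {missing}")
    return df


def read_survival_table(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [
        c
        for c in ("gene_id", "cluster", "survival_diff_months", "significant")
        if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"survival table is missing columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    pd.DataFrame(df).to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(config: dict) -> str:
    """Order-independent hash of a (nested) configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_provenance(out_dir, seed: int, config: dict) -> None:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    block = {
        "package": "emtkit",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(block, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
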