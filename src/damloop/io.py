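"""Readers and writers for the plain-text formats the toolkit exchanges.

BED output is 0-based half-open, matching the internal coordinate
convention.  Human-readable TSV reports are the only place 1-based
coordinates appear.
"""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed6(df: pd.DataFrame, path) -> None:
    """Write a BED6 file; missing name/score/strand columns are filled."""
    out = df.copy()
    if "name" not in out:
        out["name"] = [f"feature_{i}" for i in range(len(out))]
    if "score" not in out:
        out["score"] = 0
    if "strand" not in out:
        out["strand"] = "."
    out[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, names: list[str] | None = None) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name, ...])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = (names or cols)[: df.shape[1]]
    return df


def write_bedgraph(chroms, starts, ends, values, path, precision: int = 4) -> None:
    with open(path, "w") as fh:
        for c, s, e, v in zip(chroms, starts, ends, values):
            fh.write(f"{c}\t{s}\t{e}\t{v:.{precision}f}\n")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: Mapping, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")


def load_config(path) -> dict:
    """Load a flat key-value YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"configuration in {path} must be a mapping")
    return cfg
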