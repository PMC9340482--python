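"""Tabular and FASTA I/O with schema checking and atomic writes.

Canonical tabular dialect: tab-separated, UTF-8, '.' decimal, with a
header row.  All writers go through a temp-file + rename so a crashed
run never leaves a truncated output behind.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_table", "write_table", "atomic_write", "write_json"]

# column -> dtype schemas for the formats the package consumes
SCHEMAS = {
    "half_life": {"gene_id": str, "half_life_min": float},
    "codon_weights": {"codon": str, "value": float},
    "decay": {"gene": str, "genotype": str, "replicate": str,
              "time_min": float, "rel_expr": float},
    "qpcr": {"sample_id": str, "target": str, "ct": float,
             "efficiency": float, "role": str},
    "cells": {"cell_id": str, "image_id": str, "replicate_id": str,
              "genotype": str, "length": float, "count_whole": int,
              "count_cyto": int, "count_nuc": int},
    "spots": {"cell_id": str, "channel": str, "x": float, "y": float,
              "z": float, "intensity": float},
}


@contextmanager
def atomic_write(path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_table(path, schema: str | dict) -> pd.DataFrame:
    """Read a TSV into a typed DataFrame, validating required columns.

    ``schema`` is a name from ``SCHEMAS`` or a column->dtype mapping.
    Extra columns are tolerated (and logged); a missing required column
    raises an error naming it; 'NA' in a numeric column becomes NaN and
    the affected rows are flagged in the log, never silently zeroed.
    """
    cols = SCHEMAS[schema] if isinstance(schema, str) else dict(schema)
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", "NaN", ""])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in cols]
    if extra:
        logger.info("%s: extra columns tolerated: %s", path, ", ".join(extra))
    for c, dtype in cols.items():
        if dtype in (float, int):
            vals = pd.to_numeric(df[c], errors="coerce")
            n_missing = int(vals.isna().sum())
            if n_missing:
                logger.warning("%s: column %s has %d missing value(s)",
                               path, c, n_missing)
            if dtype is int and not vals.isna().any():
                vals = vals.astype(int)
            df[c] = vals
        else:
            df[c] = df[c].astype(str)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    with atomic_write(path) as fh:
        json.dump(_jsonify(obj), fh, indent=2)
        fh.write("\n")
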