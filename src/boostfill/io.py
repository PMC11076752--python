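"""Table I/O, run manifests, and output writing.

Tables are CSV/TSV with a header row and a sample-identifier index column;
cells are read as text and typed downstream by the preprocessing rules.
Numeric output is written with up to 12 significant digits and without
scientific notation for integer values.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _infer_delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def read_table(
    path: str | Path, delimiter: str | None = None, index_column: int = 0
) -> pd.DataFrame:
    """Read a CSV/TSV into a text-celled DataFrame with the sample-id index.

    The delimiter is inferred from the extension (``.tsv``/``.tab``/``.txt``
    are tab-separated) unless given.  Duplicate header names or duplicate
    row identifiers raise an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = delimiter or _infer_delimiter(path)
    # pandas mangles duplicate headers (a, a.1); check the raw header line
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    names = header[:index_column] + header[index_column + 1 :]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate column headers: {dupes}")
    df = pd.read_csv(
        path,
        sep=sep,
        index_col=index_column,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=False,
    )
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate column headers: {dupes}")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()].astype(str)))
        raise ValueError(f"duplicate row identifiers: {dupes}")
    return df


def format_number(value: float, sig_digits: int = 12) -> str:
    """Up to 12 significant digits; integers without scientific notation."""
    if value != value:  # NaN
        return ""
    if math.isfinite(value) and float(value) == int(value) and abs(value) < 1e15:
        return str(int(value))
    return f"{value:.{sig_digits}g}"


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        values = out[col].to_numpy(dtype=object, copy=True)
        for i, v in enumerate(values):
            if isinstance(v, (float, int, np.floating, np.integer)) and not isinstance(v, bool):
                values[i] = format_number(float(v))
            elif v is None:
                values[i] = ""
        out[col] = values
    return out


def write_outputs(result, out_dir: str | Path, input_path: str | None = None) -> dict[str, Path]:
    """Write imputed_clean.csv, imputed_encoded.csv and manifest.json.

    Categorical cells appear as their original text in the clean output;
    excluded columns pass through verbatim.  The manifest echoes the full
    configuration and seeds so a run can be reproduced bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clean": out_dir / "imputed_clean.csv",
        "encoded": out_dir / "imputed_encoded.csv",
        "manifest": out_dir / "manifest.json",
    }
    _format_frame(result.imputed_clean).to_csv(paths["clean"])
    _format_frame(result.imputed_encoded).to_csv(paths["encoded"])

    from . import __version__

    config = result.config
    manifest = {
        "version": __version__,
        "input": input_path,
        "master_seed": config.master_seed if config else None,
        "config": {
            **({k: v for k, v in asdict(config).items() if k != "factorization"} if config else {}),
            "factorization": asdict(config.factorization) if config else None,
        },
        "excluded_columns": result.excluded_columns,
        "column_profiles": {
            name: {
                "inferred_type": p.inferred_type,
                "n_missing": int(p.missing_mask.sum()),
                "n_coerced": int(p.n_coerced),
                "n_categories": len(p.category_map) if p.category_map else None,
            }
            for name, p in result.profiles.items()
        },
        "records": {
            name: {
                "learner": r.learner,
                "tuned": r.tuned,
                "n_models": r.n_models,
                "fallback_reason": r.fallback_reason,
                "params": asdict(r.params),
            }
            for name, r in result.records.items()
        },
        "per_iteration_change": result.per_iteration_change,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("outputs written to %s", out_dir)
    return paths
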