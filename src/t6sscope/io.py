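"""Small TSV/JSON I/O helpers shared by the pipeline stages."""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import pandas as pd


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"required input file not found: {path}")
    return pd.read_csv(path, sep="\t", **kwargs)


def _round_floats(obj, sig: int = 10):
    """Round every float to ``sig`` significant digits (hash stability)."""
    if isinstance(obj, float):
        if obj == 0 or not math.isfinite(obj):
            return obj
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True,
                               default=str) + "\n")
    return path


def report_hash(report: dict) -> str:
    """Stable content hash of a report (floats at 10 significant digits)."""
    payload = json.dumps(_round_floats(report), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()
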