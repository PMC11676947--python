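"""Delimited-text writers, run manifests and coefficient files.

Every tabular output is plain columnar text with '#' header metadata; every
run writes a JSON manifest (tool version, arguments, seeds, checksums) that
suffices to regenerate the output exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .transfer import COEFF_NAMES, TFCoefficients

__all__ = [
    "write_table",
    "read_table",
    "write_raster",
    "write_coefficients",
    "read_coefficients",
    "write_manifest",
    "sha256_of",
]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Tab-separated table with '#'-prefixed metadata header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_raster(path, raster, meta: dict | None = None) -> None:
    """Two-column (neuron_id, spike_time_ms) raster export."""
    rows = raster.to_rows()
    df = pd.DataFrame(rows, columns=["neuron_id", "spike_time_ms"])
    df["neuron_id"] = df["neuron_id"].astype(int)
    base = {"duration_ms": raster.duration, "dt_ms": raster.dt}
    base.update({f"pop_{k}": f"{lo}:{hi}" for k, (lo, hi) in raster.populations.items()})
    base.update(meta or {})
    write_table(path, df, base)


def write_coefficients(path, coeffs: TFCoefficients, meta: dict | None = None) -> None:
    df = pd.DataFrame([coeffs.P], columns=list(COEFF_NAMES))
    df.insert(0, "cell", coeffs.cell or "?")
    base = dict(coeffs.norm)
    base.update(meta or {})
    write_table(path, df, base)


def read_coefficients(path, cell: str | None = None) -> TFCoefficients:
    df = read_table(path)
    if cell is not None and "cell" in df.columns:
        df = df[df["cell"] == cell]
    row = df.iloc[0]
    return TFCoefficients(P=row[list(COEFF_NAMES)].to_numpy(dtype=float),
                          cell=str(row.get("cell", "")))


def write_manifest(path, args: dict, outputs, seed=None) -> dict:
    """JSON manifest: version, arguments, seed, output checksums, wall time."""
    manifest = {
        "tool": "thalmf",
        "version": __version__,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": seed,
        "args": {k: _jsonable(v) for k, v in args.items() if not callable(v)},
        "outputs": {str(p): sha256_of(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    return v
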