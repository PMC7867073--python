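"""Reading and writing spectral CSV tables and fitted-model JSON files.

CSV dialect (wide): one row per sample with header
``sample_id,temperature_C,salinity_psu,nitrate_umol_L,A_<wl>,...`` where the
wavelength in each absorbance column name is printed to three decimals
(``A_210.400``).  ``nitrate_umol_L`` may be empty for unlabeled samples.

Models are stored one per JSON file, self-describing with a schema version,
so a fitted pipeline can be re-applied bit-identically in a later session.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import SampleTable

__all__ = ["read_table", "write_table", "save_model", "load_model", "ParseError"]

SCHEMA_VERSION = 1

_META_COLS = ["sample_id", "temperature_C", "salinity_psu", "nitrate_umol_L"]


class ParseError(ValueError):
    """Malformed table or model file."""


def write_table(table: SampleTable, path) -> None:
    """Write a :class:`SampleTable` as wide CSV (lossless to full precision)."""
    cols = {
        "sample_id": table.sample_ids,
        "temperature_C": table.temperature,
        "salinity_psu": table.salinity,
        "nitrate_umol_L": table.reference_conc,
    }
    wl_cols = pd.DataFrame(
        table.absorbance,
        columns=[f"A_{wl:.3f}" for wl in table.wavelengths],
    )
    df = pd.concat([pd.DataFrame(cols), wl_cols], axis=1)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> SampleTable:
    """Read a wide spectral CSV into a :class:`SampleTable`.

    Raises :class:`ParseError` naming the missing column or the first
    non-numeric cell (row/column) on malformed input.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"sample_id": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in ("sample_id", "temperature_C", "salinity_psu"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    wl_cols = [c for c in df.columns if c.startswith("A_")]
    if not wl_cols:
        raise ParseError(f"{path}: no absorbance columns (prefix 'A_')")
    try:
        wavelengths = np.array([float(c[2:]) for c in wl_cols])
    except ValueError as exc:
        raise ParseError(f"{path}: malformed wavelength column name: {exc}") from exc
    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    wl_cols = [wl_cols[i] for i in order]

    numeric = ["temperature_C", "salinity_psu", *wl_cols]
    if "nitrate_umol_L" in df.columns:
        numeric.append("nitrate_umol_L")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {df[col][row]!r} "
                f"in column {col!r}, row {row}"
            )
        df[col] = coerced
    if df[wl_cols].isna().any().any():
        raise ParseError(f"{path}: missing absorbance values")

    ref = (
        df["nitrate_umol_L"].to_numpy(float)
        if "nitrate_umol_L" in df.columns
        else np.full(len(df), np.nan)
    )
    return SampleTable(
        sample_ids=list(df["sample_id"]),
        wavelengths=wavelengths,
        absorbance=df[wl_cols].to_numpy(float),
        temperature=df["temperature_C"].to_numpy(float),
        salinity=df["salinity_psu"].to_numpy(float),
        reference_conc=ref,
    )


# --- model serialization -------------------------------------------------

def _registry():
    # local import avoids circular imports at module load
    from .tsc import LNSModel, TSCModel
    from .kpls import KPLSModel
    from .ensemble import EnsembleModel
    from .comparators import MLRModel, ISUSModel

    return {
        cls.__name__: cls
        for cls in (LNSModel, TSCModel, KPLSModel, EnsembleModel, MLRModel, ISUSModel)
    }


def save_model(model, path) -> None:
    """Serialize a fitted model to a self-describing JSON file."""
    name = type(model).__name__
    if name not in _registry():
        raise ParseError(f"unknown model type {name!r}")
    doc = {
        "schema_version": SCHEMA_VERSION,
        "model_type": name,
        "payload": model.to_dict(),
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path):
    """Load a model JSON written by :func:`save_model`."""
    doc = json.loads(Path(path).read_text())
    for key in ("schema_version", "model_type", "payload"):
        if key not in doc:
            raise ParseError(f"{path}: not a model file (missing {key!r})")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ParseError(
            f"{path}: unsupported schema version {doc['schema_version']}"
        )
    reg = _registry()
    cls = reg.get(doc["model_type"])
    if cls is None:
        raise ParseError(f"{path}: unknown model type {doc['model_type']!r}")
    return cls.from_dict(doc["payload"])
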