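"""Readers and writers: IVGTT CSV tables and parameter files (YAML/JSON).

One tabular interchange format (CSV with unit-bearing column names) and one
parameter format (YAML or JSON keyed by the model's symbol names) are used
everywhere, so a file produced by any subcommand can be consumed by any
other.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model_core import DelayModelParameters, MinimalModelParameters

__all__ = [
    "read_ivgtt_csv",
    "write_ivgtt_csv",
    "read_params",
    "write_params",
    "DELAY_KEYS",
    "MINIMAL_KEYS",
]

TIME_COL = "time_min"
G_COL = "glucose_mg_dl"
I_COL = "insulin_uU_ml"
F_COL = "ffa_uM"
PRE_BOLUS_COL = "pre_bolus"

DELAY_KEYS = (
    "S_i", "S_g", "hepatic_input", "d_i", "sigma1", "sigma2", "alpha",
    "sigma", "gamma", "beta", "g0", "g1", "I2", "kappa", "d_f", "tau",
)
MINIMAL_KEYS = ("S_G", "S_I", "c_X", "l0", "l2", "X2", "A", "c_f", "G_b", "I_b")



def read_ivgtt_csv(path):
    """Read and validate an IVGTT dataset CSV.

    Required columns: time_min, glucose_mg_dl, insulin_uU_ml; ffa_uM is
    optional (its absence disables FFA fitting, flagged on the dataset).
    Times must be strictly increasing and all concentrations positive;
    errors name the offending (1-based, header-exclusive) row.
    """
    from .synthetic_data import IVGTTDataset  # local import: avoid cycle

    path = Path(path)
    df = pd.read_csv(path)
    required = [TIME_COL, G_COL, I_COL]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    has_ffa = F_COL in df.columns
    value_cols = [G_COL, I_COL] + ([F_COL] if has_ffa else [])
    for col in [TIME_COL] + value_cols:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric value in column {col!r} at row {bad[0] + 1}")
        df[col] = pd.to_numeric(df[col])
    t = df[TIME_COL].to_numpy(dtype=float)
    dup = np.where(np.diff(t) == 0)[0]
    if dup.size:
        raise ValueError(f"{path}: duplicate time at row {dup[0] + 2}")
    nonmono = np.where(np.diff(t) < 0)[0]
    if nonmono.size:
        raise ValueError(f"{path}: times not increasing at row {nonmono[0] + 2}")
    for col in value_cols:
        v = df[col].to_numpy(dtype=float)
        bad = np.where(v <= 0)[0]
        if bad.size:
            raise ValueError(f"{path}: nonpositive {col} at row {bad[0] + 1}")
    pre = (
        df[PRE_BOLUS_COL].astype(bool).to_numpy()
        if PRE_BOLUS_COL in df.columns
        else t < 0
    )
    return IVGTTDataset(
        times=t,
        G=df[G_COL].to_numpy(dtype=float),
        I=df[I_COL].to_numpy(dtype=float),
        F=df[F_COL].to_numpy(dtype=float) if has_ffa else None,
        pre_bolus=pre,
        group=None,
        truth=None,
        seed=None,
    )


def write_ivgtt_csv(dataset, path, sidecar: bool = True) -> None:
    """Write a dataset as CSV; optionally a JSON sidecar with truth + seed."""
    path = Path(path)
    cols = {TIME_COL: dataset.times, G_COL: dataset.G, I_COL: dataset.I}
    if dataset.F is not None:
        cols[F_COL] = dataset.F
    cols[PRE_BOLUS_COL] = dataset.pre_bolus.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)
    if sidecar and (dataset.truth is not None or dataset.seed is not None):
        from . import __version__

        meta = {"group": dataset.group, "seed": dataset.seed,
                "glifa_version": __version__, "truth": dataset.truth}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _load_mapping(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names to values")
    return data


def read_params(path, model: str):
    """Read a parameter file into the typed parameter object for ``model``.

    The file must contain exactly the keys of the chosen model (symbol
    names as in the model definitions); missing or unknown keys are
    reported by name, and the type's own invariants are enforced.
    """
    path = Path(path)
    if model not in ("delay", "minimal"):
        raise ValueError(f"unknown model {model!r}; expected 'delay' or 'minimal'")
    keys = DELAY_KEYS if model == "delay" else MINIMAL_KEYS
    data = _load_mapping(path)
    missing = [k for k in keys if k not in data]
    if missing:
        raise ValueError(f"{path}: missing parameter key(s) {missing}")
    unknown = [k for k in data if k not in keys]
    if unknown:
        raise ValueError(f"{path}: unknown parameter key(s) {unknown}")
    values = {k: float(data[k]) for k in keys}
    cls = DelayModelParameters if model == "delay" else MinimalModelParameters
    return cls(**values)


def write_params(params, path) -> None:
    """Write a parameter object to YAML or JSON (by file extension)."""
    path = Path(path)
    if isinstance(params, DelayModelParameters):
        order = DELAY_KEYS
    elif isinstance(params, MinimalModelParameters):
        order = MINIMAL_KEYS
    else:
        raise TypeError(f"unsupported parameter type {type(params).__name__}")
    data = {k: getattr(params, k) for k in order}
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
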