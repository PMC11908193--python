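"""Configuration, provenance and fixed-dialect CSV/JSON helpers.

All CSV output uses comma separators, dot decimals, a header row and
UTF-8.  JSON reports are schema-versioned and carry a provenance block
(configuration hash, seed, package version) so any run can be traced.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .errors import DataError

SCHEMA_VERSION = 1


def _canonical_json(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"),
                      default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.bool_,)):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def config_hash(config: dict) -> str:
    return hashlib.sha256(_canonical_json(config).encode()).hexdigest()


def provenance_block(config: dict, seed: int | None) -> dict:
    from . import __version__
    return {
        "schema_version": SCHEMA_VERSION,
        "config_sha256": config_hash(config),
        "seed": seed,
        "package_version": __version__,
    }


def write_report(path, payload: dict, config: dict,
                 seed: int | None = None) -> dict:
    """Write a JSON report with a provenance block; returns the document."""
    doc = {"provenance": provenance_block(config, seed), **payload}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return doc


def load_config(path, allowed_keys: set[str]) -> dict:
    """Load a JSON run configuration, rejecting unknown keys."""
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise DataError("config must be a JSON object")
    unknown = set(cfg) - allowed_keys - {"schema_version"}
    if unknown:
        raise DataError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def write_yield_curve(df: pd.DataFrame, path) -> None:
    """Yield curve CSV with columns b0_mT, phi_s, phi_t, phi_relax."""
    cols = ["b0_mT", "phi_s", "phi_t", "phi_relax"]
    missing = set(cols) - set(df.columns)
    if missing:
        raise DataError(f"yield curve missing columns {sorted(missing)}")
    df[cols].to_csv(path, index=False)


def write_trace(t_s, b1_mt, f_rel, path) -> None:
    """Time-trace CSV with columns t_s, b1_mT, f_rel."""
    pd.DataFrame({"t_s": t_s, "b1_mT": b1_mt, "f_rel": f_rel}).to_csv(
        path, index=False)


def read_trace(path):
    df = pd.read_csv(path)
    if not {"t_s", "f_rel"} <= set(df.columns):
        raise DataError("trace CSV needs columns t_s, f_rel")
    return df
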