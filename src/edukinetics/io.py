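"""CSV/JSON readers and writers, run configuration, and run manifests.

File conventions: UTF-8 CSV with mandatory headers and '.' decimal
separator; raw data files store counts, derived files store percentages
with 4 significant digits; times are plain decimal hours. Every
artifact-producing command writes a JSON manifest (config echo, package
version, timestamp, SHA-256 digests of inputs and outputs) from which a run
can be replayed byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .errors import ValidationError
from .kinetics import KineticEstimate
from .synthdata import CURVE_COLUMNS, validate_curve

__all__ = [
    "SCHEMA_VERSION",
    "read_labeling_csv",
    "write_labeling_csv",
    "read_marker_csv",
    "write_marker_csv",
    "read_ct_csv",
    "write_ct_csv",
    "estimate_to_dict",
    "estimates_to_frame",
    "validate_config",
    "write_manifest",
    "sha256_file",
]

SCHEMA_VERSION = "1"

MARKER_COLUMNS = ("condition", "marker", "replicate", "field", "n_pos", "n_total")
CT_COLUMNS = ("sample", "condition", "bio_rep", "tech_rep", "gene", "ct")


def _read_csv(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path} is empty or has no header")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path} is missing columns {missing}")
    for col in columns:
        bad = df[df[col].isna()]
        if len(bad):
            raise ValidationError(
                f"{path}: missing value in column {col!r} at data line {bad.index[0] + 2}"
            )
    return df


def read_labeling_csv(path: str | Path) -> pd.DataFrame:
    return validate_curve(_read_csv(path, CURVE_COLUMNS))


def write_labeling_csv(curve: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_curve(curve)
    curve.to_csv(path, index=False, encoding="utf-8")
    return path


def read_marker_csv(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, MARKER_COLUMNS)


def write_marker_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, encoding="utf-8")
    return path


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path, CT_COLUMNS)
    if (df["ct"] <= 0).any():
        line = df[df["ct"] <= 0].index[0] + 2
        raise ValidationError(f"{path}: non-positive Ct at data line {line}")
    return df


def write_ct_csv(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# estimates
# ---------------------------------------------------------------------------


def estimate_to_dict(est: KineticEstimate, condition: str = "") -> dict[str, Any]:
    return {
        "condition": condition,
        "method": est.method,
        "gf_hat": est.gf_hat,
        "ts_hat": est.ts_hat,
        "tc_hat": est.tc_hat,
        "tsat_hat": est.tsat_hat,
        "ci_ts_lo": est.ci_ts[0],
        "ci_ts_hi": est.ci_ts[1],
        "ci_tc_lo": est.ci_tc[0],
        "ci_tc_hi": est.ci_tc[1],
        "ci_gf_lo": est.ci_gf[0],
        "ci_gf_hi": est.ci_gf[1],
        "n_boot": est.n_boot,
    }


def estimates_to_frame(estimates: Mapping[str, KineticEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [estimate_to_dict(est, cond) for cond, est in estimates.items()]
    )


# ---------------------------------------------------------------------------
# configuration and manifests
# ---------------------------------------------------------------------------


def validate_config(
    config: Mapping[str, Any],
    required: tuple[str, ...],
    optional: tuple[str, ...] = (),
) -> dict[str, Any]:
    """Strict flat-config validation: required keys present, unknown keys
    rejected. ``schema_version`` is always accepted and checked."""
    cfg = dict(config)
    version = str(cfg.pop("schema_version", SCHEMA_VERSION))
    if version != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION!r})"
        )
    unknown = sorted(set(cfg) - set(required) - set(optional))
    if unknown:
        raise ValidationError(f"unknown config keys: {unknown}")
    missing = sorted(set(required) - set(cfg))
    if missing:
        raise ValidationError(f"missing config keys: {missing}")
    cfg["schema_version"] = version
    return cfg


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: Mapping[str, Any],
    outputs: list[str | Path],
    inputs: list[str | Path] | None = None,
) -> Path:
    from . import __version__

    path = Path(path)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": dict(config),
        "inputs": {str(p): sha256_file(p) for p in (inputs or [])},
        "outputs": {str(p): sha256_file(p) for p in outputs},
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")
    return path
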