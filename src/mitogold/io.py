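"""Table schemas, configuration and run manifests.

All tables are UTF-8 CSV with a required header, comma separators and "."
decimals.  Schemas are declared as ordered column -> dtype maps; reading
validates the header and cell types and reports failures with row and
column context.  Configuration files are YAML (JSON is a YAML subset and
therefore also accepted); unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "PROFILES_SCHEMA",
    "POINTS_SCHEMA",
    "DISTANCES_SCHEMA",
    "DENSITIES_SCHEMA",
    "SUMMARY_SCHEMA",
    "TIMECOURSE_SCHEMA",
    "SPECTRUM_SCHEMA",
    "RATES_SCHEMA",
    "RunConfig",
    "RunManifest",
    "read_table",
    "write_table",
    "write_report",
    "load_config",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


# column -> dtype ("str", "float", "int"); order is the canonical file order
PROFILES_SCHEMA = {
    "profile_id": "str",
    "field_id": "str",
    "cx_nm": "float",
    "cy_nm": "float",
    "semi_major_nm": "float",
    "semi_minor_nm": "float",
    "theta_rad": "float",
    "membrane_inset_nm": "float",
}
POINTS_SCHEMA = {
    "point_id": "str",
    "field_id": "str",
    "profile_id": "str",
    "label": "str",
    "kind": "str",
    "x_nm": "float",
    "y_nm": "float",
    "diameter_nm": "float",
}
DISTANCES_SCHEMA = {
    "point_id": "str",
    "label": "str",
    "kind": "str",
    "profile_id": "str",
    "distance_nm": "float",
}
DENSITIES_SCHEMA = {
    "label": "str",
    "compartment": "str",
    "experiment_id": "str",
    "gold_count": "int",
    "area_um2": "float",
    "density_per_um2": "float",
}
SUMMARY_SCHEMA = {
    "label": "str",
    "compartment": "str",
    "mean": "float",
    "sem": "float",
    "n": "int",
}
TIMECOURSE_SCHEMA = {"t_s": "float", "cd_mdeg": "float"}
SPECTRUM_SCHEMA = {"field_mT": "float", "signal": "float"}
RATES_SCHEMA = {
    "reaction_id": "str",
    "condition": "str",
    "slope_mdeg_per_min": "float",
    "r2": "float",
    "relative_pct": "float",
}

_DTYPES = {"str": str, "float": float, "int": int}


def read_table(path: str | Path, schema: dict[str, str]) -> pd.DataFrame:
    """Read and validate a CSV table against ``schema``.

    Raises :class:`SchemaError` naming the offending column (and row for
    cell-level failures).  Trailing blank lines are tolerated.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file (missing header)") from None
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in schema]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s) {extra}")
    out = {}
    for col, kind in schema.items():
        if kind == "str":
            out[col] = df[col]
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header line
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}, line {row}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0]) + 2
            raise SchemaError(f"{path}: empty cell in column {col!r}, line {row}")
        out[col] = converted.astype(_DTYPES[kind])
    return pd.DataFrame(out, columns=list(schema))


def write_table(df: pd.DataFrame, path: str | Path, schema: dict[str, str]) -> None:
    """Write a table in canonical column order; round-trips via read_table."""
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {path}: missing column(s) {missing}")
    df[list(schema)].to_csv(path, index=False)


def write_report(report: dict, path: str | Path) -> None:
    """Deterministically ordered JSON report."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Defaults reproduce the study parameters: grid spacings 15.5 nm
    (mitosome) and 206.1 nm (cytoplasm/nucleus), a 20-nm matrix band,
    a 4.5-min initial-rate window, and the published per-protein gold
    counts via the synthetic generator's defaults.
    """

    out_dir: str = "mitogold_out"
    rng_seed: int = 0
    log_level: str = "INFO"
    # synthetic field
    n_fields: int = 3
    profiles_per_field: int = 8
    membrane_inset_nm: float = 15.0
    gold_law: str = "membrane_proximal"
    gold_scale_nm: float = 10.0
    counts_per_label: dict | None = None
    # stereology
    grid_spacing_mitosome_nm: float = 15.5
    grid_spacing_cyto_nucleus_nm: float = 206.1
    # membrane statistics
    band_width_nm: float = 20.0
    bin_edges_nm: tuple = tuple(float(e) for e in range(-40, 61, 10))
    # kinetics
    rate_window_min: float = 4.5
    # EPR
    epr_frequency_GHz: float = 9.6359
    epr_g_values: tuple = (1.89, 1.92, 2.05)
    epr_linewidths_mT: tuple = (2.0, 2.0, 2.0)
    epr_field_range_mT: tuple = (300.0, 380.0)
    epr_n_field_points: int = 4096

    def config_hash(self) -> str:
        """Hash over the scientific parameters (output path and logging
        excluded, so relocated runs stay comparable)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload.pop("log_level")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise SchemaError(f"{path}: unknown config key(s) {unknown}")
    for key in ("bin_edges_nm", "epr_g_values", "epr_linewidths_mT", "epr_field_range_mT"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record of a pipeline run."""

    tool_version: str
    config_hash: str
    input_hashes: dict
    seed: int
    timestamp_utc: str

    def manifest_hash(self) -> str:
        """Hash over config, inputs and seed (timestamp excluded), so
        identical runs have identical manifest hashes."""
        payload = json.dumps(
            dict(
                tool_version=self.tool_version,
                config_hash=self.config_hash,
                input_hashes=self.input_hashes,
                seed=self.seed,
            ),
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["manifest_hash"] = self.manifest_hash()
        return d
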