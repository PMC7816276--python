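"""Configuration files, run manifests and numeric output writers.

The configuration is a single YAML document with three optional top-level
sections::

    parameters:      # any ModelParameters field
      K_DOC: 60.0
      luxury_uptake_B: false
    integration:     # any IntegrationSettings field
      dt: 0.02
      t_end: 35.0
    experiment:      # free-form overrides consumed by the CLI
      steps: 41

An empty (or absent) file resolves to the full default parameter set.
Unknown keys are rejected, naming every offending key.  There is no
random number generator anywhere in the package: identical configs
produce byte-identical numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import STATE_NAMES, STATE_UNITS
from .integrate import IntegrationSettings, TimeSeries
from .params import ModelParameters

_SECTIONS = ("parameters", "integration", "experiment")


class ConfigError(ValueError):
    """Raised with a message listing every failing key."""


def load_config(path: str | Path | None
                ) -> tuple[ModelParameters, IntegrationSettings, dict]:
    """Parse a YAML config into parameters, settings and CLI overrides.

    Defaults are applied for every absent key; validation errors are
    accumulated and reported together.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    errors: list[str] = []
    unknown_sections = sorted(set(raw) - set(_SECTIONS))
    for key in unknown_sections:
        errors.append(f"unknown section {key!r} (expected one of {_SECTIONS})")

    pdict = dict(raw.get("parameters") or {})
    unknown = sorted(set(pdict) - set(ModelParameters.field_names()))
    for key in unknown:
        errors.append(f"unknown parameter key {key!r}")
    for key in unknown:
        pdict.pop(key)
    params = None
    try:
        params = ModelParameters(**pdict)
    except (ValueError, TypeError) as exc:
        errors.append(str(exc))

    idict = dict(raw.get("integration") or {})
    known_settings = {f.name for f in dataclasses.fields(IntegrationSettings)}
    unknown = sorted(set(idict) - known_settings)
    for key in unknown:
        errors.append(f"unknown integration key {key!r}")
    for key in unknown:
        idict.pop(key)
    settings = None
    try:
        settings = IntegrationSettings(**idict)
    except (ValueError, TypeError) as exc:
        errors.append(str(exc))

    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))
    return params, settings, dict(raw.get("experiment") or {})


def config_hash(params: ModelParameters, settings: IntegrationSettings,
                extra: dict | None = None) -> str:
    """SHA-256 over the canonical JSON of the fully resolved configuration."""
    doc = {"parameters": params.to_dict(),
           "integration": dataclasses.asdict(settings),
           "experiment": extra or {}}
    blob = json.dumps(doc, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def make_manifest(params: ModelParameters, settings: IntegrationSettings,
                  run_id: str, extra: dict | None = None,
                  started: str | None = None) -> dict:
    return {
        "run_id": run_id,
        "software_version": __version__,
        "config_hash": config_hash(params, settings, extra),
        "parameters": params.to_dict(),
        "integration": dataclasses.asdict(settings),
        "experiment": extra or {},
        "started_utc": started or datetime.now(timezone.utc).isoformat(),
        "finished_utc": datetime.now(timezone.utc).isoformat(),
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _units_header(columns: list[str]) -> list[str]:
    units = dict(zip(STATE_NAMES, STATE_UNITS))
    units.update({
        "t_days": "days", "cum_Fe_uptake_P": "nmol Fe/L",
        "cum_Fe_uptake_B": "nmol Fe/L", "Fe": "nmol Fe/L",
        "PAR": "W/m2", "DOC": "umol C/L",
        "mu_P": "1/d", "mu_B": "1/d", "C_fix": "umol C/L/d",
        "exud_flux": "umol C/L/d", "DOC_uptake": "umol C/L/d",
        "respiration": "umol C/L/d", "Fe_uptake_P": "nmol Fe/L/d",
        "Fe_uptake_B": "nmol Fe/L/d", "mort_P": "umol C/L/d",
        "mort_B": "umol C/L/d", "Q_P": "umol Fe/mol C",
        "Q_B": "umol Fe/mol C",
    })
    return [units.get(c, "-") for c in columns]


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    """CSV with a units row under the header; floats at full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(df.columns) + "\n")
        fh.write(",".join(_units_header(list(df.columns))) + "\n")
        df.to_csv(fh, index=False, header=False, float_format="%.17g")


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read back a units-row CSV written by :func:`write_csv`."""
    return pd.read_csv(path, skiprows=[1], float_precision="round_trip")


def write_grid_netcdf(grid, path: str | Path) -> None:
    """Self-describing array container with named axes (netCDF-3)."""
    ds = grid.to_xarray()
    ds.to_netcdf(str(path), engine="scipy")


def open_grid_dataset(path: str | Path):
    import xarray as xr
    return xr.open_dataset(str(path), engine="scipy")
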