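"""Table and configuration file handling.

The interchange format is TSV throughout: an abundance table is a
samples x taxa matrix with sample ids in the first column and taxon ids
in the header row, with optional sidecar TSVs for sample and species
metadata.  Scenario configurations are YAML with strict key checking.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from .sampling import load_pool, save_pool
from .scenarios import AbundanceTable, ScenarioConfig

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "load_config",
    "dump_config",
    "write_manifest",
]


class TableFormatError(ValueError):
    """Raised when an abundance table file is malformed."""


def read_abundance_table(path) -> AbundanceTable:
    """Read an abundance table from a TSV file or a directory.

    A directory is expected to contain ``abundances.tsv`` plus optional
    ``samples.tsv`` / ``species.tsv`` metadata and a ``pool/``
    subdirectory.  A single TSV file yields a table with minimal
    metadata (all samples marked converged).
    """
    path = pathlib.Path(path)
    if path.is_dir():
        values = _read_matrix(path / "abundances.tsv")
        meta_path = path / "samples.tsv"
        if meta_path.exists():
            sample_meta = pd.read_csv(meta_path, sep="\t", index_col=0)
            sample_meta.index = sample_meta.index.astype(str)
        else:
            sample_meta = _default_sample_meta(values)
        species_path = path / "species.tsv"
        if species_path.exists():
            species_meta = pd.read_csv(species_path, sep="\t", index_col=0)
            species_meta.index = species_meta.index.astype(str)
        else:
            species_meta = pd.DataFrame(
                {"family": ["unknown"] * values.shape[1]},
                index=pd.Index(values.columns, name="species"),
            )
        pool = load_pool(path / "pool") if (path / "pool").is_dir() else None
        supply_path = path / "supply.tsv"
        supply = None
        if supply_path.exists():
            supply = pd.read_csv(supply_path, sep="\t", index_col=0, float_precision="round_trip")
            supply.index = supply.index.astype(str)
            supply = supply.loc[values.index]
        if "converged" not in sample_meta.columns:
            sample_meta["converged"] = True
        return AbundanceTable(
            values=values, sample_meta=sample_meta.loc[values.index],
            species_meta=species_meta.loc[values.columns], pool=pool, supply=supply,
        )
    values = _read_matrix(path)
    return AbundanceTable(
        values=values,
        sample_meta=_default_sample_meta(values),
        species_meta=pd.DataFrame(
            {"family": ["unknown"] * values.shape[1]},
            index=pd.Index(values.columns, name="species"),
        ),
        pool=None,
    )


def _read_matrix(path: pathlib.Path) -> pd.DataFrame:
    if not path.exists():
        raise TableFormatError(f"{path}: file not found")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        n_cols = len(header)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n_cols:
                raise TableFormatError(
                    f"{path}:{lineno}: ragged row (expected {n_cols} fields)"
                )
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as err:
        raise TableFormatError(f"{path}: cannot parse as TSV: {err}") from err
    if df.shape[1] == 0:
        raise TableFormatError(f"{path}: no taxon columns found in header")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as err:
        raise TableFormatError(f"{path}: non-numeric abundance value: {err}") from err
    if df.isna().any().any():
        row, col = next(zip(*np.where(df.isna())))
        raise TableFormatError(
            f"{path}: missing value at sample {df.index[row]!r}, taxon {df.columns[col]!r}"
        )
    neg = np.where(df.to_numpy() < 0)
    if neg[0].size:
        r, c = neg[0][0], neg[1][0]
        raise TableFormatError(
            f"{path}: negative abundance at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
        )
    df.index = df.index.astype(str)
    return df


def _default_sample_meta(values: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": ["external"] * len(values),
            "m_env": np.nan,
            "n_colonists": np.nan,
            "richness": (values.to_numpy() > 0).sum(axis=1),
            "converged": True,
            "max_residual": np.nan,
        },
        index=values.index,
    )


def write_abundance_table(table: AbundanceTable, directory, include_pool: bool = True) -> list[pathlib.Path]:
    """Write a table (values + metadata + optional pool) to a directory."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    p = directory / "abundances.tsv"
    table.values.to_csv(p, sep="\t", float_format="%.17g")
    written.append(p)
    p = directory / "samples.tsv"
    table.sample_meta.to_csv(p, sep="\t")
    written.append(p)
    p = directory / "species.tsv"
    table.species_meta.to_csv(p, sep="\t")
    written.append(p)
    if table.supply is not None:
        p = directory / "supply.tsv"
        table.supply.to_csv(p, sep="\t", float_format="%.17g")
        written.append(p)
    if include_pool and table.pool is not None:
        save_pool(table.pool, directory / "pool")
        written.append(directory / "pool")
    return written


_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(ScenarioConfig)}


def load_config(path_or_text) -> ScenarioConfig:
    """Load a scenario configuration from YAML (strict keys).

    Omitted fields fall back to the documented defaults (the structured
    host-associated scenario with its standard parameter values);
    unknown keys and type mismatches are hard errors.
    """
    as_path = pathlib.Path(str(path_or_text)) if str(path_or_text).strip() else None
    if isinstance(path_or_text, pathlib.Path) or (as_path is not None and as_path.is_file()):
        text = pathlib.Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("configuration must be a mapping")
    unknown = set(data) - set(_CONFIG_FIELDS)
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for key, value in data.items():
        expected = _CONFIG_FIELDS[key].type
        if key in ("n_samples",) and value is not None and not isinstance(value, int):
            raise ValueError(f"{key} must be an integer, got {value!r}")
        if key in ("scale", "total_flux", "residual_tol", "t_max", "rtol") and not isinstance(
            value, (int, float)
        ):
            raise ValueError(f"{key} must be numeric, got {value!r}")
        if key in ("name", "kind", "dispersal") and not isinstance(value, str):
            raise ValueError(f"{key} must be a string, got {value!r}")
        if key == "params_overrides" and not isinstance(value, dict):
            raise ValueError("params_overrides must be a mapping")
    cfg = ScenarioConfig(**data)
    _validate_overrides(cfg)
    return cfg


def _validate_overrides(cfg: ScenarioConfig) -> None:
    ov = cfg.params_overrides
    if "f_w" in ov or "f_s" in ov:
        f_w = float(ov.get("f_w", 0.45))
        f_s = float(ov.get("f_s", 0.45))
        if f_w + f_s > 1.0 + 1e-12:
            raise ValueError(f"f_w + f_s must be <= 1, got {f_w + f_s}")


def dump_config(cfg: ScenarioConfig) -> str:
    """Serialize a configuration back to YAML (round-trips load_config)."""
    return yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False)


def write_manifest(
    directory, cfg: ScenarioConfig, table: AbundanceTable, artifacts: list
) -> pathlib.Path:
    """Write a run manifest recording config hash, seed and outcomes."""
    directory = pathlib.Path(directory)
    cfg_text = dump_config(cfg)
    manifest = {
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "config": dataclasses.asdict(cfg),
        "master_seed": cfg.master_seed,
        "package_version": _version(),
        "n_samples": table.n_samples,
        "n_discarded": table.n_discarded(),
        "discard_rule": "per-capita residual |d ln N_i/dt| >= 1e-5",
        "artifacts": [str(a) for a in artifacts],
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("micrm")
    except Exception:
        return "unknown"
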