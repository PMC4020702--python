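"""Readers and writers for the package's CSV schemas and text configs.

All CSV files are comma-delimited UTF-8 with "." decimals, months as integers
1–12 and years as calendar integers.  Output files may carry leading ``#``
provenance comment lines (version, seed, config hash); the readers skip them,
so every file the package writes is re-parseable by the package.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datamodel import (
    Dataset,
    KNOWN_FATE_COLUMNS,
    KnownFateSeries,
    ModelSpec,
    RADIO_HARVEST_COLUMNS,
    RadioHarvestSeries,
    RecoveryData,
    RECOVERY_COLUMNS,
    RELEASE_COLUMNS,
    DataValidationError,
    validate_known_fate,
    validate_radio_harvest,
    validate_recoveries,
)
from .simulation import Scenario

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_known_fate",
    "read_recovery_data",
    "read_radio_harvest",
    "load_model_spec",
    "save_model_spec",
    "load_scenario",
    "save_scenario",
    "provenance",
    "provenance_lines",
    "write_csv_with_provenance",
]

KNOWN_FATE_FILE = "known_fate.csv"
RELEASES_FILE = "releases.csv"
RECOVERIES_FILE = "recoveries.csv"
RADIO_HARVEST_FILE = "radio_harvest.csv"


def _read_csv(path: Path, columns, what: str) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise DataValidationError(
            f"{what} ({path}): missing columns {missing}; expected {list(columns)}, "
            f"found {list(table.columns)}"
        )
    for col in columns:
        if col in ("stratum", "age", "unit", "tag_type"):
            continue
        try:
            table[col] = pd.to_numeric(table[col])
        except (ValueError, TypeError):
            bad = table[pd.to_numeric(table[col], errors="coerce").isna()].index[0]
            raise DataValidationError(
                f"{what} ({path}): malformed value in column '{col}' at data row "
                f"{bad + 1}"
            ) from None
    return table


def read_known_fate(path) -> KnownFateSeries:
    return validate_known_fate(
        KnownFateSeries(_read_csv(Path(path), KNOWN_FATE_COLUMNS, "known-fate file"))
    )


def read_recovery_data(releases_path, recoveries_path) -> RecoveryData:
    return validate_recoveries(
        RecoveryData(
            releases=_read_csv(Path(releases_path), RELEASE_COLUMNS, "releases file"),
            recoveries=_read_csv(
                Path(recoveries_path), RECOVERY_COLUMNS, "recoveries file"
            ),
        )
    )


def read_radio_harvest(path) -> RadioHarvestSeries:
    return validate_radio_harvest(
        RadioHarvestSeries(
            _read_csv(Path(path), RADIO_HARVEST_COLUMNS, "radio-harvest file")
        )
    )


def read_dataset(directory) -> Dataset:
    """Read a dataset directory; absent optional files yield absent streams.

    Expects ``known_fate.csv``, ``releases.csv`` + ``recoveries.csv``, and
    ``radio_harvest.csv``; at least one stream must be present, and releases
    and recoveries must come together.
    """
    directory = Path(directory)
    known_fate = None
    if (directory / KNOWN_FATE_FILE).exists():
        known_fate = read_known_fate(directory / KNOWN_FATE_FILE)
    recoveries = None
    has_rel = (directory / RELEASES_FILE).exists()
    has_rec = (directory / RECOVERIES_FILE).exists()
    if has_rel != has_rec:
        raise DataValidationError(
            f"{RELEASES_FILE} and {RECOVERIES_FILE} must both be present or both absent"
        )
    if has_rel:
        recoveries = read_recovery_data(
            directory / RELEASES_FILE, directory / RECOVERIES_FILE
        )
    radio = None
    if (directory / RADIO_HARVEST_FILE).exists():
        radio = read_radio_harvest(directory / RADIO_HARVEST_FILE)
    return Dataset(
        known_fate=known_fate, recoveries=recoveries, radio_harvest=radio
    ).validate()


def write_dataset(data: Dataset, directory, header_lines=()) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if data.known_fate is not None:
        write_csv_with_provenance(
            data.known_fate.table, directory / KNOWN_FATE_FILE, header_lines
        )
    if data.recoveries is not None:
        write_csv_with_provenance(
            data.recoveries.releases, directory / RELEASES_FILE, header_lines
        )
        write_csv_with_provenance(
            data.recoveries.recoveries, directory / RECOVERIES_FILE, header_lines
        )
    if data.radio_harvest is not None:
        write_csv_with_provenance(
            data.radio_harvest.table, directory / RADIO_HARVEST_FILE, header_lines
        )


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


def load_model_spec(path) -> ModelSpec:
    """Load a model spec from a YAML config with a top-level ``model`` block.
    Unknown keys are errors."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "model" not in doc:
        raise ValueError(f"{path}: expected a top-level 'model' block")
    unknown = set(doc) - {"model"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    return ModelSpec.from_dict(doc["model"])


def save_model_spec(spec: ModelSpec, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"model": spec.to_dict()}, fh, sort_keys=False)


def load_scenario(path) -> Scenario:
    """Load a simulation scenario from a YAML config with a top-level
    ``scenario`` block.  Unknown keys are errors."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "scenario" not in doc:
        raise ValueError(f"{path}: expected a top-level 'scenario' block")
    unknown = set(doc) - {"scenario"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level keys {sorted(unknown)}")
    return Scenario.from_dict(doc["scenario"])


def save_scenario(scenario: Scenario, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"scenario": scenario.to_dict()}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# provenance and reports
# ---------------------------------------------------------------------------


def provenance(seed=None, config=None) -> dict:
    """Version / seed / config-hash stamp carried by every output.

    Deterministic by construction (no timestamps) so identical runs write
    byte-identical files.
    """
    stamp = {"package": "jointharvest", "version": __version__}
    if seed is not None:
        stamp["seed"] = seed
    if config is not None:
        canon = json.dumps(config, sort_keys=True, default=str)
        stamp["config_hash"] = hashlib.sha256(canon.encode()).hexdigest()[:12]
    return stamp


def provenance_lines(stamp: dict) -> list:
    return ["# " + " ".join(f"{k}={v}" for k, v in stamp.items())]


def write_csv_with_provenance(table: pd.DataFrame, path, header_lines=()) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(line.rstrip("\n") + "\n")
        table.to_csv(fh, index=False)


def write_fit_report(fitted, out_dir, stamp: dict) -> None:
    """Write ``estimates.csv`` (real-scale estimates, SEs, 95% intervals) and
    ``fit.json`` (log-likelihood, K, effective n, AICc, convergence)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_csv_with_provenance(
        fitted.estimates, out_dir / "estimates.csv", provenance_lines(stamp)
    )
    report = {
        "provenance": stamp,
        "loglik": fitted.loglik,
        "K": fitted.K,
        "n_eff": fitted.n_eff,
        "AICc": fitted.aicc,
        "converged": fitted.converged,
        "se_available": fitted.se_available,
        "message": fitted.message,
        "model": fitted.spec.to_dict(),
    }
    with open(out_dir / "fit.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
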