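"""CSV/FASTA/config I/O with explicit schemas and unit conversion.

All CSV files are comma-separated UTF-8 with a mandatory header row and dot
decimals.  Concentrations are converted to the package's canonical internal
unit (µM) on read; a missing or misspelt column raises a SchemaError naming
the column, and an unrecognized unit raises a UnitError.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .helix import HelixPeptide
from .hydro import CalibrationSeries
from .kinetics import ElongationAssay, RateTitration

__all__ = [
    "SchemaError",
    "UnitError",
    "to_uM",
    "read_titration_csv",
    "read_rate_titration_csv",
    "read_exchange_csv",
    "read_calibration_csv",
    "read_fasta_peptides",
    "load_config",
    "write_json_report",
]

_UNIT_TO_UM = {"uM": 1.0, "µM": 1.0, "um": 1.0, "nM": 1e-3, "nm": 1e-3, "mM": 1e3}


class SchemaError(ValueError):
    """A required column is missing or malformed."""


class UnitError(ValueError):
    """A concentration unit is missing or not recognized."""


def to_uM(values, unit: str):
    """Convert concentrations in ``unit`` (nM/µM/mM) to µM."""
    if unit not in _UNIT_TO_UM:
        raise UnitError(f"unrecognized concentration unit {unit!r}; expected nM, uM or mM")
    return np.asarray(values, dtype=float) * _UNIT_TO_UM[unit]


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_titration_csv(path) -> pd.DataFrame:
    """Fluorescence titration: ligand_conc_uM, signal[, signal_sd]."""
    df = pd.read_csv(path)
    _require(df, ["ligand_conc_uM", "signal"], path)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_rate_titration_csv(path) -> RateTitration:
    """Rate titration with assay context columns.

    Schema: ligand_conc, ligand_unit, norm_rate_pct[, rate_sd], end, A0_uM,
    seeds_nM.  The ligand grid keeps its native unit (nM for capping fits,
    µM for sequestration fits); the unit column records it.
    """
    df = pd.read_csv(path)
    _require(df, ["ligand_conc", "ligand_unit", "norm_rate_pct", "end", "A0_uM", "seeds_nM"], path)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    units = df["ligand_unit"].unique()
    if len(units) != 1:
        raise UnitError(f"{path}: mixed ligand units {list(units)}")
    unit = str(units[0])
    if unit in ("µM", "um"):
        unit = "uM"
    elif unit == "nm":
        unit = "nM"
    if unit not in ("nM", "uM"):
        raise UnitError(f"{path}: unrecognized ligand unit {units[0]!r}")
    assay = ElongationAssay(
        end=str(df["end"].iloc[0]),
        seeds0=float(df["seeds_nM"].iloc[0]),
        A0=float(df["A0_uM"].iloc[0]),
    )
    sd = df["rate_sd"].to_numpy(dtype=float) if "rate_sd" in df else None
    if sd is not None and not np.all(sd > 0):
        sd = None
    return RateTitration(
        ligand=df["ligand_conc"].to_numpy(dtype=float),
        rates=df["norm_rate_pct"].to_numpy(dtype=float),
        assay=assay,
        rate_sd=sd,
        ligand_unit=unit,
    )


def read_exchange_csv(path) -> pd.DataFrame:
    """Exchange time course: time_s, signal."""
    df = pd.read_csv(path)
    _require(df, ["time_s", "signal"], path)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_calibration_csv(path) -> CalibrationSeries:
    """Marker calibration table: marker, known_value, known_unit, observed_position."""
    df = pd.read_csv(path)
    _require(df, ["marker", "known_value", "known_unit", "observed_position"], path)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return CalibrationSeries(
        names=list(df["marker"]),
        known=df["known_value"].to_numpy(dtype=float),
        positions=df["observed_position"].to_numpy(dtype=float),
        unit=str(df["known_unit"].iloc[0]),
    )


def read_fasta_peptides(path) -> list[HelixPeptide]:
    """One-letter peptide sequences from a FASTA file."""
    peptides = [
        HelixPeptide(identifier=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not peptides:
        raise SchemaError(f"{path}: no FASTA records found")
    return peptides


def load_config(path) -> dict:
    """Key-value run configuration (YAML mapping)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a key-value mapping")
    return cfg


def write_json_report(path, payload: dict, seed: int | None = None) -> None:
    """Deterministic JSON report embedding package version and seed."""
    from . import __version__

    report = {"actinkit_version": __version__, "seed": seed, **payload}
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
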