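"""TSV/JSON input-output with column validation and provenance.

All tables are plain tab-separated text with a header row.  Readers
validate the required columns and basic value constraints, naming the file
and (for value errors) the 1-based line of the first offending record, so
malformed inputs fail loudly rather than propagating NaNs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

__all__ = [
    "read_peptide_inventory",
    "read_intensities",
    "read_survival_counts",
    "read_defect_events",
    "read_wave_onsets",
    "write_tsv",
    "write_json",
    "provenance",
]

INTENSITY_COLUMNS = [
    "genotype", "protein_id", "peptide_sequence", "charge_state",
    "injection", "intensity",
]
SURVIVAL_COLUMNS = ["genotype", "arm", "n_total", "n_dead", "uv_dose"]
EVENT_COLUMNS = ["genotype", "embryo_id", "nucleus_id", "cycle", "time_s", "category"]
ONSET_COLUMNS = ["genotype", "embryo_id", "position", "onset_time_s"]


def _read(path: str | Path, required: list[str], optional: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"nucleus_id": "string"} )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def _check_numeric(df: pd.DataFrame, path: str | Path, column: str, allow_na: bool = False) -> None:
    col = pd.to_numeric(df[column], errors="coerce")
    bad = col.isna() & df[column].notna()
    if not allow_na:
        bad |= df[column].isna()
    if bad.any():
        # +2: header line plus 1-based indexing
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: non-numeric value in column {column!r} at line {line}")


def read_peptide_inventory(path: str | Path) -> pd.DataFrame:
    df = _read(path, ["protein_id", "peptide_sequence", "charge_state"])
    _check_numeric(df, path, "charge_state")
    seq = df["peptide_sequence"].astype(str)
    if (seq.str.len() == 0).any() or not seq.str.fullmatch("[A-Z]+").all():
        raise ValueError(f"{path}: peptide sequences must be non-empty uppercase")
    if df.duplicated(["protein_id", "peptide_sequence", "charge_state"]).any():
        raise ValueError(f"{path}: duplicate peptide inventory entries")
    return df


def read_intensities(path: str | Path) -> pd.DataFrame:
    df = _read(path, INTENSITY_COLUMNS)
    _check_numeric(df, path, "injection")
    _check_numeric(df, path, "intensity", allow_na=True)  # blank = missing
    df["intensity"] = pd.to_numeric(df["intensity"], errors="coerce")
    return df


def read_survival_counts(path: str | Path) -> pd.DataFrame:
    df = _read(path, ["genotype", "arm", "n_total", "n_dead"])
    for col in ("n_total", "n_dead"):
        _check_numeric(df, path, col)
    if "uv_dose" not in df.columns:
        df["uv_dose"] = pd.NA
    return df


def read_defect_events(path: str | Path) -> pd.DataFrame:
    df = _read(path, EVENT_COLUMNS)
    if len(df):
        _check_numeric(df, path, "time_s")
    return df


def read_wave_onsets(path: str | Path) -> pd.DataFrame:
    df = _read(path, ONSET_COLUMNS)
    for col in ("position", "onset_time_s"):
        _check_numeric(df, path, col)
    return df


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(obj: Mapping[str, Any], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def provenance(config_dict: Mapping[str, Any]) -> dict[str, Any]:
    """Deterministic provenance block embedded in every JSON report."""
    from . import __version__

    canonical = json.dumps(config_dict, sort_keys=True).encode()
    return {
        "package": "tfiihkit",
        "version": __version__,
        "config_sha256": hashlib.sha256(canonical).hexdigest(),
        "config": dict(config_dict),
    }
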