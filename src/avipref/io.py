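"""CSV readers/writers, configuration, and run manifests.

All schemas are UTF-8 comma-separated files with a header row and '.'
decimals.  Ordered list fields (``trees``, ``flock_members``) are
';'-joined in files and Python lists in memory.  Readers validate row by
row and report malformed rows with their file line numbers; by default any
bad row aborts the read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .observations import DETECTION_COLUMNS, as_list

__all__ = [
    "SchemaError",
    "RowError",
    "read_inventory",
    "read_routes",
    "read_observations",
    "write_inventory",
    "write_routes",
    "write_observations",
    "load_native_list",
    "apply_native_list",
    "RunManifest",
    "preference_report",
]

log = logging.getLogger(__name__)

INVENTORY_SCHEMA = ["route_id", "species", "origin", "dbh_cm", "position_m"]
ROUTE_SCHEMA = ["route_id", "length_km", "income_class"]
OBSERVATION_SCHEMA = DETECTION_COLUMNS + ["substrate", "duration_s"]


class SchemaError(ValueError):
    """A file is missing required columns."""


@dataclass
class RowError:
    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _collect(df, checks, skip_bad, path):
    """Run per-row checks; each returns an error message or None."""
    errors: list[RowError] = []
    bad = np.zeros(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        for check in checks:
            msg = check(row)
            if msg:
                errors.append(RowError(line=i + 2, message=msg))  # header is line 1
                bad[i] = True
                break
    if errors and not skip_bad:
        raise ValueError(
            f"{path}: {len(errors)} malformed row(s); first: {errors[0]}"
        )
    if errors:
        log.warning("%s: skipped %d malformed row(s)", path, len(errors))
    return df.loc[~bad].reset_index(drop=True), errors


def _positive_number(value) -> bool:
    try:
        return float(value) > 0
    except (TypeError, ValueError):
        return False


def _non_negative(value) -> bool:
    try:
        return float(value) >= 0
    except (TypeError, ValueError):
        return False


def read_inventory(path, skip_bad: bool = False):
    """Read a street-tree inventory CSV.

    Returns ``(trees, errors)`` where ``errors`` lists skipped rows (empty
    unless ``skip_bad``).
    """
    df = pd.read_csv(path, dtype={"route_id": str, "species": str, "origin": str})
    _check_columns(df, INVENTORY_SCHEMA, path)
    checks = [
        lambda r: None if _positive_number(r.dbh_cm) else f"non-positive or non-numeric dbh_cm {r.dbh_cm!r}",
        lambda r: None if _non_negative(r.position_m) else f"bad position_m {r.position_m!r}",
        lambda r: None if r.origin in ("native", "nonnative", "unknown") else f"bad origin {r.origin!r}",
    ]
    df, errors = _collect(df, checks, skip_bad, path)
    df["dbh_cm"] = df["dbh_cm"].astype(float)
    df["position_m"] = df["position_m"].astype(float)
    return df, errors


def read_routes(path, skip_bad: bool = False):
    """Read route metadata CSV (route_id, length_km, income_class[, median_income])."""
    df = pd.read_csv(path, dtype={"route_id": str, "income_class": str})
    _check_columns(df, ROUTE_SCHEMA, path)
    checks = [
        lambda r: None if _positive_number(r.length_km) else f"non-positive length_km {r.length_km!r}",
        lambda r: None if r.income_class in ("low", "medium", "high") else f"bad income_class {r.income_class!r}",
    ]
    df, errors = _collect(df, checks, skip_bad, path)
    df["length_km"] = df["length_km"].astype(float)
    return df, errors


def read_observations(path, skip_bad: bool = False):
    """Read a raw-detection CSV; list columns are ';'-separated."""
    df = pd.read_csv(path, dtype={"route_id": str, "bird_species": str, "group": str})
    _check_columns(df, ["route_id", "visit_id", "bird_species", "group", "trees", "position_m"], path)
    checks = [
        lambda r: None if str(r.group) in ("migratory", "year_round") else f"bad group {r.group!r}",
        lambda r: None if as_list(r.trees) else "empty tree list",
    ]
    df, errors = _collect(df, checks, skip_bad, path)
    df["trees"] = df["trees"].map(as_list)
    if "flock_members" in df.columns:
        df["flock_members"] = df["flock_members"].map(as_list)
    else:
        df["flock_members"] = df["bird_species"].map(lambda b: [b])
    if "sex_distinct" not in df.columns:
        df["sex_distinct"] = False
    df["sex_distinct"] = df["sex_distinct"].astype(bool)
    if "flock_size" not in df.columns:
        df["flock_size"] = 1
    df["position_m"] = df["position_m"].astype(float)
    df["visit_id"] = df["visit_id"].astype(int)
    return df, errors


def _join_lists(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in ("trees", "flock_members"):
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: ";".join(v) if isinstance(v, (list, tuple)) else v
            )
    return out


def write_inventory(trees: pd.DataFrame, path) -> None:
    trees.to_csv(path, index=False)


def write_routes(routes: pd.DataFrame, path) -> None:
    routes.to_csv(path, index=False)


def write_observations(detections: pd.DataFrame, path) -> None:
    _join_lists(detections).to_csv(path, index=False)


def load_native_list(path) -> list[str]:
    """Load a native-species list from YAML or JSON (a plain list of labels)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if isinstance(data, dict) and "native_species" in data:
        data = data["native_species"]
    if not isinstance(data, list):
        raise SchemaError(f"{path}: expected a list of native species labels")
    return [str(s) for s in data]


def apply_native_list(trees: pd.DataFrame, native_species) -> pd.DataFrame:
    """Set the origin flag from a configured native list.

    Labels on the list become ``native``; everything else defaults to
    ``nonnative`` (unlisted labels in this survey are overwhelmingly
    nonnative).
    """
    native = set(native_species)
    out = trees.copy()
    out["origin"] = out["species"].map(lambda s: "native" if s in native else "nonnative")
    return out


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every command's outputs."""

    command: str
    seed: int | None = None
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> digest
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, out_dir) -> Path:
        path = Path(out_dir) / "manifest.json"
        payload = {
            "command": self.command,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "config": self.config,
            "inputs": self.inputs,
            "version": self.version,
            "timestamp": self.timestamp,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return path


def preference_report(preference: pd.DataFrame) -> pd.DataFrame:
    """Report-ready wide preference table (groupings as columns).

    Values are carried at full precision upstream; rounding happens only
    here — two decimals for percentages and indices, integer percent for
    proportional use.
    """
    if len(preference) == 0:
        return pd.DataFrame(
            columns=["tree_species", "iv_pct"]
        )
    iv = preference.drop_duplicates("tree_species").set_index("tree_species")["iv_pct"]
    wide = preference.pivot(index="tree_species", columns="grouping",
                            values="preference_index")
    prop = preference.pivot(index="tree_species", columns="grouping",
                            values="proportional_use")
    out = pd.DataFrame({"iv_pct": iv.round(2)})
    for col in wide.columns:
        out[f"pi_{col}"] = wide[col].round(2)
    for col in prop.columns:
        out[f"use_vs_avail_{col}"] = prop[col].round(0).astype("Int64").astype(str) + "%"
    out = out.sort_values("iv_pct", ascending=False)
    return out.reset_index()
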