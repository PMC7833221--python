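"""File I/O: delimited time-series matrices, pmf tables, JSON reports.

All artifacts are UTF-8 text.  Time series travel as tab- or
comma-delimited files with a header row and an optional ``trial`` column;
probability tables as ``pmf`` files (one joint outcome per line: integer
codes then the mass, tab-separated); emergence reports as schema-versioned
JSON with full provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .criteria import EmergenceReport
from .prob import ArgumentError, ProbabilityTable, SampleMatrix

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_pmf",
    "write_pmf",
    "write_report",
    "read_report",
    "SchemaError",
]

REPORT_SCHEMA = 1


class SchemaError(ValueError):
    """Report file schema version mismatch or malformed report."""


def _load_frame(path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ArgumentError(f"cannot parse {path.name}: {exc}") from exc
    if frame.columns.duplicated().any():
        raise ArgumentError(f"{path.name}: duplicate column names in header")
    if frame.isna().any().any():
        rows = frame.index[frame.isna().any(axis=1)][:3].tolist()
        raise ArgumentError(
            f"{path.name}: missing/ragged values near data row(s) {rows}"
        )
    return frame


def _column_kind(frame: pd.DataFrame, cols) -> str:
    kinds = set()
    for c in cols:
        if pd.api.types.is_integer_dtype(frame[c]):
            kinds.add("discrete")
        elif pd.api.types.is_float_dtype(frame[c]):
            kinds.add("continuous")
        else:
            raise ArgumentError(f"column {c!r} is neither integer nor real")
    if len(kinds) != 1:
        raise ArgumentError(
            "mixed integer and real columns in one group; discretise "
            "explicitly or split the groups"
        )
    return kinds.pop()


def read_timeseries(
    path,
    feature_cols: list[str],
    system_cols: list[str] | None = None,
) -> tuple[SampleMatrix, SampleMatrix]:
    """Read a delimited file into (system, feature) sample matrices.

    The optional ``trial`` column partitions rows into trials of equal
    length, so that lag pairing never crosses trial boundaries; without it
    the file is a single trial.  Remaining columns (neither feature nor
    ``trial``) form the system unless ``system_cols`` names them explicitly.
    """
    frame = _load_frame(path)
    missing = [c for c in feature_cols if c not in frame.columns]
    if system_cols:
        missing += [c for c in system_cols if c not in frame.columns]
    if missing:
        raise ArgumentError(f"missing named column(s): {missing}")
    if not feature_cols:
        raise ArgumentError("at least one feature column is required")
    if system_cols is None:
        system_cols = [
            c for c in frame.columns if c not in feature_cols and c != "trial"
        ]
    if not system_cols:
        raise ArgumentError("no system columns left after removing the feature")
    overlap = set(feature_cols) & set(system_cols)
    if overlap:
        raise ArgumentError(f"columns {sorted(overlap)} are both feature and system")

    if "trial" in frame.columns:
        groups = [g for _, g in frame.groupby("trial", sort=True)]
        lengths = {len(g) for g in groups}
        if len(lengths) != 1:
            raise ArgumentError(
                f"trials have unequal lengths {sorted(lengths)}; pad or split"
            )
        sys_vals = np.stack([g[system_cols].to_numpy() for g in groups])
        feat_vals = np.stack([g[feature_cols].to_numpy() for g in groups])
    else:
        sys_vals = frame[system_cols].to_numpy()[None]
        feat_vals = frame[feature_cols].to_numpy()[None]

    kind_sys = _column_kind(frame, system_cols)
    kind_feat = _column_kind(frame, feature_cols)
    if kind_sys != kind_feat:
        raise ArgumentError(
            "system and feature columns must be both discrete or both "
            "continuous"
        )
    system = SampleMatrix(sys_vals, kind=kind_sys)
    feature = SampleMatrix(feat_vals, kind=kind_feat)
    return system, feature


def write_timeseries(
    path, columns: dict[str, np.ndarray], trial: np.ndarray | None = None
) -> None:
    """Write named columns (and an optional trial index) as a TSV file."""
    frame = pd.DataFrame(columns)
    if trial is not None:
        frame.insert(0, "trial", trial)
    frame.to_csv(path, sep="\t", index=False)


def read_pmf(path) -> ProbabilityTable:
    """Read a pmf file: per line, integer outcome codes then the mass."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ArgumentError(
                    f"line {lineno}: need at least one code and a mass"
                )
            try:
                codes = [int(p) for p in parts[:-1]]
                mass = float(parts[-1])
            except ValueError as exc:
                raise ArgumentError(f"line {lineno}: {exc}") from exc
            rows.append((codes, mass))
    if not rows:
        raise ArgumentError("pmf file holds no outcomes")
    n_vars = len(rows[0][0])
    if any(len(c) != n_vars for c, _ in rows):
        raise ArgumentError("inconsistent number of outcome codes per line")
    cards = [max(c[i] for c, _ in rows) + 1 for i in range(n_vars)]
    masses = np.zeros(cards)
    for codes, mass in rows:
        masses[tuple(codes)] += mass
    names = [f"x{i + 1}" for i in range(n_vars)]
    return ProbabilityTable(names, masses, normalise=True)


def write_pmf(path, table: ProbabilityTable) -> None:
    """Write a ProbabilityTable in the pmf line format (zero cells skipped)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# " + "\t".join(table.names) + "\tmass\n")
        for idx in np.ndindex(*table.cardinalities):
            mass = table.masses[idx]
            if mass > 0:
                fh.write(
                    "\t".join(str(i) for i in idx) + f"\t{mass:.17g}\n"
                )


def report_to_dict(report: EmergenceReport, provenance: dict | None = None) -> dict:
    data = asdict(report)
    data["provenance"] = {**data.get("provenance", {}), **(provenance or {})}
    data["provenance"].setdefault("package_version", __version__)
    return {"schema_version": REPORT_SCHEMA, "report": data}


def write_report(
    report: EmergenceReport, path, provenance: dict | None = None
) -> None:
    """Serialise an EmergenceReport (plus provenance) as versioned JSON."""
    payload = report_to_dict(report, provenance)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> EmergenceReport:
    """Read a report written by :func:`write_report`."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != REPORT_SCHEMA:
        raise SchemaError(
            f"report schema {version!r} unsupported (expected {REPORT_SCHEMA})"
        )
    data = dict(payload["report"])
    field_names = EmergenceReport.__dataclass_fields__.keys()
    unknown = set(data) - set(field_names)
    if unknown:
        raise SchemaError(f"unknown report fields: {sorted(unknown)}")
    return EmergenceReport(**data)
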