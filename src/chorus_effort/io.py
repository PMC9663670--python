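"""Readers and writers for the tabular inputs and outputs.

All inputs are delimited text (comma by default, tab accepted), UTF-8,
with a header row. Column names can be remapped via ``column_map`` so
externally deposited tables with different headers can be ingested
without editing the files.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import datetime, timedelta, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import GridValidationError, SchemaError
from .model import DetectionRecord, IncidenceMatrix, Phase, phase_of_offset

_GENUS_ONLY_RE = re.compile(r"\bsp\.?$", re.IGNORECASE)
_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


@dataclass(slots=True)
class IngestReport:
    """Accounting of an annotation-table ingest.

    Invariant: ``rows_read == rows_retained + rows_excluded``.
    """

    rows_read: int = 0
    rows_retained: int = 0
    rows_excluded: int = 0
    exclusions: list[tuple[int, str, str]] = field(default_factory=list)  # (row, species, reason)

    def record_exclusion(self, row: int, species: str, reason: str) -> None:
        self.rows_excluded += 1
        self.exclusions.append((row, species, reason))


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a comma- or tab-delimited text table with a header row."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")


def _resolve_columns(df: pd.DataFrame, wanted: Mapping[str, bool], column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map logical column names to actual headers; raise SchemaError if a
    required one is missing. ``wanted`` maps logical name -> required?."""
    column_map = dict(column_map or {})
    lower = {c.lower(): c for c in df.columns}
    out: dict[str, str] = {}
    for logical, required in wanted.items():
        actual = column_map.get(logical, logical)
        if actual in df.columns:
            out[logical] = actual
        elif actual.lower() in lower:
            out[logical] = lower[actual.lower()]
        elif required:
            raise SchemaError(f"required column {actual!r} (for {logical!r}) not found in {list(df.columns)}")
    return out


def _parse_genus_only(raw: str | None, species: str) -> bool:
    """Genus-level flag: explicit column value if given, else inferred from a
    trailing 'sp.' in the species code (e.g. 'Certhia sp.')."""
    if raw is not None:
        v = raw.strip().lower()
        if v in _TRUTHY:
            return True
        if v in _FALSY:
            return False
        raise GridValidationError(f"unparseable genus-only flag {raw!r}")
    return bool(_GENUS_ONLY_RE.search(species.strip()))


def read_annotations(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    max_days: int = 4,
) -> tuple[list[DetectionRecord], IngestReport]:
    """Read an annotation table into validated detection records.

    Expected logical columns: ``plot``, ``day``, ``species``, and either
    ``offset`` (signed minutes from sunrise) or ``phase`` + ``minute``
    (0-59 within the phase hour). An optional ``genus_only`` column
    overrides the trailing-'sp.' inference.

    Genus-level-only identifications are excluded here (not downstream)
    and itemised in the returned :class:`IngestReport`.
    """
    df = _read_table(path)
    cols = _resolve_columns(
        df,
        {"plot": True, "day": True, "species": True, "offset": False, "phase": False, "minute": False, "genus_only": False},
        column_map,
    )
    has_offset = "offset" in cols
    if not has_offset and not ("phase" in cols and "minute" in cols):
        raise SchemaError("need either an 'offset' column or both 'phase' and 'minute' columns")

    report = IngestReport(rows_read=len(df))
    records: list[DetectionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        species = str(row_d[cols["species"]]).strip()
        try:
            day = int(row_d[cols["day"]])
        except ValueError as exc:
            raise GridValidationError(f"row {i}: unparseable day {row_d[cols['day']]!r}") from exc
        if not (1 <= day <= max_days):
            raise GridValidationError(f"row {i}: day {day} outside 1..{max_days}")
        if has_offset:
            try:
                offset = int(row_d[cols["offset"]])
            except ValueError as exc:
                raise GridValidationError(f"row {i}: unparseable offset {row_d[cols['offset']]!r}") from exc
        else:
            phase_label = str(row_d[cols["phase"]]).strip().lower()
            try:
                phase = Phase(phase_label)
            except ValueError as exc:
                raise GridValidationError(f"row {i}: unknown phase label {phase_label!r}") from exc
            try:
                minute = int(row_d[cols["minute"]])
            except ValueError as exc:
                raise GridValidationError(f"row {i}: unparseable minute {row_d[cols['minute']]!r}") from exc
            if not (0 <= minute < 60):
                raise GridValidationError(f"row {i}: minute {minute} outside 0..59")
            offset = phase.start + minute
        try:
            phase_of_offset(offset)
        except ValueError as exc:
            raise GridValidationError(f"row {i}: {exc}") from exc
        genus_raw = str(row_d[cols["genus_only"]]) if "genus_only" in cols else None
        genus_only = _parse_genus_only(genus_raw, species)
        if genus_only:
            report.record_exclusion(i, species, "genus-level identification")
            continue
        records.append(DetectionRecord(str(row_d[cols["plot"]]).strip(), day, offset, species))
        report.rows_retained += 1
    return records, report


def write_annotations(records: Iterable[DetectionRecord], path: str | Path) -> None:
    """Write detection records as a comma-delimited table (round-trippable
    through :func:`read_annotations`)."""
    df = pd.DataFrame(
        {
            "plot": [r.plot_id for r in records],
            "day": [r.day_index for r in records],
            "offset": [r.offset_min for r in records],
            "species": [r.species_code for r in records],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_sunrise_table(path: str | Path, *, column_map: Mapping[str, str] | None = None) -> dict[tuple[str, Date], datetime]:
    """Read a per-plot-day sunrise table into a (plot, date) -> datetime map.

    Expected columns: ``plot``, ``date`` (ISO), ``sunrise`` — a local clock
    time carrying its UTC offset (e.g. ``05:52:00+02:00``); alternatively a
    plain time plus a ``utc_offset`` column of hours. Duplicate (plot, date)
    keys are rejected.
    """
    df = _read_table(path)
    cols = _resolve_columns(df, {"plot": True, "date": True, "sunrise": True, "utc_offset": False}, column_map)
    mapping: dict[tuple[str, Date], datetime] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        plot = str(row_d[cols["plot"]]).strip()
        day = Date.fromisoformat(str(row_d[cols["date"]]).strip())
        raw = str(row_d[cols["sunrise"]]).strip()
        try:
            t = datetime.fromisoformat(f"{day.isoformat()}T{raw}")
        except ValueError as exc:
            raise SchemaError(f"row {i}: unparseable sunrise time {raw!r}") from exc
        if t.tzinfo is None:
            if "utc_offset" not in cols:
                raise SchemaError(f"row {i}: sunrise {raw!r} has no UTC offset and no utc_offset column given")
            t = t.replace(tzinfo=timezone(timedelta(hours=float(row_d[cols["utc_offset"]]))))
        key = (plot, day)
        if key in mapping:
            raise SchemaError(f"row {i}: duplicate (plot, date) key {key}")
        mapping[key] = t
    return mapping


def read_point_counts(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    unit_ids: Sequence[str] | None = None,
) -> IncidenceMatrix:
    """Read a point-count detection table (plot, species) into a
    plots x species presence/absence matrix for the reference method."""
    df = _read_table(path)
    cols = _resolve_columns(df, {"plot": True, "species": True}, column_map)
    pairs = [(str(p).strip(), str(s).strip()) for p, s in zip(df[cols["plot"]], df[cols["species"]])]
    if not pairs:
        warnings.warn(f"point-count table {path} contains no detections", stacklevel=2)
    return IncidenceMatrix.from_pairs(pairs, unit_ids=unit_ids)


# ---------------------------------------------------------------------------
# Output writing

_FLOAT_FORMAT = "%.10g"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    results: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    *,
    manifest_extra: Mapping[str, object] | None = None,
) -> dict[str, str]:
    """Write result tables as delimited text plus a run manifest.

    Each entry of ``results`` becomes ``<name>.csv`` under ``out_dir``;
    the manifest (``manifest.txt``, ``key: value`` lines, sorted) records
    a sha256 per file plus any extra keys (config hash, seed). Output is
    byte-stable for identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {str(k): str(v) for k, v in (manifest_extra or {}).items()}
    for name, frame in results.items():
        fname = f"{name}.csv"
        frame.to_csv(out_dir / fname, index=False, lineterminator="\n", float_format=_FLOAT_FORMAT)
        manifest[f"sha256:{fname}"] = _sha256(out_dir / fname)
    lines = [f"{k}: {manifest[k]}" for k in sorted(manifest)]
    (out_dir / "manifest.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
    return manifest
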