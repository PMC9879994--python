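"""Reading and writing specimen / transect tables and fit files.

All tables are comma-separated UTF-8 text with a mandatory header row and
"." as the decimal separator.  Numeric fields round-trip at 6 significant
digits.  Rows that violate record invariants are rejected individually with
row-numbered diagnostics; well-formed rows are kept.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .datatypes import (
    CoralMeasurement,
    FrameScale,
    RecordError,
    SpecimenRecord,
    TransectRecord,
)

log = logging.getLogger(__name__)

SPECIMEN_COLUMNS = (
    "species", "state", "site", "region",
    "max_diameter_cm", "perp_diameter_cm", "weight_g", "is_fragment",
)
TRANSECT_COLUMNS = (
    "transect_id", "state", "location", "reef", "site", "depth_m",
    "length_m", "width_m", "species", "max_length_cm", "width_cm",
    "partially_visible",
)
_NUMERIC_FMT = "%.6g"


class SchemaError(ValueError):
    """The file is missing a mandatory column."""


@dataclass
class RowReport:
    """Per-file parse diagnostics: which rows were rejected and why."""

    path: str
    n_rows: int = 0
    n_accepted: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"{self.path}: {self.n_accepted}/{self.n_rows} rows accepted"]
        for row, reason in self.rejected:
            lines.append(f"  row {row}: {reason}")
        return "\n".join(lines)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value)


def _as_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return False
    return str(value).strip().lower() in ("true", "1", "yes")


def read_specimens(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    species_vocab: Sequence[str] | None = None,
    report: RowReport | None = None,
) -> list[SpecimenRecord]:
    """Read a specimen table into validated records, preserving file order.

    ``schema`` maps canonical column names to the names used in the file.
    Invalid rows are dropped with a logged, row-numbered diagnostic (also
    collected on ``report`` when given); a missing mandatory column raises
    :class:`SchemaError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    mandatory = ("species", "state", "max_diameter_cm", "weight_g")
    for col in mandatory:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    if report is None:
        report = RowReport(path=str(path))
    report.n_rows = len(df)
    if len(df) == 0:
        warnings.warn(f"{path}: empty specimen file", stacklevel=2)
        return []

    records: list[SpecimenRecord] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based, header is line 1
        try:
            rec = SpecimenRecord(
                species=str(row["species"]),
                state=str(row["state"]),
                max_diameter_cm=float(row["max_diameter_cm"]),
                weight_g=float(row["weight_g"]),
                perp_diameter_cm=_opt_float(row.get("perp_diameter_cm")),
                site=_opt_str(row.get("site")),
                region=_opt_str(row.get("region")),
                is_fragment=_as_bool(row.get("is_fragment")),
            )
            if species_vocab is not None:
                rec.validate_vocab(species_vocab)
        except (RecordError, TypeError, ValueError) as exc:
            report.rejected.append((rownum, str(exc)))
            log.warning("%s row %d rejected: %s", path, rownum, exc)
            continue
        records.append(rec)
    report.n_accepted = len(records)
    return records


def write_specimens(records: Sequence[SpecimenRecord], path: str | Path) -> Path:
    """Write records with the canonical header; inverse of :func:`read_specimens`."""
    path = Path(path)
    rows = [
        {
            "species": r.species,
            "state": r.state,
            "site": r.site,
            "region": r.region,
            "max_diameter_cm": r.max_diameter_cm,
            "perp_diameter_cm": r.perp_diameter_cm,
            "weight_g": r.weight_g,
            "is_fragment": r.is_fragment,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=list(SPECIMEN_COLUMNS))
    df.to_csv(path, index=False, float_format=_NUMERIC_FMT)
    return path


def read_transects(
    path: str | Path,
    report: RowReport | None = None,
) -> list[TransectRecord]:
    """Read a transect table (one row per measured coral) into records.

    Rows sharing a ``transect_id`` form one transect.  A row may give the
    coral size either pre-converted (``max_length_cm``) or as raw frame
    pixels (``reference_pixels``, ``measured_pixels`` with an optional
    ``reference_length_m``, default 1.0), in which case the scale conversion
    is applied on read.  A row with an empty ``species`` field declares an
    empty (coral-free) transect.
    """
    from .transects import pixels_to_cm

    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if "transect_id" not in df.columns or "state" not in df.columns:
        raise SchemaError(f"{path}: missing mandatory column 'transect_id' or 'state'")
    has_cm = "max_length_cm" in df.columns
    has_px = "measured_pixels" in df.columns and "reference_pixels" in df.columns
    if not (has_cm or has_px):
        raise SchemaError(
            f"{path}: need either 'max_length_cm' or 'reference_pixels'+'measured_pixels'"
        )
    if report is None:
        report = RowReport(path=str(path))
    report.n_rows = len(df)

    meta: dict[str, dict] = {}
    corals: dict[str, list[CoralMeasurement]] = {}
    order: list[str] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2
        tid = str(row["transect_id"])
        if tid not in meta:
            order.append(tid)
            meta[tid] = {
                "state": str(row["state"]),
                "location": _opt_str(row.get("location")),
                "reef": _opt_str(row.get("reef")),
                "site": _opt_str(row.get("site")),
                "depth_m": _opt_float(row.get("depth_m")) or 0.0,
                "length_m": _opt_float(row.get("length_m")) or 50.0,
                "width_m": _opt_float(row.get("width_m")) or 1.0,
            }
            corals[tid] = []
        species = _opt_str(row.get("species"))
        if species is None:
            continue  # metadata-only row: empty transect
        try:
            if has_cm and _opt_float(row.get("max_length_cm")) is not None:
                length_cm = float(row["max_length_cm"])
            elif has_px:
                scale = FrameScale(
                    reference_length_m=_opt_float(row.get("reference_length_m")) or 1.0,
                    reference_pixels=float(row["reference_pixels"]),
                    frame_id=_opt_str(row.get("frame_id")) or "",
                )
                length_cm = pixels_to_cm(scale, float(row["measured_pixels"]))
            else:
                raise RecordError("no size measurement on row")
            corals[tid].append(
                CoralMeasurement(
                    species=species,
                    max_length_cm=length_cm,
                    width_cm=_opt_float(row.get("width_cm")),
                    partially_visible=_as_bool(row.get("partially_visible")),
                )
            )
        except (RecordError, TypeError, ValueError) as exc:
            report.rejected.append((rownum, str(exc)))
            log.warning("%s row %d rejected: %s", path, rownum, exc)
            continue

    out: list[TransectRecord] = []
    for tid in order:
        out.append(TransectRecord(transect_id=tid, corals=tuple(corals[tid]), **meta[tid]))
    report.n_accepted = report.n_rows - len(report.rejected)
    return out


def write_transects(transects: Sequence[TransectRecord], path: str | Path) -> Path:
    """Write transects one-coral-per-row; empty transects get a metadata row."""
    path = Path(path)
    rows = []
    for t in transects:
        base = {
            "transect_id": t.transect_id, "state": t.state, "location": t.location,
            "reef": t.reef, "site": t.site, "depth_m": t.depth_m,
            "length_m": t.length_m, "width_m": t.width_m,
        }
        if not t.corals:
            rows.append({**base, "species": None, "max_length_cm": None,
                         "width_cm": None, "partially_visible": None})
        for c in t.corals:
            rows.append({**base, "species": c.species, "max_length_cm": c.max_length_cm,
                         "width_cm": c.width_cm, "partially_visible": c.partially_visible})
    df = pd.DataFrame(rows, columns=list(TRANSECT_COLUMNS))
    df.to_csv(path, index=False, float_format=_NUMERIC_FMT)
    return path


def write_fit_summaries(summaries: Mapping[str, object], path: str | Path) -> Path:
    """Serialise per-species fit summaries as JSON (see FitSummary.to_dict)."""
    path = Path(path)
    payload = {
        sp: (s.to_dict() if hasattr(s, "to_dict") else s) for sp, s in summaries.items()
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_fit_summaries(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
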