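"""Readers and writers for sample sheets, peak tables and result reports.

The wide-format *sample sheet* carries one row per sherd with columns
``sample_id, site, vessel_form, lipid_concentration, d13c_16_0, d13c_18_0,
tag_40..tag_56, acid_tartaric..acid_oxalic, extractions``; a long-format
companion *peak table* carries one row per identified compound per sample.
Blank optional blocks become absent fields (``None``), never zeros, so
"not analysed" survives a round trip.  A column-mapping dict adapts foreign
spreadsheet layouts to the canonical column names.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .types import (
    COMMODITY_LABELS,
    COMPOUND_CLASSES,
    AcidQuant,
    CommodityProfile,
    EvidenceLevel,
    IsotopeMeasurement,
    Peak,
    PeakTable,
    SampleRecord,
    SchemaError,
    TagProfile,
    TAG_CARBONS,
    ValidationError,
)

PathLike = Union[str, Path]

MANDATORY_COLUMNS = ("sample_id", "site", "lipid_concentration")
ACID_COLUMNS = tuple(f"acid_{name}" for name in AcidQuant.ACID_NAMES)
TAG_COLUMNS = tuple(f"tag_{c}" for c in TAG_CARBONS)

PEAK_COLUMNS = (
    "sample_id",
    "compound",
    "compound_class",
    "chain_length",
    "substituent_position",
    "unsaturation",
    "abundance",
)


@dataclass
class RowDiagnostic:
    """Why one sheet row failed validation (0-based data-row index)."""

    row_index: int
    sample_id: str
    message: str


@dataclass
class SheetReadResult:
    """Valid records plus row-indexed diagnostics for rejected rows."""

    records: List[SampleRecord] = field(default_factory=list)
    diagnostics: List[RowDiagnostic] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _read_table(path: PathLike, fmt: Optional[str]) -> pd.DataFrame:
    p = Path(path)
    fmt = fmt or {"csv": "csv", "tsv": "tsv", "txt": "tsv", "xlsx": "xlsx"}.get(
        p.suffix.lstrip(".").lower(), "csv"
    )
    if fmt == "csv":
        return pd.read_csv(p, float_precision="round_trip")
    if fmt == "tsv":
        return pd.read_csv(p, sep="\t", float_precision="round_trip")
    if fmt == "xlsx":
        return pd.read_excel(p)
    raise SchemaError(f"unsupported sample-sheet format {fmt!r}")


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and not value.strip():
        return True
    return False


def _row_to_record(row: Mapping, columns: Sequence[str]) -> SampleRecord:
    sample_id = str(row["sample_id"]).strip()
    site = str(row["site"]).strip() if not _is_blank(row.get("site")) else ""
    vessel_form = (
        str(row["vessel_form"]).strip()
        if "vessel_form" in columns and not _is_blank(row.get("vessel_form"))
        else "other"
    )
    conc = row["lipid_concentration"]
    if _is_blank(conc):
        raise ValidationError("lipid_concentration missing")
    conc = float(conc)

    isotopes = None
    if "d13c_16_0" in columns and "d13c_18_0" in columns:
        v16, v18 = row.get("d13c_16_0"), row.get("d13c_18_0")
        if not _is_blank(v16) and not _is_blank(v18):
            isotopes = IsotopeMeasurement(float(v16), float(v18))

    tag_profile = None
    tag_values = {
        c: float(row[f"tag_{c}"])
        for c in TAG_CARBONS
        if f"tag_{c}" in columns and not _is_blank(row.get(f"tag_{c}"))
    }
    if any(v > 0 for v in tag_values.values()):
        tag_profile = TagProfile(tag_values)

    acids = None
    acid_values = {
        name: float(row[f"acid_{name}"])
        for name in AcidQuant.ACID_NAMES
        if f"acid_{name}" in columns and not _is_blank(row.get(f"acid_{name}"))
    }
    if acid_values:
        acids = AcidQuant(**acid_values)

    if "extractions" in columns and not _is_blank(row.get("extractions")):
        flags = frozenset(
            f.strip() for f in str(row["extractions"]).split(";") if f.strip()
        )
    else:  # infer from which measurement blocks exist
        inferred = {"acid_methanol"}
        if tag_profile is not None:
            inferred.add("solvent")
        if acids is not None:
            inferred.add("butylation")
        flags = frozenset(inferred)

    return SampleRecord(
        sample_id=sample_id,
        site=site,
        vessel_form=vessel_form,
        lipid_concentration=conc,
        isotopes=isotopes,
        tag_profile=tag_profile,
        acids=acids,
        extraction_flags=flags,
    )


def read_sample_sheet(
    path: PathLike,
    format: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> SheetReadResult:
    """Read a sample sheet; every row becomes a record or a diagnostic.

    ``column_map`` maps canonical column names to the file's own headers,
    adapting foreign layouts.  A missing mandatory column raises
    :class:`SchemaError`; a duplicated sample_id raises
    :class:`ValidationError`.
    """
    df = _read_table(path, format)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    columns = list(df.columns)
    for col in MANDATORY_COLUMNS:
        if col not in columns:
            raise SchemaError(f"sample sheet missing mandatory column {col!r}")

    ids = [str(v).strip() for v in df["sample_id"] if not _is_blank(v)]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValidationError(f"duplicate sample_id values: {sorted(dupes)}")

    result = SheetReadResult()
    for idx, row in enumerate(df.to_dict(orient="records")):
        sid = "" if _is_blank(row.get("sample_id")) else str(row["sample_id"]).strip()
        try:
            result.records.append(_row_to_record(row, columns))
        except (ValidationError, ValueError) as exc:
            result.diagnostics.append(RowDiagnostic(idx, sid, str(exc)))
    return result


def read_peak_table(path: PathLike, format: Optional[str] = None) -> Dict[str, PeakTable]:
    """Read the long-format companion peak table into per-sample PeakTables.

    Rows with an unknown compound_class are dropped from the tables and
    reported once per class through a logged warning, so unrecognized
    vocabulary never silently influences the rules.
    """
    df = _read_table(path, format)
    for col in PEAK_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"peak table missing mandatory column {col!r}")
    tables: Dict[str, List[Peak]] = {}
    unknown: set = set()
    for row in df.to_dict(orient="records"):
        cls = str(row["compound_class"]).strip()
        if cls not in COMPOUND_CLASSES:
            unknown.add(cls)
            continue
        sid = str(row["sample_id"]).strip()
        tables.setdefault(sid, []).append(
            Peak(
                compound=str(row["compound"]).strip(),
                compound_class=cls,
                chain_length=int(row["chain_length"]),
                substituent_position=int(row["substituent_position"]),
                unsaturation=int(row["unsaturation"]),
                abundance=float(row["abundance"]),
            )
        )
    if unknown:
        logging.getLogger(__name__).warning(
            "peak table: ignoring rows with unknown compound classes %s", sorted(unknown)
        )
    return {sid: PeakTable(rows) for sid, rows in tables.items()}


def attach_peaks(records: Iterable[SampleRecord], tables: Mapping[str, PeakTable]) -> None:
    """Attach per-sample peak tables to records in place (missing -> empty)."""
    for rec in records:
        if rec.sample_id in tables:
            rec.peaks = tables[rec.sample_id]


def write_sample_sheet(records: Sequence[SampleRecord], path: PathLike) -> None:
    """Write records to a canonical wide-format CSV sample sheet."""
    rows = []
    for rec in records:
        row: Dict[str, object] = {
            "sample_id": rec.sample_id,
            "site": rec.site,
            "vessel_form": rec.vessel_form,
            "lipid_concentration": rec.lipid_concentration,
            "d13c_16_0": rec.isotopes.d13c_16_0 if rec.isotopes else "",
            "d13c_18_0": rec.isotopes.d13c_18_0 if rec.isotopes else "",
        }
        for c in TAG_CARBONS:
            row[f"tag_{c}"] = (
                rec.tag_profile.abundances.get(c, 0.0) if rec.tag_profile else ""
            )
        for name in AcidQuant.ACID_NAMES:
            row[f"acid_{name}"] = getattr(rec.acids, name) if rec.acids else ""
        row["extractions"] = ";".join(sorted(rec.extraction_flags))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_peak_table(tables: Mapping[str, PeakTable], path: PathLike) -> None:
    """Write per-sample peak tables to the long-format companion CSV."""
    rows = []
    for sid in sorted(tables):
        for p in tables[sid]:
            rows.append(
                {
                    "sample_id": sid,
                    "compound": p.compound,
                    "compound_class": p.compound_class,
                    "chain_length": p.chain_length,
                    "substituent_position": p.substituent_position,
                    "unsaturation": p.unsaturation,
                    "abundance": p.abundance,
                }
            )
    pd.DataFrame(rows, columns=list(PEAK_COLUMNS)).to_csv(path, index=False)


_NOTE_SEP = " | "


def write_report(
    profiles: Sequence[Tuple[SampleRecord, CommodityProfile]],
    path: PathLike,
    format: str = "json",
) -> None:
    """Write per-vessel commodity profiles to JSON (nested) or TSV (flat).

    Column/key order is deterministic; evidence levels serialize as their
    string values; audit notes are included in both formats.
    """
    if not profiles:
        raise ValidationError("write_report requires at least one profile")
    if format == "json":
        payload = {
            "samples": [
                {
                    "sample_id": rec.sample_id,
                    "site": rec.site,
                    "vessel_form": rec.vessel_form,
                    "lipid_concentration": rec.lipid_concentration,
                    "heating": prof.heating,
                    "flags": {label: prof.flags[label].value for label in COMMODITY_LABELS},
                    "notes": list(prof.notes),
                }
                for rec, prof in profiles
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
        return
    if format == "tsv":
        header = (
            ["sample_id", "site", "vessel_form", "lipid_concentration", "heating"]
            + list(COMMODITY_LABELS)
            + ["notes"]
        )
        lines = ["\t".join(header)]
        for rec, prof in profiles:
            cells = [
                rec.sample_id,
                rec.site,
                rec.vessel_form,
                repr(rec.lipid_concentration),
                str(prof.heating),
                *(prof.flags[label].value for label in COMMODITY_LABELS),
                _NOTE_SEP.join(prof.notes),
            ]
            lines.append("\t".join(cells))
        Path(path).write_text("\n".join(lines) + "\n")
        return
    raise ValidationError(f"unsupported report format {format!r}")


def read_report(path: PathLike, format: str = "json") -> List[Dict]:
    """Parse a written report back into plain dicts (round-trip aid)."""
    p = Path(path)
    if format == "json":
        data = json.loads(p.read_text())
        return list(data["samples"])
    if format == "tsv":
        lines = p.read_text().splitlines()
        header = lines[0].split("\t")
        out = []
        for line in lines[1:]:
            cells = line.split("\t")
            row = dict(zip(header, cells))
            flags = {label: row.pop(label) for label in COMMODITY_LABELS}
            notes = row.pop("notes")
            out.append(
                {
                    "sample_id": row["sample_id"],
                    "site": row["site"],
                    "vessel_form": row["vessel_form"],
                    "lipid_concentration": float(row["lipid_concentration"]),
                    "heating": row["heating"] == "True",
                    "flags": flags,
                    "notes": notes.split(_NOTE_SEP) if notes else [],
                }
            )
        return out
    raise ValidationError(f"unsupported report format {format!r}")
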