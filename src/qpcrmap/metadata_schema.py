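"""Darwin-Core-aligned sample metadata: record type and validation.

Every qPCR reaction (one well) carries nine required fields. ``run_location``
(the well name, e.g. ``A1``) doubles as the primary key that joins metadata to
the raw fluorescence curves. Spatio-temporal fields follow Darwin Core
(``eventDate``, ``decimalLatitude``, ``decimalLongitude``, ``taxonID``);
unknown extra columns are carried through verbatim so study-specific fields
survive the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

from .core import SchemaError

#: The nine required fields, in canonical column order.
REQUIRED_FIELDS: tuple[str, ...] = (
    "run_location",
    "run_platform",
    "threshold",
    "organismScope",
    "eventDate",
    "decimalLatitude",
    "decimalLongitude",
    "taxonID",
    "species",
)

#: Optional Darwin Core fields given first-class treatment in map exports.
KNOWN_OPTIONAL_FIELDS: tuple[str, ...] = ("recordedBy", "vernacularName")

#: Column-name aliases accepted on input (both spellings occur in the wild).
COLUMN_ALIASES: dict[str, str] = {"decimalLongtitude": "decimalLongitude"}

#: Flag column marking assays that target a higher taxon (genus, family, ...)
#: rather than a single species; it relaxes the "Genus species" shape check.
HIGHER_TAXON_FLAG = "is_higher_taxon"

NCBI_TAXONOMY_URL = (
    "https://www.ncbi.nlm.nih.gov/Taxonomy/Browser/wwwtax.cgi?mode=Info&id={}"
)

_TRUE_TOKENS = {"true", "1", "yes", "y"}
_FALSE_TOKENS = {"false", "0", "no", "n", ""}


@dataclass
class MetadataRecord:
    """One sampling/assay event: a single qPCR well and its provenance."""

    run_location: str
    run_platform: str
    threshold: float
    organismScope: str
    eventDate: date
    decimalLatitude: float
    decimalLongitude: float
    taxonID: int | str
    species: str
    is_higher_taxon: bool = False
    #: Extra columns preserved verbatim (values kept as strings).
    extras: dict[str, str] = field(default_factory=dict)


def field_dictionary() -> dict[str, Any]:
    """Return the shipped metadata field dictionary (name -> description)."""
    text = resources.files("qpcrmap").joinpath("data/field_dictionary.json").read_text()
    return json.loads(text)


def taxonomy_link(taxon_id: int | str) -> str:
    """NCBI Taxonomy browser URL for a numeric taxonID; '' for user tokens.

    Higher-taxon assays may use user-created identifiers that have no NCBI
    page, so non-numeric (or non-positive) identifiers yield an empty string.
    """
    s = str(taxon_id).strip()
    if s.isdigit() and int(s) > 0:
        return NCBI_TAXONOMY_URL.format(int(s))
    return ""


def _coerce_taxon_id(raw: str) -> int | str:
    s = raw.strip()
    return int(s) if s.isdigit() else s


def _parse_bool(raw: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE_TOKENS:
        return True
    if s in _FALSE_TOKENS:
        return False
    raise ValueError(f"not a boolean flag: {raw!r}")


def record_from_mapping(row: Mapping[str, str]) -> MetadataRecord:
    """Build a MetadataRecord from one string-valued row mapping.

    Raises ``ValueError`` with a field-specific message on the first invalid
    field; :func:`validate_metadata` wraps this to collect problems per row.
    """
    problems = _row_problems(row)
    if problems:
        fld, msg = problems[0]
        raise ValueError(f"{fld}: {msg}")
    return _build_record(row)


def _row_problems(row: Mapping[str, str]) -> list[tuple[str, str]]:
    problems: list[tuple[str, str]] = []
    for fld in REQUIRED_FIELDS:
        if str(row.get(fld, "")).strip() == "":
            problems.append((fld, "required field is blank"))
    if problems:
        return problems

    try:
        thr = float(row["threshold"])
        if not thr > 0:
            problems.append(("threshold", "must be > 0"))
    except ValueError:
        problems.append(("threshold", "not a number"))

    try:
        lat = float(row["decimalLatitude"])
        if not -90.0 <= lat <= 90.0:
            problems.append(("decimalLatitude", "out of range [-90, 90]"))
    except ValueError:
        problems.append(("decimalLatitude", "not a number"))

    try:
        lon = float(row["decimalLongitude"])
        if not -180.0 <= lon <= 180.0:
            problems.append(("decimalLongitude", "out of range [-180, 180]"))
    except ValueError:
        problems.append(("decimalLongitude", "not a number"))

    try:
        date.fromisoformat(str(row["eventDate"]).strip())
    except ValueError:
        problems.append(("eventDate", "not an ISO 8601 date (YYYY-MM-DD)"))

    higher = False
    if HIGHER_TAXON_FLAG in row:
        try:
            higher = _parse_bool(row[HIGHER_TAXON_FLAG])
        except ValueError:
            problems.append((HIGHER_TAXON_FLAG, "not a boolean flag"))
    if not higher and " " not in str(row["species"]).strip():
        problems.append(
            ("species", "expected 'Genus species' (or set is_higher_taxon)")
        )
    return problems


def _build_record(row: Mapping[str, str]) -> MetadataRecord:
    higher = _parse_bool(row[HIGHER_TAXON_FLAG]) if HIGHER_TAXON_FLAG in row else False
    known = set(REQUIRED_FIELDS) | {HIGHER_TAXON_FLAG}
    extras = {
        k: str(v) for k, v in row.items() if k not in known and str(v).strip() != ""
    }
    return MetadataRecord(
        run_location=str(row["run_location"]).strip(),
        run_platform=str(row["run_platform"]).strip(),
        threshold=float(row["threshold"]),
        organismScope=str(row["organismScope"]).strip(),
        eventDate=date.fromisoformat(str(row["eventDate"]).strip()),
        decimalLatitude=float(row["decimalLatitude"]),
        decimalLongitude=float(row["decimalLongitude"]),
        taxonID=_coerce_taxon_id(str(row["taxonID"])),
        species=str(row["species"]).strip(),
        is_higher_taxon=higher,
        extras=extras,
    )


def _load_table(rows: pd.DataFrame | str | Path) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        path = Path(rows)
        if path.suffix.lower() in {".xlsx", ".xlsm", ".xls"}:
            df = pd.read_excel(path, dtype=str)
        else:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.rename(columns=COLUMN_ALIASES)
    return df.fillna("").astype(str)


def validate_metadata(
    rows: pd.DataFrame | str | Path,
) -> tuple[list[MetadataRecord], list[tuple[int, str, str]]]:
    """Validate a metadata table against the nine-required-field schema.

    Parameters
    ----------
    rows
        A DataFrame, or a path to a CSV/XLSX file with a header row.

    Returns
    -------
    (valid, problems)
        ``valid`` holds one :class:`MetadataRecord` per clean row; ``problems``
        holds ``(row_index, field, message)`` for every failed check. Each
        input row lands in exactly one of the two (a row with any problem is
        excluded from ``valid``).

    Raises
    ------
    SchemaError
        If a required column is missing entirely (whole-file failure).
    """
    df = _load_table(rows)
    missing = [f for f in REQUIRED_FIELDS if f not in df.columns]
    if missing:
        raise SchemaError(f"missing required metadata column(s): {', '.join(missing)}")

    valid: list[MetadataRecord] = []
    problems: list[tuple[int, str, str]] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        row_problems = _row_problems(row)
        if row_problems:
            problems.extend((idx, fld, msg) for fld, msg in row_problems)
        else:
            valid.append(_build_record(row))
    return valid, problems


def records_to_frame(records: Iterable[MetadataRecord]) -> pd.DataFrame:
    """Tabulate records with canonical column order (extras sorted last)."""
    records = list(records)
    extra_cols = sorted({k for r in records for k in r.extras})
    cols = list(REQUIRED_FIELDS) + [HIGHER_TAXON_FLAG] + extra_cols
    data = []
    for r in records:
        row = {
            "run_location": r.run_location,
            "run_platform": r.run_platform,
            "threshold": repr(r.threshold),
            "organismScope": r.organismScope,
            "eventDate": r.eventDate.isoformat(),
            "decimalLatitude": repr(r.decimalLatitude),
            "decimalLongitude": repr(r.decimalLongitude),
            "taxonID": str(r.taxonID),
            "species": r.species,
            HIGHER_TAXON_FLAG: "true" if r.is_higher_taxon else "false",
        }
        for c in extra_cols:
            row[c] = r.extras.get(c, "")
        data.append(row)
    return pd.DataFrame(data, columns=cols)
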