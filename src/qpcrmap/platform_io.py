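"""Raw fluorescence export parsing and merged-table CSV round trip.

Vendor exports differ mainly in orientation (wells as columns vs rows), the
label of the cycle axis, and how many banner rows precede the header. A
:class:`PlatformDescriptor` captures exactly that, so new instruments are a
configuration file, not a code change. Three canonical dialects ship built in:

``mic``
    Wells as columns; first column ``Cycle`` holds cycle numbers.
``biomeme2``
    Wells as rows; header ``Well,1,2,...`` carries the cycle numbers.
``biomeme3``
    As ``biomeme2`` but with one banner row above the header.

The merged table (metadata columns + ``fluorescence`` string + ``ct``) is the
pipeline's interchange format: each well's readings are serialized into a
single ``;``-separated string so the whole record fits one CSV row.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core import (
    NO_CROSSING,
    CurveParseError,
    EmptyRunError,
    SchemaError,
    StructureError,
)
from .metadata_schema import (
    HIGHER_TAXON_FLAG,
    REQUIRED_FIELDS,
    MetadataRecord,
    record_from_mapping,
    records_to_frame,
)

WELLS_AS_COLUMNS = "wells_as_columns"
WELLS_AS_ROWS = "wells_as_rows"

#: Default well-name shape: row letter(s) + column number, e.g. A1, P24.
DEFAULT_WELL_PATTERN = r"^[A-Za-z]{1,2}\d{1,2}$"


@dataclass(frozen=True)
class PlatformDescriptor:
    """Declarative description of one instrument's raw export layout."""

    platform_id: str
    orientation: str
    cycle_field: str
    well_label_pattern: str = DEFAULT_WELL_PATTERN
    header_rows_to_skip: int = 0
    sheet_name: str | None = None

    def __post_init__(self):
        if not self.platform_id:
            raise ValueError("platform_id must be nonempty")
        if self.orientation not in (WELLS_AS_COLUMNS, WELLS_AS_ROWS):
            raise ValueError(f"unknown orientation: {self.orientation!r}")
        if self.header_rows_to_skip < 0:
            raise ValueError("header_rows_to_skip must be >= 0")
        re.compile(self.well_label_pattern)  # must compile

    @property
    def well_regex(self) -> re.Pattern:
        return re.compile(self.well_label_pattern)


BUILTIN_DESCRIPTORS: dict[str, PlatformDescriptor] = {
    "mic": PlatformDescriptor(
        platform_id="mic",
        orientation=WELLS_AS_COLUMNS,
        cycle_field="Cycle",
    ),
    "biomeme2": PlatformDescriptor(
        platform_id="biomeme2",
        orientation=WELLS_AS_ROWS,
        cycle_field="Well",
    ),
    "biomeme3": PlatformDescriptor(
        platform_id="biomeme3",
        orientation=WELLS_AS_ROWS,
        cycle_field="Well",
        header_rows_to_skip=1,
    ),
}


def get_descriptor(platform_id: str) -> PlatformDescriptor:
    try:
        return BUILTIN_DESCRIPTORS[platform_id]
    except KeyError:
        raise KeyError(
            f"unknown platform {platform_id!r}; "
            f"built-ins: {', '.join(sorted(BUILTIN_DESCRIPTORS))}"
        ) from None


def descriptor_from_json(path: str | Path) -> PlatformDescriptor:
    """Load a user-defined platform descriptor from a JSON file."""
    with open(path) as fh:
        payload = json.load(fh)
    return PlatformDescriptor(**payload)


def descriptor_to_json(descriptor: PlatformDescriptor, path: str | Path) -> None:
    payload = {
        "platform_id": descriptor.platform_id,
        "orientation": descriptor.orientation,
        "cycle_field": descriptor.cycle_field,
        "well_label_pattern": descriptor.well_label_pattern,
        "header_rows_to_skip": descriptor.header_rows_to_skip,
        "sheet_name": descriptor.sheet_name,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


@dataclass(frozen=True)
class FluorescenceCurve:
    """Ordered cycle -> fluorescence readings for one well."""

    well_id: str
    cycles: tuple[int, ...]
    readings: tuple[float, ...]

    def __post_init__(self):
        if len(self.readings) != len(self.cycles):
            raise ValueError(
                f"well {self.well_id}: {len(self.readings)} readings "
                f"for {len(self.cycles)} cycles"
            )
        if len(self.cycles) < 2:
            raise ValueError(f"well {self.well_id}: need at least 2 cycles")
        if any(c2 <= c1 for c1, c2 in zip(self.cycles, self.cycles[1:])):
            raise ValueError(f"well {self.well_id}: cycles not strictly increasing")
        if self.cycles[0] <= 0:
            raise ValueError(f"well {self.well_id}: cycles must be positive")
        if not all(math.isfinite(r) for r in self.readings):
            raise ValueError(f"well {self.well_id}: non-finite reading")


@dataclass
class RawRun:
    """All curves parsed from one raw export, keyed by well name."""

    platform_id: str
    curves: dict[str, FluorescenceCurve]
    #: Labels present in the file that failed the well-name pattern.
    rejected_wells: tuple[str, ...] = ()


def _read_raw_frame(path: Path, descriptor: PlatformDescriptor) -> pd.DataFrame:
    if descriptor.sheet_name is not None or path.suffix.lower() in {".xlsx", ".xlsm"}:
        df = pd.read_excel(
            path,
            sheet_name=descriptor.sheet_name or 0,
            skiprows=descriptor.header_rows_to_skip,
            dtype=str,
        )
    else:
        df = pd.read_csv(
            path,
            skiprows=descriptor.header_rows_to_skip,
            dtype=str,
            keep_default_na=False,
        )
    return df.fillna("")

def _parse_cycles(tokens: Sequence[str], context: str) -> tuple[int, ...]:
    cycles = []
    for tok in tokens:
        try:
            val = int(float(tok))
            if float(tok) != val:
                raise ValueError
        except ValueError:
            raise StructureError(f"{context}: non-integer cycle value {tok!r}")
        cycles.append(val)
    if any(b <= a for a, b in zip(cycles, cycles[1:])):
        raise StructureError(f"{context}: cycle values not strictly increasing")
    if cycles and cycles[0] <= 0:
        raise StructureError(f"{context}: cycle values must be positive")
    return tuple(cycles)


def _parse_readings(tokens: Sequence[str], well: str) -> tuple[float, ...]:
    readings = []
    for i, tok in enumerate(tokens):
        try:
            val = float(tok)
        except ValueError:
            raise StructureError(
                f"well {well}: non-numeric reading {tok!r} at position {i + 1}"
            )
        if not math.isfinite(val):
            raise StructureError(f"well {well}: non-finite reading at position {i + 1}")
        readings.append(val)
    return tuple(readings)


def parse_raw_run(path: str | Path, descriptor: PlatformDescriptor) -> RawRun:
    """Parse a raw fluorescence export into a :class:`RawRun`.

    Well labels that fail the descriptor's pattern are collected in
    ``RawRun.rejected_wells`` (never silently dropped). Raises
    :class:`EmptyRunError` when nothing matches and :class:`StructureError`
    on ragged or non-numeric content, naming the offending well.
    """
    path = Path(path)
    df = _read_raw_frame(path, descriptor)
    pattern = descriptor.well_regex
    curves: dict[str, FluorescenceCurve] = {}
    rejected: list[str] = []

    if descriptor.orientation == WELLS_AS_COLUMNS:
        if descriptor.cycle_field not in df.columns:
            raise StructureError(
                f"cycle column {descriptor.cycle_field!r} not found in {path.name}"
            )
        cycle_rows = [str(v).strip() for v in df[descriptor.cycle_field]]
        cycles = _parse_cycles(cycle_rows, f"cycle column {descriptor.cycle_field!r}")
        for col in df.columns:
            if col == descriptor.cycle_field:
                continue
            label = str(col).strip()
            if not pattern.match(label):
                rejected.append(label)
                continue
            readings = _parse_readings([str(v).strip() for v in df[col]], label)
            _check_unique(label, curves)
            curves[label] = FluorescenceCurve(label, cycles, readings)
    else:
        header = list(df.columns)
        if not header or str(header[0]).strip() != descriptor.cycle_field:
            raise StructureError(
                f"expected first header cell {descriptor.cycle_field!r} "
                f"in {path.name}, found {header[0]!r}" if header
                else f"empty file {path.name}"
            )
        cycles = _parse_cycles(
            [str(h).strip() for h in header[1:]], "header cycle row"
        )
        for _, row in df.iterrows():
            label = str(row.iloc[0]).strip()
            if not pattern.match(label):
                rejected.append(label)
                continue
            readings = _parse_readings(
                [str(v).strip() for v in row.iloc[1:]], label
            )
            _check_unique(label, curves)
            curves[label] = FluorescenceCurve(label, cycles, readings)

    if not curves:
        raise EmptyRunError(
            f"no well matching pattern {descriptor.well_label_pattern!r} "
            f"in {path.name}"
        )
    return RawRun(descriptor.platform_id, curves, tuple(rejected))


def _check_unique(label: str, curves: dict) -> None:
    if label in curves:
        raise StructureError(f"duplicate well {label} in raw run")


# ---------------------------------------------------------------------------
# Curve string serialization (one well -> one CSV cell)
# ---------------------------------------------------------------------------

def serialize_curve(curve: FluorescenceCurve) -> str:
    """Join readings in cycle order with ';', shortest round-trip decimals."""
    return ";".join(repr(float(r)) for r in curve.readings)


def deserialize_curve(
    text: str, start_cycle: int = 1, well_id: str = ""
) -> FluorescenceCurve:
    """Inverse of :func:`serialize_curve`; cycles numbered from ``start_cycle``."""
    tokens = text.split(";")
    readings = []
    for i, tok in enumerate(tokens):
        try:
            readings.append(float(tok))
        except ValueError:
            raise CurveParseError(
                f"non-numeric token {tok!r} at position {i + 1}", token_index=i + 1
            )
    cycles = tuple(range(start_cycle, start_cycle + len(readings)))
    return FluorescenceCurve(well_id, cycles, tuple(readings))


# ---------------------------------------------------------------------------
# Merged table (metadata + fluorescence string + ct)
# ---------------------------------------------------------------------------

@dataclass
class MergedRecord:
    """One merged-table row: metadata + raw curve + computed Ct."""

    metadata: MetadataRecord
    curve: FluorescenceCurve
    ct: float | object  # float or NO_CROSSING

    def __post_init__(self):
        if self.metadata.run_location.split("#")[0] != self.curve.well_id:
            raise ValueError(
                f"run_location {self.metadata.run_location!r} does not match "
                f"curve well {self.curve.well_id!r}"
            )


def _format_ct(ct) -> str:
    return "" if ct is NO_CROSSING else repr(float(ct))


def _parse_ct(raw: str):
    raw = raw.strip()
    return NO_CROSSING if raw == "" else float(raw)


def merged_to_frame(records: Sequence[MergedRecord]) -> pd.DataFrame:
    """Merged records as a DataFrame (metadata columns, fluorescence, ct)."""
    meta = records_to_frame([r.metadata for r in records])
    meta["fluorescence"] = [serialize_curve(r.curve) for r in records]
    meta["ct"] = [_format_ct(r.ct) for r in records]
    return meta


def write_merged_table(records: Sequence[MergedRecord], path: str | Path) -> None:
    """Write records as the canonical merged CSV (header always present)."""
    merged_to_frame(records).to_csv(path, index=False)


def read_merged_table(path: str | Path) -> list[MergedRecord]:
    """Read a merged CSV back into records.

    Curves are reconstructed from the fluorescence string with contiguous
    1-based cycles (the canonical numbering of every shipped dialect).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return frame_to_merged(df)


def frame_to_merged(df: pd.DataFrame) -> list[MergedRecord]:
    missing = [
        c for c in (*REQUIRED_FIELDS, "fluorescence", "ct") if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"merged table missing column(s): {', '.join(missing)}")
    records = []
    for row in df.to_dict(orient="records"):
        fluor = row.pop("fluorescence")
        ct = _parse_ct(row.pop("ct"))
        meta = record_from_mapping(row)
        curve = deserialize_curve(fluor, well_id=meta.run_location.split("#")[0])
        records.append(MergedRecord(metadata=meta, curve=curve, ct=ct))
    return records
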