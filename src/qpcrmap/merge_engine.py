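"""Join raw fluorescence curves to metadata rows and compute Ct.

The well name (``run_location``) is the primary key. The join is 1:1:
duplicate keys in the metadata are an error, and wells or metadata rows
without a partner are collected in an :class:`OrphanReport` (strict mode
turns any orphan into an error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import KeyCollisionError, MergeError, SchemaError
from .ct_engine import ct_from_curve
from .metadata_schema import MetadataRecord
from .platform_io import MergedRecord, RawRun


@dataclass(frozen=True)
class OrphanReport:
    """Wells without metadata and metadata rows without wells."""

    unmatched_wells: tuple[str, ...]
    unmatched_metadata: tuple[str, ...]

    def __bool__(self) -> bool:
        return bool(self.unmatched_wells or self.unmatched_metadata)


def merge_run(
    run: RawRun, metadata: Sequence[MetadataRecord], strict: bool = False
) -> tuple[list[MergedRecord], OrphanReport]:
    """Merge one parsed run with validated metadata.

    Each matched well yields a :class:`MergedRecord` whose Ct is computed
    against that row's own threshold. Output rows are sorted by
    ``run_location`` so the merge is deterministic.
    """
    keys = [m.run_location for m in metadata]
    dupes = sorted({k for k in keys if keys.count(k) > 1})
    if dupes:
        raise KeyCollisionError(
            f"duplicate run_location in metadata: {', '.join(dupes)}"
        )
    by_key = {m.run_location: m for m in metadata}

    matched = sorted(set(by_key) & set(run.curves))
    orphans = OrphanReport(
        unmatched_wells=tuple(sorted(set(run.curves) - set(by_key))),
        unmatched_metadata=tuple(sorted(set(by_key) - set(run.curves))),
    )
    if strict and orphans:
        raise MergeError(
            f"orphans under strict merge: wells {list(orphans.unmatched_wells)}, "
            f"metadata {list(orphans.unmatched_metadata)}"
        )

    records = []
    for key in matched:
        meta = by_key[key]
        curve = run.curves[key]
        records.append(
            MergedRecord(
                metadata=meta, curve=curve, ct=ct_from_curve(curve, meta.threshold)
            )
        )
    return records, orphans


def combine_merged(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate merged tables from separate runs into one.

    All tables must share the merged schema (same columns, same order).
    ``run_location`` stays the unique primary key: a key already seen in an
    earlier table is suffixed with ``#k`` where ``k`` is the (0-based) index
    of the table it came from.
    """
    if not tables:
        raise ValueError("no tables to combine")
    ref_cols = list(tables[0].columns)
    for t in tables[1:]:
        cols = list(t.columns)
        if cols != ref_cols:
            diff = next(
                (a for a, b in zip(cols, ref_cols) if a != b),
                (cols + ref_cols)[min(len(cols), len(ref_cols))],
            )
            raise SchemaError(f"merged tables differ at column {diff!r}")

    seen: set[str] = set()
    out_frames = []
    for k, t in enumerate(tables):
        t = t.copy()
        new_keys = []
        for key in t["run_location"].astype(str):
            if key in seen:
                key = f"{key}#{k}"
            seen.add(key)
            new_keys.append(key)
        t["run_location"] = new_keys
        out_frames.append(t)
    return pd.concat(out_frames, ignore_index=True)
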