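"""Reading, writing and validation of annotated heavy-chain rearrangements.

One record is one sequenced V(D)J rearrangement; because the underlying
material is genomic DNA, one rearrangement corresponds to one B cell, and
``duplicate_count`` carries the number of cells observed with an identical
sequence.

Internally all intervals (framework/CDR regions, N regions) are 0-based
half-open on the ungapped ``sequence``. On disk the AIRR Rearrangement
convention is used: tab-separated with a header row, 1-based closed
coordinates, booleans written ``T``/``F``. ``gc_id``, ``replicate_id`` and
the N-region columns (``n1_start`` ...) are extension columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3", "cdr3", "fwr4")

#: on-disk column order (stable; AIRR core columns first)
COLUMNS = (
    ["sequence_id", "sequence", "v_call", "j_call", "junction",
     "junction_length", "vj_in_frame", "duplicate_count"]
    + [f"{r}_{w}" for r in REGIONS for w in ("start", "end")]
    + ["n1_start", "n1_end", "n2_start", "n2_end", "gc_id", "replicate_id"]
)


class FormatError(ValueError):
    """The file does not conform to the expected AIRR dialect."""


class ValidationError(ValueError):
    """One or more rows violate record invariants."""


@dataclass
class RearrangementRecord:
    """One annotated V(D)J rearrangement (= one B cell)."""

    sequence_id: str
    gc_id: str
    replicate_id: str
    sequence: str
    v_call: str
    j_call: str
    junction: str
    junction_length: int
    region_bounds: dict[str, tuple[int, int]]
    n_region_bounds: list[tuple[int, int]] = field(default_factory=list)
    in_frame_junction: bool = True
    duplicate_count: int = 1

    @property
    def junction_span(self) -> tuple[int, int] | None:
        """Span of the junction on ``sequence`` (conserved C to conserved W)."""
        cdr3 = self.region_bounds.get("cdr3")
        if cdr3 is None:
            return None
        return (cdr3[0] - 3, cdr3[1] + 3)


def validate_record(rec: RearrangementRecord) -> list[str]:
    """Return a list of invariant violations (empty when the record is valid)."""
    problems: list[str] = []
    if rec.junction_length != len(rec.junction):
        problems.append(
            f"junction_length={rec.junction_length} but junction has "
            f"{len(rec.junction)} nt"
        )
    if rec.in_frame_junction and rec.junction_length % 3 != 0:
        problems.append("in-frame junction whose length is not a multiple of 3")
    if rec.duplicate_count < 1:
        problems.append("duplicate_count must be >= 1")
    n = len(rec.sequence)
    prev_end = 0
    prev_name = None
    for name in REGIONS:
        if name not in rec.region_bounds:
            continue
        start, end = rec.region_bounds[name]
        if not (0 <= start < end <= n):
            problems.append(f"region {name} interval ({start},{end}) outside sequence")
        if start < prev_end:
            problems.append(f"region {name} overlaps or precedes {prev_name}")
        prev_end, prev_name = end, name
    span = rec.junction_span
    for i, (start, end) in enumerate(rec.n_region_bounds, start=1):
        if span is None or not (span[0] <= start < end <= span[1]):
            problems.append(f"N{i} interval ({start},{end}) outside the junction span")
    return problems


def _row_of(rec: RearrangementRecord) -> dict:
    row: dict = {
        "sequence_id": rec.sequence_id,
        "sequence": rec.sequence,
        "v_call": rec.v_call,
        "j_call": rec.j_call,
        "junction": rec.junction,
        "junction_length": rec.junction_length,
        "vj_in_frame": "T" if rec.in_frame_junction else "F",
        "duplicate_count": rec.duplicate_count,
        "gc_id": rec.gc_id,
        "replicate_id": rec.replicate_id,
    }
    for r in REGIONS:
        if r in rec.region_bounds:
            s, e = rec.region_bounds[r]
            row[f"{r}_start"], row[f"{r}_end"] = s + 1, e  # 1-based closed
        else:
            row[f"{r}_start"] = row[f"{r}_end"] = ""
    for i in (1, 2):
        if len(rec.n_region_bounds) >= i:
            s, e = rec.n_region_bounds[i - 1]
            row[f"n{i}_start"], row[f"n{i}_end"] = s + 1, e
        else:
            row[f"n{i}_start"] = row[f"n{i}_end"] = ""
    return row


def _record_of(row: pd.Series) -> RearrangementRecord:
    bounds = {}
    for r in REGIONS:
        s, e = row[f"{r}_start"], row[f"{r}_end"]
        if s != "" and e != "":
            bounds[r] = (int(s) - 1, int(e))
    n_bounds = []
    for i in (1, 2):
        s, e = row[f"n{i}_start"], row[f"n{i}_end"]
        if s != "" and e != "":
            n_bounds.append((int(s) - 1, int(e)))
    return RearrangementRecord(
        sequence_id=str(row["sequence_id"]),
        gc_id=str(row["gc_id"]),
        replicate_id=str(row["replicate_id"]),
        sequence=str(row["sequence"]),
        v_call=str(row["v_call"]),
        j_call=str(row["j_call"]),
        junction=str(row["junction"]),
        junction_length=int(row["junction_length"]),
        region_bounds=bounds,
        n_region_bounds=n_bounds,
        in_frame_junction=str(row["vj_in_frame"]).upper() in ("T", "TRUE"),
        duplicate_count=int(row["duplicate_count"]),
    )


def read_rearrangements(path: str | Path, strict: bool = False) -> list[RearrangementRecord]:
    """Read an AIRR Rearrangement TSV.

    Rows violating record invariants are dropped with a logged diagnostic
    (QC-filter behaviour); pass ``strict=True`` to raise instead.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[RearrangementRecord] = []
    bad: list[str] = []
    for _, row in df.iterrows():
        rec = _record_of(row)
        problems = validate_record(rec)
        if problems:
            bad.append(f"{rec.sequence_id}: {'; '.join(problems)}")
        else:
            records.append(rec)
    if bad:
        msg = f"{path}: rejected {len(bad)} row(s): " + " | ".join(bad[:10])
        if strict:
            raise ValidationError(msg)
        logger.warning(msg)
    return records


def write_rearrangements(records: list[RearrangementRecord], path: str | Path) -> None:
    """Write records as an AIRR Rearrangement TSV with a stable column order."""
    df = pd.DataFrame([_row_of(r) for r in records], columns=list(COLUMNS))
    df.to_csv(Path(path), sep="\t", index=False)
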