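"""Prophage coordinate parsing and validation.

A prophage is an integrated temperate-phage genome described by a half-closed
interval on a host scaffold.  Two input dialects are supported: a minimal
manual TSV (``scaffold  fragment  start  stop``) and the integrated-prophage
coordinate table emitted by the VIBRANT prophage predictor.  All user-facing
coordinates are 1-based inclusive, matching prophage-prediction tool output;
0-based half-open positions are derived on demand for array slicing.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import CoordinateValidationError, FormatError

logger = logging.getLogger(__name__)

MANUAL_COLUMNS = ("scaffold", "fragment", "start", "stop")

#: Reasons attached to prophages excluded from analysis.
REASON_PROPHAGE_SHORT = "prophage below minimum length"
REASON_HOST_SHORT = "host region below minimum length"
REASON_SCAFFOLD_MASKED_OUT = "scaffold shorter than twice the end mask"
REASON_SCAFFOLD_UNKNOWN = "scaffold not present in reference"


@dataclass(frozen=True)
class ProphageCoordinate:
    """One prophage's location on its host scaffold (1-based inclusive)."""

    prophage_id: str
    scaffold_id: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateValidationError(
                f"{self.prophage_id}: start must be >= 1, got {self.start}"
            )
        if self.stop < self.start:
            raise CoordinateValidationError(
                f"{self.prophage_id}: stop {self.stop} < start {self.start}"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start + 1

    @property
    def slice0(self) -> slice:
        """0-based half-open slice of the prophage interval."""
        return slice(self.start - 1, self.stop)


@dataclass
class ScaffoldRecord:
    """A host scaffold together with the prophages integrated in it."""

    scaffold_id: str
    length: int
    prophages: list[ProphageCoordinate] = field(default_factory=list)


def _parse_row(fields: Sequence[str], colmap: Mapping[str, int], lineno: int) -> ProphageCoordinate:
    try:
        start = int(fields[colmap["start"]])
        stop = int(fields[colmap["stop"]])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer coordinate ({exc})") from exc
    if start > stop:
        logger.warning(
            "line %d: start %d > stop %d; interval ends swapped", lineno, start, stop
        )
        start, stop = stop, start
    return ProphageCoordinate(
        prophage_id=fields[colmap["fragment"]],
        scaffold_id=fields[colmap["scaffold"]],
        start=start,
        stop=stop,
    )


def _check_unique(coords: Sequence[ProphageCoordinate]) -> None:
    seen: set[str] = set()
    for c in coords:
        if c.prophage_id in seen:
            raise CoordinateValidationError(f"duplicate fragment id: {c.prophage_id}")
        seen.add(c.prophage_id)


def parse_manual_coordinates(path: str | os.PathLike) -> list[ProphageCoordinate]:
    """Parse the manual coordinate dialect.

    Tab-separated with a header naming the columns ``scaffold``, ``fragment``,
    ``start`` and ``stop`` (any order, case-insensitive).  Rows with
    ``start > stop`` are treated as unordered interval ends and swapped with a
    warning.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        names = [h.strip().lower() for h in header.split("\t")]
        missing = [c for c in MANUAL_COLUMNS if c not in names]
        if missing:
            raise FormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        colmap = {c: names.index(c) for c in MANUAL_COLUMNS}
        coords = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(names):
                raise FormatError(f"{path}: line {lineno}: expected {len(names)} fields")
            coords.append(_parse_row(fields, colmap, lineno))
    if not coords:
        logger.warning("%s: zero prophages supplied", path)
    _check_unique(coords)
    return coords


# Column headers used by VIBRANT's integrated_prophage_coordinates table.
_VIBRANT_COLS = {
    "scaffold": "scaffold",
    "fragment": "fragment",
    "nucleotide start": "start",
    "nucleotide stop": "stop",
}


def parse_vibrant_coordinates(path: str | os.PathLike) -> list[ProphageCoordinate]:
    """Parse a VIBRANT integrated-prophage coordinate table.

    ``path`` may be the table itself or a VIBRANT results directory, which is
    searched (recursively) for ``*integrated_prophage_coordinates*.tsv``.
    Fragment ids follow VIBRANT's ``<scaffold>_fragment_<n>`` convention and
    are preserved verbatim.
    """
    path = Path(path)
    if path.is_dir():
        candidates = sorted(path.rglob("*integrated_prophage_coordinates*.tsv"))
        if not candidates:
            raise FileNotFoundError(
                f"{path}: no integrated-prophage coordinate table found; "
                "supply a manual coordinate TSV instead"
            )
        path = candidates[0]
    if not path.exists():
        raise FileNotFoundError(
            f"{path}: coordinate table not found; supply a manual coordinate TSV instead"
        )
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        names = [h.strip().lower() for h in header.split("\t")]
        missing = [c for c in _VIBRANT_COLS if c not in names]
        if missing:
            raise FormatError(
                f"{path}: unrecognized column layout; missing {', '.join(missing)}"
            )
        colmap = {std: names.index(raw) for raw, std in _VIBRANT_COLS.items()}
        coords = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            coords.append(_parse_row(line.split("\t"), colmap, lineno))
    _check_unique(coords)
    return coords


def write_manual_coordinates(
    coords: Iterable[ProphageCoordinate], path: str | os.PathLike
) -> None:
    """Write coordinates in the manual TSV dialect (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("scaffold\tfragment\tstart\tstop\n")
        for c in coords:
            fh.write(f"{c.scaffold_id}\t{c.prophage_id}\t{c.start}\t{c.stop}\n")


def read_scaffold_lengths(fasta: str | os.PathLike) -> dict[str, int]:
    """Scaffold id -> length from a (multi-)FASTA file."""
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}


def attach_and_validate(
    coords: Sequence[ProphageCoordinate],
    scaffold_lengths: Mapping[str, int],
    *,
    min_region_len: int = 1000,
    mask_len: int = 150,
) -> tuple[list[ScaffoldRecord], dict[str, str]]:
    """Group coordinates by scaffold and apply the analyzability rules.

    Both the prophage and the residual (prophage-excluded, end-masked) host
    region must reach ``min_region_len``.  Prophages failing a rule are kept in
    the returned records but flagged with an explicit reason so that downstream
    reporting can surface them rather than silently dropping them.  Coordinates
    running past the scaffold end are clipped with a warning; overlapping
    prophage intervals on one scaffold are rejected because the host
    segmentation model assumes disjoint intervals.

    Returns ``(records, flags)`` where ``flags`` maps prophage_id -> reason for
    every prophage excluded from analysis.
    """
    _check_unique(coords)
    unknown = sorted({c.scaffold_id for c in coords} - set(scaffold_lengths))
    if unknown:
        raise CoordinateValidationError(
            "scaffold id(s) absent from reference: " + ", ".join(unknown)
        )

    by_scaffold: dict[str, list[ProphageCoordinate]] = {}
    for c in coords:
        length = scaffold_lengths[c.scaffold_id]
        if c.start > length:
            raise CoordinateValidationError(
                f"{c.prophage_id}: start {c.start} beyond scaffold end {length}"
            )
        if c.stop > length:
            logger.warning(
                "%s: stop %d beyond scaffold end %d; clipped",
                c.prophage_id, c.stop, length,
            )
            c = ProphageCoordinate(c.prophage_id, c.scaffold_id, c.start, length)
        by_scaffold.setdefault(c.scaffold_id, []).append(c)

    records: list[ScaffoldRecord] = []
    flags: dict[str, str] = {}
    for scaffold_id in sorted(by_scaffold):
        prophages = sorted(by_scaffold[scaffold_id], key=lambda c: (c.start, c.stop))
        length = scaffold_lengths[scaffold_id]
        for prev, cur in zip(prophages, prophages[1:]):
            if cur.start <= prev.stop:
                raise CoordinateValidationError(
                    f"overlapping prophage intervals on {scaffold_id}: "
                    f"{prev.prophage_id} and {cur.prophage_id}"
                )
        record = ScaffoldRecord(scaffold_id, length, prophages)
        records.append(record)

        if length <= 2 * mask_len:
            for c in prophages:
                flags[c.prophage_id] = REASON_SCAFFOLD_MASKED_OUT
            continue
        # Host positions: interior (end-masked) minus the union of prophages.
        interior = length - 2 * mask_len
        prophage_interior = sum(
            max(0, min(c.stop, length - mask_len) - max(c.start, mask_len + 1) + 1)
            for c in prophages
        )
        host_len = interior - prophage_interior
        for c in prophages:
            if c.length < min_region_len:
                flags[c.prophage_id] = REASON_PROPHAGE_SHORT
            elif host_len < min_region_len:
                flags[c.prophage_id] = REASON_HOST_SHORT
    return records, flags
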