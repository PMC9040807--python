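"""Read-alignment processing: identity filtering and per-base depth.

The coverage statistics downstream compare mean read depth between a prophage
interval and its flanking host region, so depth must be computed per
nucleotide with zero-coverage positions retained.  Reads are first filtered by
alignment percent identity

    identity = (l - g - m) / l * 100

where *l* is the number of alignment columns (read-consuming plus gap
columns, soft/hard clips excluded), *g* the number of gap columns (inserted
plus deleted bases) and *m* the number of mismatched columns.  *m* is derived
from the standard ``NM`` edit-distance tag as ``NM - g``; records carrying
neither ``NM`` nor an ``MD`` string are excluded with a run-level count.

Reads whose identity falls below the threshold (default 97%) are removed —
the filter is meant to keep accurately aligned reads while tolerating minor
sequencing errors.  The lower bound is closed: a read at exactly the
threshold is retained.
"""

from __future__ import annotations

import logging
import os
import re
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam

from .errors import AlignerNotFoundError, AlignmentError, ComputationError

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 97.0

# CIGAR operation codes (pysam numeric encoding).
_OP_ALIGNED = {0, 7, 8}   # M, =, X : consume read and reference
_OP_INS = 1               # I      : consumes read only
_OP_DEL = 2               # D      : consumes reference only
_OP_REFSKIP = 3           # N


def percent_identity(l: int, g: int, m: int) -> float:
    """Alignment percent identity: ``(l - g - m) / l * 100``.

    ``l`` alignment columns, ``g`` gap columns, ``m`` mismatch columns.
    """
    if l <= 0:
        raise ComputationError("percent identity undefined for zero-length alignment")
    if g < 0 or m < 0 or g + m > l:
        raise ComputationError(f"inconsistent alignment counts l={l} g={g} m={m}")
    return (l - g - m) / l * 100.0


@dataclass(frozen=True)
class AlignedReadView:
    """Minimal view of one aligned read, sufficient for depth and identity.

    ``blocks`` are 0-based half-open reference intervals covered by read
    bases; deletion columns are excluded, so depth counts only positions under
    an actual read base.
    """

    reference_id: str
    reference_start: int
    blocks: tuple[tuple[int, int], ...]
    alignment_length: int  # l
    mismatches: int        # m
    gaps: int              # g

    @property
    def identity(self) -> float:
        return percent_identity(self.alignment_length, self.gaps, self.mismatches)

    @property
    def aligned_ref_bases(self) -> int:
        """Reference positions covered by read bases (sum of block lengths)."""
        return sum(e - s for s, e in self.blocks)


@dataclass
class FilterCounts:
    """Accounting of records seen by the identity filter."""

    total: int = 0
    excluded_unmapped: int = 0     # unmapped, secondary or supplementary
    excluded_identity: int = 0
    excluded_missing_tags: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


_MD_MISMATCH = re.compile(r"[ACGTN]")


def _mismatches_from_md(md: str) -> int:
    # Mismatched reference bases appear as letters outside ^-deletion runs.
    n = 0
    for part in re.split(r"\^[ACGTN]+", md):
        n += len(_MD_MISMATCH.findall(part))
    return n


def view_from_segment(seg: pysam.AlignedSegment) -> AlignedReadView | None:
    """Build an :class:`AlignedReadView` from a SAM/BAM record.

    Returns ``None`` when the record carries neither an ``NM`` tag nor an
    ``MD`` string, in which case mismatches cannot be derived.
    """
    cig = seg.cigartuples
    if not cig:
        return None
    aligned = ins = dele = 0
    blocks: list[tuple[int, int]] = []
    pos = seg.reference_start
    for op, ln in cig:
        if op in _OP_ALIGNED:
            blocks.append((pos, pos + ln))
            pos += ln
            aligned += ln
        elif op == _OP_INS:
            ins += ln
        elif op == _OP_DEL:
            dele += ln
            pos += ln
        elif op == _OP_REFSKIP:
            pos += ln
        # S/H/P consume neither reference nor alignment columns
    l = aligned + ins + dele
    g = ins + dele
    if seg.has_tag("NM"):
        m = int(seg.get_tag("NM")) - g
    elif seg.has_tag("MD"):
        m = _mismatches_from_md(str(seg.get_tag("MD")))
    else:
        return None
    m = max(m, 0)
    return AlignedReadView(
        reference_id=seg.reference_name,
        reference_start=seg.reference_start,
        blocks=tuple(blocks),
        alignment_length=l,
        mismatches=m,
        gaps=g,
    )


def filter_alignments(
    alignment: str | os.PathLike | pysam.AlignmentFile,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    counts: FilterCounts | None = None,
) -> Iterator[AlignedReadView]:
    """Yield identity-filtered read views from a SAM/BAM file.

    Unmapped, secondary and supplementary records are excluded; both mates of
    a proper pair are counted independently.  Records below ``min_identity``
    are dropped (closed lower bound: identity == threshold is retained).
    """
    own = not isinstance(alignment, pysam.AlignmentFile)
    af = (
        pysam.AlignmentFile(str(alignment), check_sq=False)
        if own
        else alignment
    )
    counts = counts if counts is not None else FilterCounts()
    missing_logged = False
    try:
        for seg in af.fetch(until_eof=True):
            counts.total += 1
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                counts.excluded_unmapped += 1
                continue
            view = view_from_segment(seg)
            if view is None:
                counts.excluded_missing_tags += 1
                if not missing_logged:
                    logger.warning(
                        "record %s lacks NM/MD tags; such records are excluded",
                        seg.query_name,
                    )
                    missing_logged = True
                continue
            if view.identity < min_identity:
                counts.excluded_identity += 1
                continue
            counts.retained += 1
            yield view
    finally:
        if own:
            af.close()
    if counts.excluded_missing_tags:
        logger.warning(
            "%d record(s) excluded for missing NM/MD tags", counts.excluded_missing_tags
        )


@dataclass
class DepthProfile:
    """Per-nucleotide read depth over one scaffold, zeros included."""

    scaffold_id: str
    depth: np.ndarray  # int64, length == scaffold length

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)

    @property
    def length(self) -> int:
        return int(self.depth.size)


def compute_depth(
    reads: Iterable[AlignedReadView], scaffold_lengths: Mapping[str, int]
) -> dict[str, DepthProfile]:
    """Per-base depth for every scaffold, including uncovered scaffolds.

    ``depth[i]`` counts retained reads whose aligned blocks cover position
    ``i`` (0-based); deletion columns inside a read do not contribute.  The
    sum of a profile equals the total reference-consuming aligned bases of
    the reads mapped to that scaffold.
    """
    arrays = {
        sid: np.zeros(length, dtype=np.int64)
        for sid, length in scaffold_lengths.items()
    }
    for view in reads:
        arr = arrays.get(view.reference_id)
        if arr is None:
            raise ComputationError(
                f"read maps to unknown scaffold {view.reference_id!r}"
            )
        for s, e in view.blocks:
            arr[s:e] += 1
    return {sid: DepthProfile(sid, arr) for sid, arr in arrays.items()}


# ---------------------------------------------------------------------------
# External aligner orchestration
# ---------------------------------------------------------------------------

#: Supported aligner backends in auto-detection order.
ALIGNERS = ("bowtie2", "minimap2", "bwa")


def _detect_aligner() -> str:
    for name in ALIGNERS:
        if shutil.which(name):
            return name
    raise AlignerNotFoundError(
        "no supported read aligner found on PATH (looked for: "
        + ", ".join(ALIGNERS)
        + ")"
    )


def _run(cmd: list[str], log: list[str], stdout=None) -> None:
    log.append(" ".join(cmd))
    logger.info("running: %s", " ".join(cmd))
    proc = subprocess.run(cmd, stdout=stdout, stderr=subprocess.PIPE, text=stdout is None)
    if proc.returncode != 0:
        stderr = proc.stderr if isinstance(proc.stderr, str) else proc.stderr.decode()
        raise AlignmentError(f"{cmd[0]} exited {proc.returncode}: {stderr.strip()}")


def _check_reads_nonempty(reads: Iterable[str | os.PathLike]) -> None:
    for r in reads:
        p = Path(r)
        if not p.exists():
            raise FileNotFoundError(p)
        if p.stat().st_size == 0:
            raise AlignmentError(f"read file is empty: {p}")


def align_reads(
    scaffolds_fasta: str | os.PathLike,
    reads: list[str | os.PathLike],
    *,
    paired: bool = False,
    threads: int = 1,
    out_prefix: str | os.PathLike,
    aligner: str | None = None,
) -> Path:
    """Align short reads to the scaffolds and return a sorted BAM path.

    Thin orchestration over an external aligner (auto-detected among
    bowtie2, minimap2 ``-ax sr`` and bwa mem); every command line executed is
    logged verbatim so a run can be reproduced or replaced by a user-supplied
    SAM/BAM, which downstream code treats identically.
    """
    _check_reads_nonempty(reads)
    if paired and len(reads) != 2:
        raise ValueError("paired mode requires exactly two read files")
    aligner = aligner or _detect_aligner()
    if shutil.which(aligner) is None:
        raise AlignerNotFoundError(f"required aligner executable not found: {aligner}")
    fasta = str(scaffolds_fasta)
    out_prefix = Path(out_prefix)
    sam = out_prefix.with_suffix(".sam")
    bam = out_prefix.with_suffix(".bam")
    cmds: list[str] = []
    reads = [str(r) for r in reads]

    with open(sam, "w") as sam_fh:
        if aligner == "bowtie2":
            index = str(out_prefix) + ".idx"
            _run(["bowtie2-build", "-q", fasta, index], cmds)
            cmd = ["bowtie2", "-x", index, "-p", str(threads), "--no-unal"]
            cmd += ["-1", reads[0], "-2", reads[1]] if paired else ["-U", ",".join(reads)]
            _run(cmd, cmds, stdout=sam_fh)
        elif aligner == "minimap2":
            _run(["minimap2", "-ax", "sr", "-t", str(threads), fasta, *reads], cmds,
                 stdout=sam_fh)
        elif aligner == "bwa":
            _run(["bwa", "index", fasta], cmds)
            _run(["bwa", "mem", "-t", str(threads), fasta, *reads], cmds, stdout=sam_fh)
        else:
            raise ValueError(f"unknown aligner: {aligner}")

    pysam.sort("-@", str(threads), "-o", str(bam), str(sam))
    cmds.append(f"samtools sort -@ {threads} -o {bam} {sam}")
    sam.unlink()
    align_reads.last_commands = cmds  # type: ignore[attr-defined]
    return bam
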