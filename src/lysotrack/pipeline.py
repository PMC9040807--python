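"""End-to-end orchestration: parse -> (align) -> filter -> depth -> stats -> call.

The pipeline is deterministic: the core computation has no randomness, so
repeated runs on identical inputs produce byte-identical result tables, and
the thread count (which only affects the external aligner) never changes any
reported statistic.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as aln
from . import coordinates as coord_io
from . import coverage as cov
from .classify import ActivityResult, Thresholds, classify_all
from .errors import ComputationError, LysotrackError

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "prophage", "scaffold", "start", "stop", "prophage_length",
    "host_length", "prophage_mean_cov", "prophage_median_cov",
    "prophage_sd_cov", "host_mean_cov", "host_median_cov", "host_sd_cov",
    "prophage_breadth", "prophage_host_ratio", "cohens_d", "category",
    "reason",
]


@dataclass
class RunManifest:
    """Provenance record for one run."""

    input_mode: str = ""
    coordinate_source: str = ""
    thresholds: Thresholds = field(default_factory=Thresholds)
    filter_counts: aln.FilterCounts = field(default_factory=aln.FilterCounts)
    category_counts: dict[str, int] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    aligner_commands: list[str] = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["# lysotrack run manifest"]
        lines.append(f"input_mode\t{self.input_mode}")
        lines.append(f"coordinate_source\t{self.coordinate_source}")
        for k, v in dataclasses.asdict(self.thresholds).items():
            lines.append(f"threshold.{k}\t{v}")
        for k, v in self.filter_counts.as_dict().items():
            lines.append(f"reads.{k}\t{v}")
        for k, v in sorted(self.category_counts.items()):
            lines.append(f"category.{k}\t{v}")
        for k, v in self.timings.items():
            lines.append(f"seconds.{k}\t{v:.2f}")
        for cmd in self.aligner_commands:
            lines.append(f"command\t{cmd}")
        return "\n".join(lines) + "\n"


def _result_row(r: ActivityResult, host_len: int | None) -> dict:
    p, h = r.prophage_summary, r.host_summary
    nan = math.nan
    return {
        "prophage": r.prophage_id,
        "scaffold": r.scaffold_id,
        "start": r.start,
        "stop": r.stop,
        "prophage_length": r.stop - r.start + 1,
        "host_length": host_len if host_len is not None else 0,
        "prophage_mean_cov": p.mean_depth if p else nan,
        "prophage_median_cov": p.median_depth if p else nan,
        "prophage_sd_cov": p.sd_depth if p else nan,
        "host_mean_cov": h.mean_depth if h else nan,
        "host_median_cov": h.median_depth if h else nan,
        "host_sd_cov": h.sd_depth if h else nan,
        "prophage_breadth": p.breadth if p else nan,
        "prophage_host_ratio": r.ratio,
        "cohens_d": r.effect_size_d,
        "category": r.category,
        "reason": r.reason,
    }


def write_results(
    results: list[ActivityResult],
    path: str | Path,
    host_lengths: dict[str, int] | None = None,
) -> Path:
    """Write the per-prophage results TSV (floats at 4 decimals, NA for
    undefined values)."""
    host_lengths = host_lengths or {}
    rows = [_result_row(r, host_lengths.get(r.scaffold_id)) for r in results]
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f", na_rep="NA")
    return Path(path)


def compute_statistics(
    records: list[coord_io.ScaffoldRecord],
    profiles: dict[str, aln.DepthProfile],
    flags: dict[str, str],
    thresholds: Thresholds,
) -> tuple[list, dict[str, int]]:
    """Per-prophage (coordinate, prophage summary, host summary, flag) entries.

    The host summary is computed once per scaffold and shared by every
    co-resident prophage.  Returns the entries plus the host-region length
    used per scaffold.
    """
    entries = []
    host_lengths: dict[str, int] = {}
    for rec in records:
        if not rec.prophages:
            continue
        profile = profiles.get(rec.scaffold_id)
        scaffold_flag = None
        hsum = None
        host_mask = None
        if profile is None:
            scaffold_flag = coord_io.REASON_SCAFFOLD_UNKNOWN
        else:
            try:
                interior = cov.mask_ends(profile, thresholds.mask_len)
            except ComputationError:
                scaffold_flag = coord_io.REASON_SCAFFOLD_MASKED_OUT
            else:
                seg = cov.segment_host(rec, interior)
                host_mask = seg.host_mask
                n_host = int(host_mask.sum())
                host_lengths[rec.scaffold_id] = n_host
                if n_host < thresholds.min_region_len:
                    scaffold_flag = coord_io.REASON_HOST_SHORT
                else:
                    hsum = cov.summarize_region(profile, host_mask)
        for p in rec.prophages:
            flag = flags.get(p.prophage_id) or scaffold_flag
            psum = None
            if flag is None:
                pmask = np.zeros(profile.length, dtype=bool)
                pmask[p.slice0] = True
                pmask &= interior
                if not pmask.any():
                    flag = "prophage entirely within masked scaffold ends"
                else:
                    psum = cov.summarize_region(profile, pmask)
            entries.append((p, psum, hsum if flag is None else None, flag))
    return entries, host_lengths


def run_pipeline(
    *,
    bam: str | Path | None = None,
    sam: str | Path | None = None,
    fasta: str | Path | None = None,
    paired_reads: tuple[str, str] | None = None,
    unpaired_reads: list[str] | None = None,
    manual_coords: str | Path | None = None,
    vibrant_coords: str | Path | None = None,
    thresholds: Thresholds | None = None,
    out: str | Path = "lysotrack_results.tsv",
    log: str | Path | None = None,
    threads: int = 1,
    aligner: str | None = None,
    clean: bool = True,
    workdir: str | Path | None = None,
) -> tuple[list[ActivityResult], RunManifest, Path]:
    """Run the full workflow and write the results table.

    Exactly one alignment input mode (``bam``/``sam``, or ``fasta`` plus
    reads) and exactly one coordinate source must be supplied.
    """
    thresholds = thresholds or Thresholds()
    manifest = RunManifest(thresholds=thresholds)
    t0 = time.perf_counter()

    alignment_inputs = [x for x in (bam, sam) if x is not None]
    have_reads = paired_reads is not None or unpaired_reads
    if len(alignment_inputs) + bool(have_reads and fasta) != 1:
        raise LysotrackError(
            "supply exactly one alignment input: a BAM, a SAM, or a FASTA with reads"
        )
    if (manual_coords is None) == (vibrant_coords is None):
        raise LysotrackError(
            "supply exactly one coordinate source: a manual TSV or a VIBRANT table"
        )

    if manual_coords is not None:
        coords = coord_io.parse_manual_coordinates(manual_coords)
        manifest.coordinate_source = "manual"
    else:
        coords = coord_io.parse_vibrant_coordinates(vibrant_coords)
        manifest.coordinate_source = "vibrant"

    if alignment_inputs:
        alignment_path = Path(alignment_inputs[0])
        manifest.input_mode = "bam" if bam is not None else "sam"
    else:
        manifest.input_mode = "reads"
        workdir = Path(workdir) if workdir else Path(out).parent
        reads = list(paired_reads) if paired_reads else list(unpaired_reads)
        alignment_path = aln.align_reads(
            fasta,
            reads,
            paired=paired_reads is not None,
            threads=threads,
            out_prefix=Path(workdir) / "lysotrack_alignment",
            aligner=aligner,
        )
        manifest.aligner_commands = list(getattr(aln.align_reads, "last_commands", []))
    manifest.timings["alignment"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    import pysam

    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as af:
        scaffold_lengths = dict(zip(af.references, af.lengths))
        records, flags = coord_io.attach_and_validate(
            coords,
            scaffold_lengths,
            min_region_len=thresholds.min_region_len,
            mask_len=thresholds.mask_len,
        )
        views = aln.filter_alignments(
            af, thresholds.min_identity, counts=manifest.filter_counts
        )
        needed = {c.scaffold_id for c in coords}
        profiles = aln.compute_depth(
            (v for v in views if v.reference_id in needed),
            {s: l for s, l in scaffold_lengths.items() if s in needed},
        )
    manifest.timings["depth"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    entries, host_lengths = compute_statistics(records, profiles, flags, thresholds)
    results = classify_all(entries, thresholds)
    for r in results:
        manifest.category_counts[r.category] = manifest.category_counts.get(r.category, 0) + 1
    if not results:
        logger.warning("zero analyzable prophages; writing empty results table")
    table_path = write_results(results, out, host_lengths)
    manifest.timings["statistics"] = time.perf_counter() - t2

    if clean and manifest.input_mode == "reads":
        for p in {alignment_path, alignment_path.with_suffix(".sam")}:
            if p.exists():
                p.unlink()
    if log is not None:
        Path(log).write_text(manifest.to_text())
    return results, manifest, table_path
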