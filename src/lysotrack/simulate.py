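"""Ground-truth synthetic data: scaffolds, prophages and reads at a set ratio.

The generator realizes the genome-copy model behind the coverage test.  A
dormant prophage replicates 1:1 with its host chromosome, so its reads come
from the same uniform process as the host's.  An induced prophage adds free
phage genome copies, which contribute extra reads confined to the prophage
interval.  Concretely, for a true prophage:host copy ratio R and host mean
depth c:

* ``R >= 1`` — a baseline read process covers the whole scaffold at depth c
  (read starts uniform over all full-length placements, so coverage tapers
  only within a read length of the scaffold ends, exactly the artifact the
  150 bp end mask removes), plus an excess process confined to each prophage
  interval at depth ``(R - 1) * c``.
* ``R < 1`` — the prophage is carried by only a fraction of cells (or absent,
  R = 0): the baseline is confined to the host segments and a separate
  process covers each prophage at depth ``R * c``.

Read counts are fixed (rounded expectations), so the realized regional mean
depths match the scenario closely and replicate-to-replicate variation comes
from read placement alone.  Substitution errors are optional; with rate 0
every simulated read matches its source at 100% identity.

Reads can be emitted as FASTQ for the aligner path, or directly as SAM with
exact coordinates (CIGAR ``<L>M``, NM = substitution count), which lets depth
and statistics tests bypass the external aligner.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .alignment import AlignedReadView
from .coordinates import ProphageCoordinate, write_manual_coordinates
from .errors import ScenarioError

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {65: 84, 67: 71, 71: 67, 84: 65, 78: 78}  # A<->T, C<->G byte codes


@dataclass(frozen=True)
class SimulationScenario:
    """One synthetic experiment: a scaffold, its prophages and a read budget.

    ``true_ratio`` is the prophage:host genome copy ratio R the reads encode;
    the expected prophage depth is ``R * host_mean_depth``.
    """

    seed: int
    scaffold_length: int
    prophage_intervals: Sequence[tuple[int, int]]  # 1-based inclusive
    host_mean_depth: float
    true_ratio: float
    read_length: int = 150
    substitution_rate: float = 0.0
    paired: bool = False
    insert_size: int = 400
    scaffold_id: str = "synth_scaffold_1"

    def __post_init__(self) -> None:
        if self.true_ratio < 0:
            raise ScenarioError("true_ratio must be >= 0")
        if self.host_mean_depth <= 0:
            raise ScenarioError("host_mean_depth must be > 0")
        if self.read_length <= 0 or self.scaffold_length <= self.read_length:
            raise ScenarioError("scaffold must be longer than one read")
        if self.paired and self.insert_size < 2 * self.read_length:
            raise ScenarioError("insert_size must be >= 2 * read_length")
        if not 0 <= self.substitution_rate < 1:
            raise ScenarioError("substitution_rate must be in [0, 1)")
        last = 0
        for start, stop in self.prophage_intervals:
            if start <= last:
                raise ScenarioError("prophage intervals must be sorted and disjoint")
            if stop < start or stop > self.scaffold_length or start < 1:
                raise ScenarioError(f"interval ({start}, {stop}) outside scaffold")
            if stop - start + 1 < 1000:
                raise ScenarioError(
                    f"interval ({start}, {stop}) shorter than the 1 kb analysis floor"
                )
            last = stop

    @property
    def coordinates(self) -> list[ProphageCoordinate]:
        return [
            ProphageCoordinate(
                f"{self.scaffold_id}_fragment_{i + 1}", self.scaffold_id, start, stop
            )
            for i, (start, stop) in enumerate(self.prophage_intervals)
        ]

    def host_segments0(self) -> list[tuple[int, int]]:
        """0-based half-open host segments between/around the prophages."""
        segs, pos = [], 0
        for start, stop in self.prophage_intervals:
            if start - 1 > pos:
                segs.append((pos, start - 1))
            pos = stop
        if pos < self.scaffold_length:
            segs.append((pos, self.scaffold_length))
        return segs


@dataclass(frozen=True)
class SimRead:
    """One simulated read; ``seq`` is the forward-strand sequence."""

    name: str
    start: int          # 0-based leftmost reference position
    length: int
    n_subs: int
    seq: bytes | None   # None when only placements were generated
    mate: int = 0       # 0 = single-end, 1/2 = pair member


def make_genome(
    scenario: SimulationScenario,
    fasta: str | os.PathLike | None = None,
    coords: str | os.PathLike | None = None,
) -> str:
    """Uniform-random A/C/G/T scaffold; optionally written with coordinates.

    Byte-identical output for a given seed.
    """
    rng = np.random.default_rng([scenario.seed, 0])
    seq_arr = _BASES[rng.integers(0, 4, scenario.scaffold_length)]
    seq = seq_arr.tobytes().decode()
    if fasta is not None:
        with open(fasta, "w") as fh:
            fh.write(f">{scenario.scaffold_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i: i + 70] + "\n")
    if coords is not None:
        write_manual_coordinates(scenario.coordinates, coords)
    return seq


def _n_reads(depth: float, n_placements: int, read_len: int) -> int:
    return int(round(depth * n_placements / read_len))


def _region_count(depth: float, region_len: int, read_len: int) -> int:
    # Confined reads: region mean equals n * read_len / region_len exactly.
    return int(round(depth * region_len / read_len))


def _placements(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    """0-based read start positions realizing the scenario's depth model."""
    rl = scenario.read_length
    L = scenario.scaffold_length
    c = scenario.host_mean_depth
    R = scenario.true_ratio
    starts: list[np.ndarray] = []
    if R >= 1:
        n_b = _n_reads(c, L - rl + 1, rl)
        starts.append(rng.integers(0, L - rl + 1, n_b))
        for start, stop in scenario.prophage_intervals:
            plen = stop - start + 1
            n_e = _region_count((R - 1) * c, plen, rl)
            if n_e:
                starts.append(rng.integers(start - 1, stop - rl + 1, n_e))
    else:
        for s0, e0 in scenario.host_segments0():
            seg_len = e0 - s0
            if seg_len < rl:
                continue
            n = _region_count(c, seg_len, rl)
            starts.append(rng.integers(s0, e0 - rl + 1, n))
        if R > 0:
            for start, stop in scenario.prophage_intervals:
                plen = stop - start + 1
                n = _region_count(R * c, plen, rl)
                starts.append(rng.integers(start - 1, stop - rl + 1, n))
    if not starts:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(starts))


def _paired_placements(
    scenario: SimulationScenario, rng: np.random.Generator
) -> np.ndarray:
    """Fragment start positions for paired-end mode (two reads per fragment)."""
    rl, ins = scenario.read_length, scenario.insert_size
    L = scenario.scaffold_length
    c = scenario.host_mean_depth
    R = scenario.true_ratio
    frags: list[np.ndarray] = []

    def n_frag(depth: float, span: int) -> int:
        return int(round(depth * span / (2 * rl)))

    if R >= 1:
        frags.append(rng.integers(0, L - ins + 1, n_frag(c, L - ins + 1)))
        for start, stop in scenario.prophage_intervals:
            plen = stop - start + 1
            if plen >= ins:
                n = n_frag((R - 1) * c, plen)
                if n:
                    frags.append(rng.integers(start - 1, stop - ins + 1, n))
    else:
        for s0, e0 in scenario.host_segments0():
            if e0 - s0 >= ins:
                frags.append(rng.integers(s0, e0 - ins + 1, n_frag(c, e0 - s0)))
        if R > 0:
            for start, stop in scenario.prophage_intervals:
                plen = stop - start + 1
                if plen >= ins:
                    frags.append(rng.integers(start - 1, stop - ins + 1, n_frag(R * c, plen)))
    if not frags:
        return np.empty(0, dtype=np.int64)
    return np.sort(np.concatenate(frags))


def _apply_substitutions(
    seq: bytearray, rng: np.random.Generator, rate: float
) -> int:
    if rate == 0:
        return 0
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return 0
    pos = rng.choice(len(seq), size=k, replace=False)
    for p in pos:
        old = seq[p]
        choices = [b for b in b"ACGT" if b != old]
        seq[p] = choices[rng.integers(0, 3)]
    return int(k)


def simulate_reads(
    scenario: SimulationScenario, genome: str | None = None
) -> list[SimRead]:
    """Draw the scenario's reads; sequences attached when ``genome`` is given.

    Deterministic for a given scenario seed.  Paired mode yields two reads
    per fragment, at the fragment's two ends, sharing a name.
    """
    rng = np.random.default_rng([scenario.seed, 1])
    rl = scenario.read_length
    gbytes = bytearray(genome, "ascii") if genome is not None else None
    reads: list[SimRead] = []

    def cut(start: int) -> tuple[bytes | None, int]:
        if gbytes is None:
            return None, 0
        piece = bytearray(gbytes[start: start + rl])
        n = _apply_substitutions(piece, rng, scenario.substitution_rate)
        return bytes(piece), n

    if scenario.paired:
        frags = _paired_placements(scenario, rng)
        for i, f in enumerate(frags):
            name = f"sim_{i:07d}"
            for mate, start in ((1, int(f)), (2, int(f) + scenario.insert_size - rl)):
                seq, n = cut(start)
                reads.append(SimRead(name, start, rl, n, seq, mate))
    else:
        for i, s in enumerate(_placements(scenario, rng)):
            seq, n = cut(int(s))
            reads.append(SimRead(f"sim_{i:07d}", int(s), rl, n, seq))
    return reads


def reads_to_views(
    reads: Iterable[SimRead], scaffold_id: str
) -> list[AlignedReadView]:
    """Exact-coordinate alignment views (gapless, NM = substitutions)."""
    return [
        AlignedReadView(
            reference_id=scaffold_id,
            reference_start=r.start,
            blocks=((r.start, r.start + r.length),),
            alignment_length=r.length,
            mismatches=r.n_subs,
            gaps=0,
        )
        for r in reads
    ]


def _revcomp(seq: bytes) -> bytes:
    return bytes(_COMP[b] for b in reversed(seq))


def write_fastq(
    reads: Sequence[SimRead],
    path: str | os.PathLike,
    path2: str | os.PathLike | None = None,
) -> None:
    """Emit reads as FASTQ (gzipped if the path ends in .gz).

    Single-end reads go to ``path``; paired reads are split into ``path``
    (mate 1, forward) and ``path2`` (mate 2, reverse-complemented).
    """
    def opener(p):
        p = str(p)
        return gzip.open(p, "wt") if p.endswith(".gz") else open(p, "w")

    paired = any(r.mate == 2 for r in reads)
    if paired and path2 is None:
        raise ValueError("paired reads require a second output path")
    out1 = opener(path)
    out2 = opener(path2) if paired else None
    try:
        for r in reads:
            if r.seq is None:
                raise ValueError("reads carry no sequences; pass a genome to simulate_reads")
            if r.mate == 2:
                seq, fh = _revcomp(r.seq), out2
            else:
                seq, fh = r.seq, out1
            qual = "I" * r.length
            fh.write(f"@{r.name}\n{seq.decode()}\n+\n{qual}\n")
    finally:
        out1.close()
        if out2:
            out2.close()


def write_sam(
    reads: Sequence[SimRead],
    scenario: SimulationScenario,
    path: str | os.PathLike,
) -> None:
    """Emit reads directly as SAM with exact coordinates.

    Each read is written as an independent forward-strand record (CIGAR
    ``<L>M``, MAPQ 60, NM = substitution count); mate pairing flags are not
    reconstructed since depth computation treats mates independently.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": scenario.scaffold_id, "LN": scenario.scaffold_length}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = r.name if r.mate == 0 else f"{r.name}/{r.mate}"
            seg.query_sequence = (r.seq or b"N" * r.length).decode()
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = r.start
            seg.mapping_quality = 60
            seg.cigartuples = [(0, r.length)]
            seg.query_qualities = pysam.qualitystring_to_array("I" * r.length)
            seg.set_tag("NM", r.n_subs)
            out.write(seg)


def subsample_in_memory(
    reads: Sequence[SimRead], fraction: float, seed: int
) -> list[SimRead]:
    """Keep each read (pair) independently with the given probability.

    Mates share a name and are kept or dropped together.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng([seed, 2])
    keep: dict[str, bool] = {}
    out = []
    for r in reads:
        if r.name not in keep:
            keep[r.name] = bool(rng.random() < fraction)
        if keep[r.name]:
            out.append(r)
    return out


def _iter_fastq(path: str | os.PathLike):
    p = str(path)
    fh = gzip.open(p, "rt") if p.endswith(".gz") else open(p)
    with fh:
        while True:
            block = [fh.readline() for _ in range(4)]
            if not block[0]:
                return
            yield block


def subsample_reads(
    fastq_in: Sequence[str | os.PathLike],
    fastq_out: Sequence[str | os.PathLike],
    fraction: float,
    seed: int,
) -> int:
    """Random FASTQ subsampling; paired files are kept in sync.

    One Bernoulli(fraction) draw per read position, shared across the paired
    files, so mates are kept or dropped together.  Returns the number of
    reads (pairs) kept.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(fastq_in) != len(fastq_out):
        raise ValueError("fastq_in and fastq_out must have equal length")
    rng = np.random.default_rng([seed, 3])
    iters = [_iter_fastq(p) for p in fastq_in]
    outs = [
        gzip.open(str(p), "wt") if str(p).endswith(".gz") else open(p, "w")
        for p in fastq_out
    ]
    kept = 0
    try:
        for blocks in zip(*iters):
            if rng.random() < fraction:
                kept += 1
                for fh, block in zip(outs, blocks):
                    fh.writelines(block)
    finally:
        for fh in outs:
            fh.close()
    return kept
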