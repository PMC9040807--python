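"""Shared fixtures: synthetic scenarios, random SAM fixtures, depth oracle."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

import lysotrack as lt
from lysotrack import coverage as cov


def summarize_scenario(scenario: lt.SimulationScenario):
    """Run a single-prophage scenario through the coverage machinery.

    Returns ``(ratio, d, prophage_summary, host_summary)`` using the
    package's own depth and statistics path (exact-coordinate views, no
    external aligner).
    """
    views = lt.reads_to_views(lt.simulate_reads(scenario), scenario.scaffold_id)
    return summarize_views(views, scenario)


def summarize_views(views, scenario, mask_len: int = 150):
    profile = lt.compute_depth(
        iter(views), {scenario.scaffold_id: scenario.scaffold_length}
    )[scenario.scaffold_id]
    interior = cov.mask_ends(profile, mask_len)
    record = lt.ScaffoldRecord(
        scenario.scaffold_id, scenario.scaffold_length, list(scenario.coordinates)
    )
    host_mask = cov.segment_host(record, interior).host_mask
    hsum = cov.summarize_region(profile, host_mask)
    coord = scenario.coordinates[0]
    pmask = np.zeros(profile.length, dtype=bool)
    pmask[coord.slice0] = True
    pmask &= interior
    psum = cov.summarize_region(profile, pmask)
    return cov.coverage_ratio(psum, hsum), cov.effect_size(hsum, psum), psum, hsum


def random_indel_sam(rng: np.random.Generator, path, n_reads: int = 80,
                     scaffold_len: int = 3000, n_scaffolds: int = 2):
    """Write a random SAM with M/I/D CIGARs and NM tags; return lengths map."""
    names = [f"ref_{i}" for i in range(n_scaffolds)]
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": n, "LN": scaffold_len} for n in names],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for i in range(n_reads):
            ref = int(rng.integers(0, n_scaffolds))
            cigar = [(0, int(rng.integers(20, 60)))]
            while rng.random() < 0.5:
                op = int(rng.choice([1, 2]))  # I or D
                cigar.append((op, int(rng.integers(1, 4))))
                cigar.append((0, int(rng.integers(10, 40))))
            ref_len = sum(ln for op, ln in cigar if op in (0, 2))
            read_len = sum(ln for op, ln in cigar if op in (0, 1))
            start = int(rng.integers(0, scaffold_len - ref_len))
            gaps = sum(ln for op, ln in cigar if op in (1, 2))
            extra_mismatch = int(rng.integers(0, 3))
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"read_{i}"
            seg.query_sequence = "A" * read_len
            seg.flag = 0
            seg.reference_id = ref
            seg.reference_start = start
            seg.mapping_quality = 60
            seg.cigartuples = cigar
            seg.set_tag("NM", gaps + extra_mismatch)
            out.write(seg)
    return {n: scaffold_len for n in names}


def brute_force_depth(path, scaffold_lengths, min_identity: float = 97.0):
    """Independent per-position depth recount straight off the SAM records.

    Walks each record's CIGAR one column at a time and tallies per-position
    counts in plain dicts; shares no code with the package's depth path.
    """
    tallies = {sid: dict() for sid in scaffold_lengths}
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for seg in af.fetch(until_eof=True):
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            matched = sum(ln for op, ln in seg.cigartuples if op in (0, 7, 8))
            ins = sum(ln for op, ln in seg.cigartuples if op == 1)
            dele = sum(ln for op, ln in seg.cigartuples if op == 2)
            l = matched + ins + dele
            if not seg.has_tag("NM"):
                continue
            m = int(seg.get_tag("NM")) - ins - dele
            identity = (l - (ins + dele) - m) / l * 100.0
            if identity < min_identity:
                continue
            pos = seg.reference_start
            tally = tallies[seg.reference_name]
            for op, ln in seg.cigartuples:
                if op in (0, 7, 8):
                    for p in range(pos, pos + ln):
                        tally[p] = tally.get(p, 0) + 1
                    pos += ln
                elif op in (2, 3):
                    pos += ln
    out = {}
    for sid, length in scaffold_lengths.items():
        arr = np.zeros(length, dtype=np.int64)
        for p, c in tallies[sid].items():
            arr[p] = c
        out[sid] = arr
    return out


@pytest.fixture
def basic_scenario():
    """10 kb prophage centred in a 50 kb scaffold, host 20x, induced 4:1."""
    return lt.SimulationScenario(
        seed=11,
        scaffold_length=50000,
        prophage_intervals=[(20001, 30000)],
        host_mean_depth=20.0,
        true_ratio=4.0,
    )


@pytest.fixture
def sam_run(tmp_path, basic_scenario):
    """Files for an end-to-end run: genome FASTA, coordinate TSV, SAM."""
    sc = basic_scenario
    genome = lt.make_genome(sc, tmp_path / "genome.fasta", tmp_path / "coords.tsv")
    reads = lt.simulate_reads(sc, genome)
    lt.write_sam(reads, sc, tmp_path / "aln.sam")
    return {
        "scenario": sc,
        "genome": genome,
        "fasta": tmp_path / "genome.fasta",
        "coords": tmp_path / "coords.tsv",
        "sam": tmp_path / "aln.sam",
        "dir": tmp_path,
    }
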