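"""Synthetic generator: determinism, ratio self-consistency, subsampling."""

import numpy as np
import pysam
import pytest

import lysotrack as lt
from lysotrack.errors import ScenarioError

from conftest import summarize_scenario, summarize_views


def scenario(**kw):
    base = dict(
        seed=1,
        scaffold_length=50000,
        prophage_intervals=[(20001, 30000)],
        host_mean_depth=20.0,
        true_ratio=4.0,
    )
    base.update(kw)
    return lt.SimulationScenario(**base)


class TestScenarioValidation:
    def test_interval_below_analysis_floor(self):
        with pytest.raises(ScenarioError, match="1 kb"):
            scenario(prophage_intervals=[(1000, 1499)])

    def test_overlapping_intervals(self):
        with pytest.raises(ScenarioError):
            scenario(prophage_intervals=[(1000, 5000), (4000, 9000)])

    def test_interval_outside_scaffold(self):
        with pytest.raises(ScenarioError):
            scenario(prophage_intervals=[(45000, 55000)])

    def test_negative_ratio(self):
        with pytest.raises(ScenarioError):
            scenario(true_ratio=-0.5)


class TestMakeGenome:
    def test_seeded_determinism(self, tmp_path):
        sc = scenario()
        a = tmp_path / "a.fasta"
        b = tmp_path / "b.fasta"
        lt.make_genome(sc, a)
        lt.make_genome(sc, b)
        assert a.read_bytes() == b.read_bytes()
        assert lt.read_scaffold_lengths(a) == {sc.scaffold_id: 50000}

    def test_coordinate_tsv_round_trips(self, tmp_path):
        sc = scenario(prophage_intervals=[(5001, 7000), (20001, 30000)])
        lt.make_genome(sc, tmp_path / "g.fasta", tmp_path / "c.tsv")
        assert lt.parse_manual_coordinates(tmp_path / "c.tsv") == sc.coordinates


class TestReadProcess:
    def test_empirical_ratio_matches_truth(self):
        """The emitted reads realize the requested prophage:host depth ratio
        (placement noise only; well inside a 5% band at 20x over 10 kb)."""
        for R in (1.0, 2.0, 5.0):
            ratio, _, psum, hsum = summarize_scenario(scenario(seed=3, true_ratio=R))
            assert ratio == pytest.approx(R, rel=0.05)
            assert hsum.mean_depth == pytest.approx(20.0, rel=0.05)

    def test_absent_phage_has_zero_prophage_coverage(self):
        sc = scenario(true_ratio=0.0)
        reads = lt.simulate_reads(sc)
        start0, stop0 = 20000, 30000
        assert all(r.start + r.length <= start0 or r.start >= stop0 for r in reads)
        _, _, psum, _ = summarize_scenario(sc)
        assert psum.breadth == 0.0 and psum.mean_depth == 0.0

    def test_substitution_free_reads_match_genome_exactly(self, tmp_path):
        sc = scenario(scaffold_length=20000, prophage_intervals=[(8001, 10000)],
                      host_mean_depth=3.0)
        genome = lt.make_genome(sc)
        reads = lt.simulate_reads(sc, genome)
        assert all(r.n_subs == 0 for r in reads)
        for r in reads[:20]:
            assert r.seq.decode() == genome[r.start: r.start + r.length]

    def test_substitutions_reported_in_nm(self):
        sc = scenario(scaffold_length=20000, prophage_intervals=[(8001, 10000)],
                      host_mean_depth=5.0, substitution_rate=0.02)
        genome = lt.make_genome(sc)
        reads = lt.simulate_reads(sc, genome)
        total = sum(r.n_subs for r in reads)
        n_bases = sum(r.length for r in reads)
        assert 0.01 < total / n_bases < 0.04
        for r in reads:
            diff = sum(a != b for a, b in zip(r.seq.decode(), genome[r.start: r.start + r.length]))
            assert diff == r.n_subs

    def test_paired_mode_emits_mate_pairs(self, tmp_path):
        sc = scenario(scaffold_length=20000, prophage_intervals=[(8001, 10000)],
                      host_mean_depth=5.0, paired=True, insert_size=400)
        genome = lt.make_genome(sc)
        reads = lt.simulate_reads(sc, genome)
        assert all(r.mate in (1, 2) for r in reads)
        by_name = {}
        for r in reads:
            by_name.setdefault(r.name, []).append(r)
        for name, pair in by_name.items():
            assert sorted(r.mate for r in pair) == [1, 2]
            r1 = next(r for r in pair if r.mate == 1)
            r2 = next(r for r in pair if r.mate == 2)
            assert r2.start - r1.start == sc.insert_size - sc.read_length


class TestSamEmission:
    def test_sam_round_trip_matches_in_memory_views(self, tmp_path):
        """Depth computed from the emitted SAM equals depth from the
        generator's own exact-coordinate views at every position."""
        sc = scenario(scaffold_length=20000, prophage_intervals=[(8001, 10000)],
                      host_mean_depth=4.0, substitution_rate=0.01)
        genome = lt.make_genome(sc)
        reads = lt.simulate_reads(sc, genome)
        lt.write_sam(reads, sc, tmp_path / "x.sam")
        lengths = {sc.scaffold_id: sc.scaffold_length}
        from_sam = lt.compute_depth(
            lt.filter_alignments(tmp_path / "x.sam", 0.0), lengths
        )[sc.scaffold_id]
        from_views = lt.compute_depth(
            iter(lt.reads_to_views(reads, sc.scaffold_id)), lengths
        )[sc.scaffold_id]
        np.testing.assert_array_equal(from_sam.depth, from_views.depth)

    def test_sam_header_lists_scaffold(self, tmp_path):
        sc = scenario()
        lt.write_sam(lt.simulate_reads(sc)[:5], sc, tmp_path / "h.sam")
        with pysam.AlignmentFile(str(tmp_path / "h.sam"), check_sq=False) as af:
            assert dict(zip(af.references, af.lengths)) == {sc.scaffold_id: 50000}


class TestSubsampling:
    def _fastq_names(self, path):
        return [line.strip() for i, line in enumerate(open(path)) if i % 4 == 0]

    def test_fraction_one_is_identity(self, tmp_path):
        sc = scenario(scaffold_length=20000, prophage_intervals=[(8001, 10000)],
                      host_mean_depth=3.0)
        genome = lt.make_genome(sc)
        lt.write_fastq(lt.simulate_reads(sc, genome), tmp_path / "in.fastq")
        kept = lt.subsample_reads([tmp_path / "in.fastq"], [tmp_path / "out.fastq"], 1.0, 7)
        assert (tmp_path / "in.fastq").read_text() == (tmp_path / "out.fastq").read_text()
        assert kept == len(self._fastq_names(tmp_path / "in.fastq"))

    def test_binomial_expectation_and_pair_sync(self, tmp_path):
        sc = scenario(scaffold_length=30000, prophage_intervals=[(10001, 20000)],
                      host_mean_depth=10.0, paired=True)
        genome = lt.make_genome(sc)
        reads = lt.simulate_reads(sc, genome)
        lt.write_fastq(reads, tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        n_pairs = len(reads) // 2
        kept = lt.subsample_reads(
            [tmp_path / "r1.fastq", tmp_path / "r2.fastq"],
            [tmp_path / "o1.fastq", tmp_path / "o2.fastq"],
            0.05, seed=11,
        )
        # 3 sigma binomial band around 0.05 * n_pairs
        sigma = (n_pairs * 0.05 * 0.95) ** 0.5
        assert abs(kept - 0.05 * n_pairs) < 3 * sigma
        # mates stay synchronized
        assert self._fastq_names(tmp_path / "o1.fastq") == self._fastq_names(tmp_path / "o2.fastq")

    def test_in_memory_subsample_keeps_mates_together(self):
        sc = scenario(scaffold_length=30000, prophage_intervals=[(10001, 20000)],
                      host_mean_depth=5.0, paired=True)
        reads = lt.simulate_reads(sc)
        sub = lt.subsample_in_memory(reads, 0.2, seed=3)
        names = {}
        for r in sub:
            names.setdefault(r.name, []).append(r.mate)
        assert all(sorted(m) == [1, 2] for m in names.values())

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            lt.subsample_in_memory([], 0.0, 1)


def test_dormant_replicates_stay_near_unit_ratio():
    """Dormant truth (R=1) at 10x: estimated ratio in [0.9, 1.1] and d below
    the 0.70 gate in >= 95% of seeded replicates."""
    ok = 0
    n = 40
    for seed in range(n):
        sc = scenario(seed=seed, host_mean_depth=10.0, true_ratio=1.0)
        ratio, d, _, _ = summarize_scenario(sc)
        ok += (0.9 <= ratio <= 1.1) and d < 0.70
    assert ok >= 0.95 * n
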