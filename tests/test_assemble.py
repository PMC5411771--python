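"""Two-pass assembly pipeline: loading, solid reads, splitting, extension."""

import numpy as np
import pytest

from bloomtig.assemble import (
    AssemblyParams,
    SeedSegment,
    assemble,
    extend_seed,
    is_solid_read,
    load_pass,
    solid_read_percent,
    split_at_branches,
)
from bloomtig.bloom import BloomFilter, BloomParams, ExactKmerSet, total_memory
from bloomtig.graph import ProbabilisticDBG
from bloomtig.hashing import canonical_hash_direct, revcomp
from bloomtig.io import ReadRecord
from bloomtig.simdata import (
    SimConfig,
    simulate_genome,
    simulate_reads,
    unique_junction_genome,
)


def canon_seq(s):
    return min(s, revcomp(s))


def tiling_reads(genome, length=100, step=20):
    reads = [genome[i : i + length] for i in range(0, len(genome) - length + 1, step)]
    reads.append(genome[-length:])
    return reads


def exact_graph_for(genome, k, **kw):
    kmers = (genome[i : i + k] for i in range(len(genome) - k + 1))
    backing = ExactKmerSet(canonical_hash_direct(s, k) for s in kmers)
    return ProbabilisticDBG(backing, k, **kw)


class TestLoadPass:
    def test_distinct_count_tiny_read(self):
        cascade, distinct = load_pass(["ACGTA"], AssemblyParams(k=4, c=1, mem_bits=2**14))
        assert distinct == 2  # ACGT, CGTA canonicalised

    def test_non_acgt_splits_read(self):
        _, distinct = load_pass(["ACNGT"], AssemblyParams(k=3, c=1, mem_bits=2**14))
        assert distinct == 0  # both runs shorter than k

    def test_simulated_distinct_equals_genome_kmer_set(self):
        cfg = SimConfig(genome_length=10_000, read_length=100, coverage=30,
                        error_rate=0.0, seed=6)
        genome = simulate_genome(cfg)
        reads = simulate_reads(genome, cfg)
        k = 21
        _, distinct = load_pass(reads, AssemblyParams(k=k, c=2, mem_bits=2**20))
        genome_set = {canon_seq(genome[i : i + k]) for i in range(len(genome) - k + 1)}
        # uniform starts rarely sample the extreme terminal k-mers
        missing = sum(
            1
            for i in list(range(0, k)) + list(range(len(genome) - 2 * k, len(genome) - k + 1))
            if True
        )
        assert abs(distinct - len(genome_set)) <= 2 * k

    def test_occurrence_threshold_separates_errors(self):
        genome = unique_junction_genome(2000, 21, seed=7)
        reads = tiling_reads(genome, step=25) * 2  # every k-mer twice
        bad = genome[500:600]
        bad = bad[:50] + ("A" if bad[50] != "A" else "C") + bad[51:]
        cascade, _ = load_pass(reads + [bad], AssemblyParams(k=21, c=2, mem_bits=2**22))
        true_km = canonical_hash_direct(genome[700:721], 21)
        err_km = canonical_hash_direct(bad[40:61], 21)
        assert cascade.solid_contains(true_km)
        assert not cascade.solid_contains(err_km)


@pytest.fixture(scope="module")
def solid_setup():
    genome = unique_junction_genome(2000, 15, seed=8)
    reads = tiling_reads(genome, step=10) * 2
    cascade, _ = load_pass(reads, AssemblyParams(k=15, c=2, mem_bits=2**22))
    return genome, cascade.solid


class TestSolidRead:
    def test_error_free_read_is_solid(self, solid_setup):
        genome, solid = solid_setup
        assert is_solid_read(ReadRecord("r", genome[100:200]), solid, 15)

    def test_read_with_singleton_error_kmer_is_not(self, solid_setup):
        genome, solid = solid_setup
        r = genome[100:200]
        r = r[:50] + ("A" if r[50] != "A" else "C") + r[51:]
        assert not is_solid_read(ReadRecord("r", r), solid, 15)

    def test_read_shorter_than_k_is_not_solid(self, solid_setup):
        _, solid = solid_setup
        assert not is_solid_read(ReadRecord("r", "ACGTACGT"), solid, 15)


class TestSplitAtBranches:
    def test_branch_free_read_is_one_segment(self):
        genome = unique_junction_genome(500, 15, seed=9)
        g = exact_graph_for(genome, 15)
        segs = split_at_branches(ReadRecord("r", genome[50:150]), g)
        assert len(segs) == 1
        assert segs[0].sequence == genome[50:150]
        assert segs[0].span == (0, 100)

    def test_read_of_exactly_k_is_one_segment(self):
        genome = unique_junction_genome(400, 15, seed=10)
        g = exact_graph_for(genome, 15)
        segs = split_at_branches(ReadRecord("r", genome[30:45]), g)
        assert len(segs) == 1 and len(segs[0].sequence) == 15

    def test_read_crossing_true_fork_splits_in_two(self):
        """A fork with two long outgoing arms cuts the read at the fork k-mer."""
        k = 9
        genome = unique_junction_genome(300, k, seed=11)
        j = 140
        node = genome[j : j + k]
        alt_base = next(b for b in "ACGT" if b != genome[j + k])
        # a second long arm leaving the same node
        arm = node + alt_base + unique_junction_genome(60, k, seed=12)
        kmers = [genome[i : i + k] for i in range(len(genome) - k + 1)]
        kmers += [arm[i : i + k] for i in range(len(arm) - k + 1)]
        backing = ExactKmerSet(canonical_hash_direct(s, k) for s in kmers)
        g = ProbabilisticDBG(backing, k)
        read = genome[j - 40 : j + 40 + k]
        segs = split_at_branches(ReadRecord("r", read), g)
        assert len(segs) == 2
        # segments overlap by k-1 at the fork and tile the read
        assert segs[0].sequence.endswith(node)
        assert segs[0].sequence + segs[1].sequence[k - 1 :] == read

    def test_n_characters_split_read(self):
        genome = unique_junction_genome(300, 15, seed=13)
        g = exact_graph_for(genome, 15)
        read = genome[10:60] + "N" + genome[61:120]
        segs = split_at_branches(ReadRecord("r", read), g)
        assert len(segs) == 2
        assert segs[0].span == (0, 50) and segs[1].span == (51, 110)


class TestExtendSeed:
    def test_seed_in_middle_reconstructs_linear_genome(self):
        genome = unique_junction_genome(500, 15, seed=14)
        g = exact_graph_for(genome, 15)
        tracking = BloomFilter(BloomParams(m=2**20, h=4))
        seg = SeedSegment(genome[240:260], "r0", (0, 20))
        u = extend_seed(seg, g, tracking, uid=0)
        assert u is not None
        assert u.sequence in (genome, revcomp(genome))

    def test_second_seed_from_same_region_is_skipped(self):
        genome = unique_junction_genome(500, 15, seed=14)
        g = exact_graph_for(genome, 15)
        tracking = BloomFilter(BloomParams(m=2**20, h=4))
        assert extend_seed(SeedSegment(genome[240:260], "r0", (0, 20)), g, tracking) is not None
        assert extend_seed(SeedSegment(genome[300:330], "r1", (0, 30)), g, tracking) is None

    def test_short_false_spur_leaves_unitig_unchanged(self):
        """Injected false-positive spur k-mers (<= depth nodes) are ignored."""
        k = 15
        genome = unique_junction_genome(500, k, seed=15)
        plain = exact_graph_for(genome, k)
        tracking = BloomFilter(BloomParams(m=2**20, h=4))
        baseline = extend_seed(SeedSegment(genome[200:230], "r", (0, 30)), plain, tracking)

        spurred = exact_graph_for(genome, k)
        j = 100
        node = genome[j : j + k]
        alt = next(b for b in "ACGT" if b != genome[j + k])
        # spur of exactly k nodes hanging off the path: still a false branch
        spur_path = node + alt + unique_junction_genome(80, k, seed=99)[: k - 1]
        for i in range(1, k + 1):
            spurred.solid.insert(canonical_hash_direct(spur_path[i : i + k], k))
        tracking2 = BloomFilter(BloomParams(m=2**20, h=4))
        u = extend_seed(SeedSegment(genome[200:230], "r", (0, 30)), spurred, tracking2)
        assert u is not None and baseline is not None
        assert u.sequence == baseline.sequence


class TestAssemble:
    def test_error_free_tiling_reconstructs_genome(self):
        genome = unique_junction_genome(5000, 21, seed=16)
        reads = tiling_reads(genome)
        unitigs, report = assemble(reads, AssemblyParams(k=21, c=1, mem_bits=2**22))
        assert len(unitigs) == 1
        assert unitigs[0].sequence in (genome, revcomp(genome))
        assert report.n50 == 5000
        assert report.n_solid_reads == report.n_reads

    def test_empty_input(self):
        unitigs, report = assemble([], AssemblyParams(k=21, c=2, mem_bits=2**14))
        assert unitigs == [] and report.n_reads == 0 and report.unitig_count == 0

    def test_deterministic_given_identical_inputs(self):
        cfg = SimConfig(genome_length=5000, read_length=100, coverage=30,
                        error_rate=0.005, seed=17)
        reads = simulate_reads(simulate_genome(cfg), cfg)
        params = AssemblyParams(k=21, c=2, mem_bits=2**20, seed=3)
        a, ra = assemble(reads, params)
        b, rb = assemble(reads, params)
        assert [(u.id, u.sequence, u.seed_id) for u in a] == [
            (u.id, u.sequence, u.seed_id) for u in b
        ]
        assert ra.traversal_steps == rb.traversal_steps

    def test_soundness_and_no_duplicate_kmers_at_negligible_fpr(self):
        """Every output k-mer occurs >= c times in the reads; no k-mer is
        emitted in two unitigs."""
        cfg = SimConfig(genome_length=6000, read_length=100, coverage=40,
                        error_rate=0.01, seed=18)
        reads = simulate_reads(simulate_genome(cfg), cfg)
        k, c = 21, 2
        unitigs, _ = assemble(reads, AssemblyParams(k=k, c=c, target_fpr=1e-6))
        from collections import Counter

        counts = Counter()
        for r in reads:
            for i in range(len(r.sequence) - k + 1):
                counts[canon_seq(r.sequence[i : i + k])] += 1
        seen = set()
        for u in unitigs:
            for i in range(u.length - k + 1):
                km = canon_seq(u.sequence[i : i + k])
                assert counts[km] >= c
                assert km not in seen
                seen.add(km)

    def test_allocation_audit(self):
        params = AssemblyParams(k=15, c=3, mem_bits=2**16)
        _, report = assemble(["ACGTACGTACGTACGTAA"], params)
        assert report.allocated_bits == total_memory(2**16, 3)
        assert report.per_level_bits == 2**16


def test_solid_read_percent_arithmetic():
    assert solid_read_percent(0, 0) == 0.0
    assert f"{solid_read_percent(9, 12):.1f}" == "75.0"
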