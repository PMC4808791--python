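import numpy as np
import pytest

from conftest import brute_force_placements, seq_from_codes
from pseudoref.fixtures import duplicated_segment_genome, random_genome
from pseudoref.formats_io import AlignmentRecord, SequenceRecord
from pseudoref.mapping import (MULTI, UNIQUE, UNMAPPED, MapperIndex,
                               MappingParams, build_index, map_read,
                               optimal_mismatch_search, profile_from_sam,
                               unique_mapping_rate)
from pseudoref.mutagenesis import MutationSpec, encode, mutate_genome
from pseudoref.readsim import SimSpec, simulate_reads


# ---------------------------------------------------------------- index

def test_index_minimal_lookup():
    idx = build_index(SequenceRecord("g", "ACGTACGT"), k=8)
    assert list(idx.lookup("ACGTACGT")) == [0]
    assert list(idx.lookup("AAAAAAAA")) == []


def test_index_k_validation():
    g = SequenceRecord("g", "ACGTACGTACGT")
    with pytest.raises(ValueError):
        build_index(g, k=7)
    with pytest.raises(ValueError):
        build_index(g, k=33)
    with pytest.raises(ValueError):  # k > min contig length
        build_index([g, SequenceRecord("tiny", "ACGT")], k=8)


def test_index_multi_contig_positions_are_global():
    a = SequenceRecord("a", "AAAAAAAACCCCCCCC")
    b = SequenceRecord("b", "GGGGGGGGACGTACGT")
    idx = build_index([a, b], k=8)
    assert list(idx.lookup("ACGTACGT")) == [24]
    assert idx.to_local(24) == ("b", 8)


def test_palindromic_read_counts_locus_once():
    """A read equal to its own reverse complement is found by both
    orientations at the same locus but reported once."""
    core = "ACGCGT"  # palindromic 6-mer inside a longer palindromic read
    read = "AAGCTAGCATGCATGCTAGCTT"
    assert read == "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c]
                           for c in reversed(read))
    genome = SequenceRecord("g", "CCCCCCCCCC" + read + "GGGGGGGGGG")
    idx = build_index(genome, k=8)
    status, placements = map_read(SequenceRecord("r", read), idx, 0)
    assert status == UNIQUE
    assert len(placements) == 1 and placements[0].pos == 10


# ---------------------------------------------------------------- map_read

def test_map_read_examples():
    g = random_genome(4000, seed=1)
    idx = build_index(g, k=12)
    gcodes = encode(g.seq)
    read = seq_from_codes(gcodes[100:180])
    assert map_read(SequenceRecord("r", read), idx, 0)[0] == UNIQUE

    dup = SequenceRecord("g", g.seq + g.seq[:500])
    idx2 = build_index(dup, k=12)
    assert map_read(SequenceRecord("r", seq_from_codes(gcodes[100:180])),
                    idx2, 0)[0] == MULTI


def test_three_seeded_mismatches_threshold():
    """N=2 → unmapped, N=3 → unique, for a read with exactly 3 mismatches."""
    g = random_genome(5000, seed=2)
    gcodes = encode(g.seq)
    rcodes = gcodes[1000:1100].copy()
    for p in (10, 50, 90):
        rcodes[p] = (rcodes[p] + 1) % 4
    read = SequenceRecord("r", seq_from_codes(rcodes))
    idx = build_index(g, k=12)
    assert map_read(read, idx, 2)[0] == UNMAPPED
    status, placements = map_read(read, idx, 3)
    assert status == UNIQUE
    assert placements[0].pos == 1000 and placements[0].mismatches == 3


def test_read_shorter_than_seed_unmapped_with_warning():
    idx = build_index(random_genome(1000, seed=3), k=12)
    with pytest.warns(UserWarning):
        status, placements = map_read(SequenceRecord("r", "ACGTACGTAC"), idx, 0)
    assert status == UNMAPPED and placements == []


def test_n_bases_count_as_mismatches():
    g = random_genome(3000, seed=4)
    gcodes = encode(g.seq)
    rcodes = gcodes[500:560].copy()
    rcodes[5] = 4  # N in the read
    read = SequenceRecord("r", seq_from_codes(rcodes))
    idx = build_index(g, k=12)
    assert map_read(read, idx, 0)[0] == UNMAPPED
    status, placements = map_read(read, idx, 1)
    assert status == UNIQUE and placements[0].mismatches == 1


# ------------------------------------------------- oracle equivalence

@pytest.mark.parametrize("trial", range(12))
def test_placements_equal_brute_force_oracle(trial):
    """Seeded and full-scan paths both equal the all-positions Hamming scan,
    for random genomes (with Ns), read lengths and N allowances."""
    rng = np.random.default_rng(1000 + trial)
    glen = int(rng.integers(300, 5000))
    g = random_genome(glen, seed=int(rng.integers(2 ** 31)))
    seq = list(g.seq)
    for p in rng.integers(0, glen, size=int(rng.integers(0, 8))):
        seq[p] = "N"
    g = SequenceRecord("g", "".join(seq))
    gcodes = encode(g.seq)
    idx = MapperIndex(g, k=8)
    L = int(rng.integers(20, 121))
    for _ in range(8):
        start = int(rng.integers(0, glen - L + 1))
        rcodes = gcodes[start:start + L].copy()
        for p in rng.integers(0, L, size=int(rng.integers(0, L // 4 + 1))):
            rcodes[p] = int(rng.integers(0, 4))
        N = int(rng.integers(0, min(25, L // 4) + 1))
        _status, placements = map_read(rcodes, idx, N)
        got = {p.pos: p.mismatches for p in placements}
        assert got == brute_force_placements(gcodes, rcodes, N)


def test_unique_rate_examples():
    g = random_genome(10_000, seed=5)
    reads, _ = simulate_reads([g], SimSpec(n_reads=200, read_length=80, seed=6))
    assert unique_mapping_rate(reads, g, 0) == 1.0
    two_chrom = [SequenceRecord("c1", g.seq), SequenceRecord("c2", g.seq)]
    assert unique_mapping_rate(reads, two_chrom, 0) == 0.0
    assert unique_mapping_rate(reads, two_chrom, 5) == 0.0
    with pytest.raises(ValueError):
        unique_mapping_rate([], g, 0)


# ------------------------------------------------- profile / optimum

def test_error_free_reads_give_n_star_zero():
    g = random_genome(20_000, seed=7)
    reads, _ = simulate_reads([g], SimSpec(n_reads=300, read_length=100, seed=8))
    profile = optimal_mismatch_search(reads, g, N_grid=range(0, 6))
    assert profile.N_star == 0  # tie rule: smallest N of the 1.0 plateau
    assert profile.unique_rate(0) == 1.0
    assert profile.optimal_mismatch_rate == 0.0


def test_profile_matches_per_n_mapping():
    """The single-scan profile equals statuses from mapping at each N."""
    g = random_genome(6000, seed=9)
    pseudo = mutate_genome(g, MutationSpec(0.04, 2.0, 10)).genome
    reads, _ = simulate_reads([g], SimSpec(n_reads=120, read_length=60, seed=11))
    grid = list(range(0, 13))
    profile = optimal_mismatch_search(reads, pseudo, N_grid=grid)
    idx = build_index(pseudo, k=12)
    for N, unique_rate, mapped_rate in profile.grid:
        statuses = [map_read(r, idx, N)[0] for r in reads]
        assert unique_rate == pytest.approx(
            statuses.count(UNIQUE) / len(reads))
        assert mapped_rate == pytest.approx(
            1 - statuses.count(UNMAPPED) / len(reads))


def test_mapped_rate_monotone_in_n():
    g = random_genome(8000, seed=12)
    pseudo = mutate_genome(g, MutationSpec(0.08, 2.0, 13)).genome
    reads, _ = simulate_reads([g], SimSpec(n_reads=150, read_length=80, seed=14))
    profile = optimal_mismatch_search(reads, pseudo, N_grid=range(0, 21))
    mapped = [m for _n, _u, m in profile.grid]
    assert all(b >= a for a, b in zip(mapped, mapped[1:]))
    unique = [u for _n, u, _m in profile.grid]
    assert all(u <= m for u, m in zip(unique, mapped))


def test_duplicated_segment_exhibits_unique_rate_peak():
    """With a diverged duplicate in the genome the unique rate rises to a
    peak and then declines as multi-mapping sets in; the optimum for a 5%
    pseudo-reference sits in the mid-single-digit N range."""
    dup = duplicated_segment_genome(seed=5, unit_length=4000, divergence=0.10)
    pseudo = mutate_genome(dup, MutationSpec(0.05, 2.0, 99)).genome
    reads, _ = simulate_reads([dup], SimSpec(n_reads=500, read_length=100,
                                             seed=3))
    profile = optimal_mismatch_search(reads, pseudo, N_grid=range(0, 26))
    unique = [u for _n, u, _m in profile.grid]
    peak = max(range(len(unique)), key=unique.__getitem__)
    assert 5 <= profile.N_star <= 10
    assert unique[peak] > unique[0]          # rises to the peak
    assert unique[-1] < unique[peak] * 0.5   # and clearly declines after it


def test_tie_rule_prefers_smaller_n():
    g = random_genome(5000, seed=15)
    reads, _ = simulate_reads([g], SimSpec(n_reads=50, read_length=50, seed=16))
    profile = optimal_mismatch_search(reads, g, N_grid=[0, 1, 2])
    # error-free reads on their own genome: all three N are unique_rate 1.0
    assert [u for _n, u, _m in profile.grid] == [1.0, 1.0, 1.0]
    assert profile.N_star == 0


def test_mixed_read_lengths_warn():
    g = random_genome(3000, seed=17)
    reads = [SequenceRecord("a", g.seq[:60]), SequenceRecord("b", g.seq[100:180])]
    with pytest.warns(UserWarning, match="mixed"):
        optimal_mismatch_search(reads, g, N_grid=[0, 1])


def test_mapping_params_validation():
    p = MappingParams(N=5, L=100)
    assert p.mismatch_rate == pytest.approx(5.0)
    with pytest.raises(ValueError):
        MappingParams(N=101, L=100)


# ------------------------------------------------- SAM-run profiles

def _alns(n_reads, nh):
    return [AlignmentRecord(f"r{i}", "chr1", i, 0, nh) for i in range(n_reads)]


def test_profile_from_sam_all_unique():
    profile = profile_from_sam([(2, _alns(10, 1), 10)], read_length=100)
    assert profile.unique_rate(2) == 1.0
    assert profile.N_star == 2
    assert profile.optimal_mismatch_rate == pytest.approx(2.0)


def test_profile_from_sam_argmax():
    runs = [
        (0, _alns(6, 1), 10),
        (2, _alns(8, 1), 10),
        (4, _alns(7, 1) + _alns(2, 2)[6:], 10),
    ]
    profile = profile_from_sam(runs)
    assert profile.N_star == 2
    assert profile.unique_rate(2) == pytest.approx(0.8)


def test_profile_from_sam_errors():
    with pytest.raises(ValueError, match="duplicate"):
        profile_from_sam([(2, _alns(5, 1), 10), (2, _alns(5, 1), 10)])
    with pytest.raises(ValueError, match="total_reads"):
        profile_from_sam([(2, _alns(5, 1), None)])
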