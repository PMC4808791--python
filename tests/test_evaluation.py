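import numpy as np
import pytest

from pseudoref.evaluation import (UnifiedGene,
                                  align_contigs_to_genes, bin_by_expression,
                                  compute_rpm, count_reads_per_transcript,
                                  gene_coverage, merge_intervals,
                                  read_alignment_tab, reconstruction_stats,
                                  unify_gene_model)
from pseudoref.fixtures import random_genome
from pseudoref.formats_io import SequenceRecord, TranscriptModel
from pseudoref.mutagenesis import MutationSpec, mutate_genome


# ------------------------------------------------------------------- RPM

def test_compute_rpm():
    recs = compute_rpm({"t1": 1, "t2": 0, "t3": 100}, 1_000_000)
    by_id = {r.transcript_id: r.rpm for r in recs}
    assert by_id == {"t1": 1.0, "t2": 0.0, "t3": 100.0}
    assert compute_rpm({"t": 100}, 2_000_000)[0].rpm == pytest.approx(50.0)
    with pytest.raises(ValueError):
        compute_rpm({"t": 1}, 0)


# ---------------------------------------------------------- unified model

def _tm(tid, gid, exons):
    return TranscriptModel(tid, gid, "c", "+", exons)


def test_unify_single_expressed_isoform():
    genes = unify_gene_model([_tm("t1", "g1", [(0, 300)])], {"t1": 0.5})
    assert len(genes) == 1
    assert genes[0].unified_exons == [(0, 300)]
    assert genes[0].exonic_length == 300


def test_unify_interval_union():
    transcripts = [_tm("t1", "g1", [(0, 100)]), _tm("t2", "g1", [(50, 150)])]
    genes = unify_gene_model(transcripts, {"t1": 1.0, "t2": 1.0},
                             min_mature_len=0)
    assert genes[0].unified_exons == [(0, 150)]
    assert genes[0].exonic_length == 150


def test_unify_rpm_floor_excludes_gene():
    genes = unify_gene_model([_tm("t1", "g1", [(0, 300)])], {"t1": 0.05})
    assert genes == []
    kept = unify_gene_model([_tm("t1", "g1", [(0, 300)])], {"t1": 0.1})
    assert len(kept) == 1  # floor is inclusive (RPM >= 0.1)


def test_unify_mature_length_filter():
    short = _tm("t1", "g1", [(0, 100), (200, 300)])  # mature length 200
    assert unify_gene_model([short], {"t1": 5.0}) == []
    longer = _tm("t2", "g2", [(0, 100), (200, 301)])  # 201 nt
    assert len(unify_gene_model([longer], {"t2": 5.0})) == 1


def test_unify_errors():
    with pytest.raises(ValueError, match="gene_id"):
        unify_gene_model([_tm("t1", "", [(0, 300)])], {"t1": 1.0})
    with pytest.raises(ValueError, match="expression"):
        unify_gene_model([_tm("t1", "g1", [(0, 300)])], {})


# ---------------------------------------------------------------- coverage

def test_gene_coverage_examples():
    gene = UnifiedGene("g", [(0, 100)])
    assert gene_coverage(gene, [(0, 100)]).coverage == 1.0
    assert gene_coverage(gene, []).coverage == 0.0
    assert gene_coverage(gene, [(25, 75), (90, 120)]).coverage == \
        pytest.approx(0.6)  # (50 + 10) / 100


def test_gene_coverage_monotone_in_alignments():
    rng = np.random.default_rng(3)
    gene = UnifiedGene("g", [(0, 200), (300, 500)])
    alignments = []
    prev = 0.0
    for _ in range(30):
        s = int(rng.integers(0, 480))
        alignments.append((s, s + int(rng.integers(5, 60))))
        cov = gene_coverage(gene, alignments).coverage
        assert cov >= prev
        prev = cov


# ------------------------------------------------------- contig alignment

def test_contig_exact_copy_covers_gene():
    gene = random_genome(800, seed=1, name="g1")
    hits = align_contigs_to_genes([SequenceRecord("c1", gene.seq)], [gene])
    assert hits["g1"] == [(0, 800)]


def test_reverse_complement_contig_found():
    from pseudoref.readsim import revcomp
    gene = random_genome(600, seed=2, name="g1")
    hits = align_contigs_to_genes([SequenceRecord("c1", revcomp(gene.seq))],
                                  [gene])
    assert hits["g1"] == [(0, 600)]


def test_random_contig_no_hit():
    gene = random_genome(800, seed=3, name="g1")
    noise = random_genome(800, seed=4, name="noise")
    hits = align_contigs_to_genes([SequenceRecord("c1", noise.seq)], [gene])
    assert hits["g1"] == []


def test_diverged_contig_covers_most_of_gene():
    """A contig at 2% divergence still aligns ≥95% of the gene."""
    gene = random_genome(1000, seed=5, name="g1")
    contig = mutate_genome(gene, MutationSpec(0.02, 2.0, 6)).genome
    hits = align_contigs_to_genes([SequenceRecord("c1", contig.seq)], [gene])
    covered = sum(e - s for s, e in hits["g1"])
    assert covered >= 0.95 * 1000


def test_read_alignment_tab(tmp_path):
    p = tmp_path / "aln.tsv"
    p.write_text("# comment\n"
                 "c1\tg1\t99.0\t200\t1\t200\n"      # kept
                 "c2\tg1\t80.0\t300\t300\t599\n"    # identity below floor
                 "c3\tg1\t100.0\t30\t700\t729\n"    # too short
                 "c4\tg2\t100.0\t100\t150\t51\n")   # reversed coordinates
    hits = read_alignment_tab(p)
    assert hits == {"g1": [(0, 200)], "g2": [(50, 150)]}


# --------------------------------------------------------------- reports

def test_reconstruction_stats_example():
    report = reconstruction_stats({"a": 1.0, "b": 1.0, "c": 0.0, "d": 0.0})
    assert report.reconstruction_rate == 0.5
    assert report.auc == pytest.approx(0.5)


@pytest.mark.parametrize("value, rate", [(0.0, 0.0), (1.0, 1.0)])
def test_reconstruction_stats_degenerate(value, rate):
    report = reconstruction_stats({f"g{i}": value for i in range(5)})
    assert report.reconstruction_rate == rate
    assert report.auc == pytest.approx(value)


def test_auc_equals_mean_coverage():
    rng = np.random.default_rng(7)
    covs = {f"g{i}": float(rng.random()) for i in range(200)}
    report = reconstruction_stats(covs)
    vals = np.array(list(covs.values()))
    assert report.auc == pytest.approx(vals.mean(), abs=1e-12)
    # the reported grid curve integrates to the same value within the
    # 0.01-step discretization error
    grid_auc = np.trapezoid(report.curve_c, report.curve_t)
    assert abs(grid_auc - report.auc) <= 0.01
    # C is non-increasing and starts at 1
    assert report.curve_c[0] == 1.0
    assert all(b <= a for a, b in zip(report.curve_c, report.curve_c[1:]))


def test_reconstruction_rate_equals_curve_just_above_zero():
    covs = {"a": 0.0, "b": 0.4, "c": 0.9, "d": 0.01}
    report = reconstruction_stats(covs)
    t_idx = int(np.flatnonzero(np.isclose(report.curve_t, 0.01))[0])
    assert report.reconstruction_rate == report.curve_c[t_idx]


def test_reconstruction_stats_errors():
    with pytest.raises(ValueError):
        reconstruction_stats({})
    with pytest.raises(ValueError):
        reconstruction_stats({"g": 1.5})


# ------------------------------------------------------------------ bins

def test_expression_bins():
    bins = bin_by_expression({"a": 0.5, "b": 1.0, "c": 50.0, "d": 0.05,
                              "e": 9.99})
    assert bins["low"] == ["a"]
    assert bins["mid"] == ["b", "e"]
    assert bins["high"] == ["c"]
    assert "d" not in bins["low"] + bins["mid"] + bins["high"]


# ------------------------------------------------------------ end-to-end

def test_perfect_assembly_reconstruction_rate_one(small_fixture):
    """Contigs that are exact transcript copies reconstruct every expressed
    gene completely."""
    fx = small_fixture
    counts = count_reads_per_transcript(fx.truth)
    total = sum(counts.values())
    rpm = {t.id: counts.get(t.id, 0) / total * 1e6 for t in fx.transcript_seqs}
    genes = unify_gene_model(fx.transcripts, rpm, min_rpm=0.1)
    assert genes
    gene_seqs = [SequenceRecord(g.gene_id,
                                "".join(fx.genome.seq[s:e]
                                        for s, e in g.unified_exons))
                 for g in genes]
    contigs = [t for t in fx.transcript_seqs]
    hits = align_contigs_to_genes(contigs, gene_seqs, k=16)
    covs = {}
    for g, gs in zip(genes, gene_seqs):
        covered = sum(e - s for s, e in hits.get(g.gene_id, []))
        covs[g.gene_id] = covered / len(gs.seq)
    report = reconstruction_stats(covs)
    assert report.reconstruction_rate == 1.0
    assert report.auc == pytest.approx(1.0)


def test_merge_intervals():
    assert merge_intervals([(5, 10), (0, 6), (20, 30), (10, 12)]) == \
        [(0, 12), (20, 30)]
    assert merge_intervals([]) == []
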