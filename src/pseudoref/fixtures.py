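"""Seeded synthetic fixtures: a miniature species pair with known truth.

``make_fixtures`` builds a random genome carrying multi-exon genes, a
mutated pseudo-reference at a chosen divergence, spliced transcript
sequences, expression weights spanning the low/mid/high FPM bins, and
paired reads with truth — everything the downstream commands need, all
reproducible from one seed.  ``duplicated_segment_genome`` builds the
two-copy genome (one copy diverged) whose unique-mapping rate peaks and
then declines as the mismatch allowance grows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .formats_io import (ReadRecord, SequenceRecord, TranscriptModel,
                         write_fasta, write_fastq, write_gtf)
from .mutagenesis import MutatedGenome, MutationSpec, mutate_genome, \
    write_truth_tsv
from .readsim import SimReadTruth, SimSpec, revcomp, simulate_reads

BASES = np.array(list("ACGT"))


def random_genome(length: int, seed: int, name: str = "chr1") -> SequenceRecord:
    """Uniform-random ACGT genome."""
    rng = np.random.default_rng(seed)
    return SequenceRecord(name, "".join(BASES[rng.integers(0, 4, length)]))


def random_gene_models(genome_length: int, n_genes: int, seed: int,
                       chrom: str = "chr1") -> list[TranscriptModel]:
    """Place multi-exon gene models (2–6 exons) at regular slots."""
    rng = np.random.default_rng(seed)
    slot = genome_length // n_genes
    transcripts = []
    for gi in range(n_genes):
        slot_start = gi * slot + 50
        slot_end = (gi + 1) * slot - 50
        n_exons = int(rng.integers(2, 7))
        exons = []
        pos = slot_start + int(rng.integers(0, 100))
        for ei in range(n_exons):
            elen = int(rng.integers(80, 251))
            if pos + elen > slot_end:
                break
            exons.append((pos, pos + elen))
            pos += elen + int(rng.integers(80, 301))
        if len(exons) < 2:
            exons = [(slot_start, slot_start + 150),
                     (slot_start + 250, slot_start + 400)]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        gid = f"g{gi:03d}"
        transcripts.append(TranscriptModel(f"{gid}.t1", gid, chrom, strand, exons))
    return transcripts


def spliced_sequence(genome: SequenceRecord, tm: TranscriptModel) -> SequenceRecord:
    """Mature transcript sequence (exons joined; '-' strand reverse
    complemented)."""
    seq = "".join(genome.seq[s:e] for s, e in tm.exons)
    if tm.strand == "-":
        seq = revcomp(seq)
    return SequenceRecord(tm.transcript_id, seq)


def expression_weights(transcripts, seed: int, log10_range=(-1.0, 2.5)) -> dict:
    """Log-uniform weights wide enough to span the three FPM bins."""
    rng = np.random.default_rng(seed)
    lo, hi = log10_range
    return {tm.transcript_id: float(10 ** rng.uniform(lo, hi))
            for tm in transcripts}


@dataclass
class Fixture:
    genome: SequenceRecord
    pseudo_reference: MutatedGenome
    transcripts: list[TranscriptModel]
    transcript_seqs: list[SequenceRecord]
    weights: dict
    reads: list[ReadRecord]
    truth: SimReadTruth
    seed: int
    files: dict = field(default_factory=dict)


def make_fixtures(seed: int, outdir=None, genome_length: int = 100_000,
                  n_genes: int = 50, pseudo_rate: float = 0.05,
                  tstv: float = 2.0, n_reads: int = 4000,
                  read_length: int = 100, paired: bool = True,
                  force: bool = False) -> Fixture:
    """Build (and optionally write) the miniature species-pair fixture."""
    genome = random_genome(genome_length, seed)
    transcripts = random_gene_models(genome_length, n_genes, seed + 1)
    tseqs = [spliced_sequence(genome, tm) for tm in transcripts]
    weights = expression_weights(transcripts, seed + 2)
    pseudo = mutate_genome(genome, MutationSpec(pseudo_rate, tstv, seed + 3))
    usable = [t for t in tseqs if len(t.seq) >= (2 * read_length if paired else read_length)]
    usable_ids = {t.id for t in usable}
    spec = SimSpec(
        n_reads=n_reads, read_length=read_length, error_rate=0.0,
        paired=paired, insert_mean=260.0, insert_sd=30.0,
        weights={k: v for k, v in weights.items() if k in usable_ids},
        seed=seed + 4,
    )
    reads, truth = simulate_reads(usable, spec)
    fx = Fixture(genome, pseudo, transcripts, tseqs, weights, reads, truth, seed)
    if outdir is not None:
        fx.files = write_fixture_files(fx, outdir, force=force)
    return fx


def write_fixture_files(fx: Fixture, outdir, force: bool = False) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "pseudo_reference": os.path.join(outdir, "pseudo_reference.fa"),
        "annotation": os.path.join(outdir, "genes.gtf"),
        "transcripts": os.path.join(outdir, "transcripts.fa"),
        "reads": os.path.join(outdir, "reads.fq"),
        "weights": os.path.join(outdir, "weights.tsv"),
        "mutation_truth": os.path.join(outdir, "pseudo_reference.truth.tsv"),
        "read_truth": os.path.join(outdir, "reads.truth.tsv"),
    }
    if not force:
        for p in paths.values():
            if os.path.exists(p):
                raise FileExistsError(f"{p} exists (use force to overwrite)")
    write_fasta([fx.genome], paths["genome"])
    write_fasta([fx.pseudo_reference.genome], paths["pseudo_reference"])
    write_gtf(fx.transcripts, paths["annotation"])
    write_fasta(fx.transcript_seqs, paths["transcripts"])
    write_fastq(fx.reads, paths["reads"])
    with open(paths["weights"], "w") as fh:
        fh.write("# transcript_id\tweight\n")
        for tid, w in fx.weights.items():
            fh.write(f"{tid}\t{w:.6g}\n")
    write_truth_tsv(fx.pseudo_reference, paths["mutation_truth"])
    with open(paths["read_truth"], "w") as fh:
        fh.write("# read_id\tsource\tposition\tstrand\terror_positions\n")
        for rid, e in fx.truth.entries.items():
            errs = ",".join(map(str, e.error_positions))
            fh.write(f"{rid}\t{e.source_id}\t{e.position}\t{e.strand}\t{errs}\n")
    return paths


def duplicated_segment_genome(seed: int, unit_length: int = 6000,
                              divergence: float = 0.10,
                              tstv: float = 2.0) -> SequenceRecord:
    """A genome made of a segment plus a diverged copy of itself.

    Reads from the segment have a true locus and a paralogous one at
    ~``divergence``; as the mismatch allowance passes the paralog's
    distance, uniquely mapped reads turn multi-mapped and the unique rate
    declines — the phenomenon the mismatch sweep is designed around.
    """
    unit = random_genome(unit_length, seed, name="dup")
    copy = mutate_genome(unit, MutationSpec(divergence, tstv, seed + 1))
    return SequenceRecord("dup2x", unit.seq + copy.genome.seq)
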