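"""Readers and writers for the plain-text formats the toolkit touches.

All sequences are normalized to the uppercase alphabet {A, C, G, T, N}:
lowercase is folded, and IUPAC ambiguity codes (R, Y, S, W, ...) collapse
to N.  N never counts as a match anywhere in the toolkit.  Coordinates are
0-based half-open internally; the 1-based inclusive conventions of GTF and
SAM are converted at this boundary.
"""

from __future__ import annotations

import logging
import re
from collections import OrderedDict
from dataclasses import dataclass, field

import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_NORMALIZE = str.maketrans(
    {c: ("N" if c not in "ACGTacgt" else c.upper()) for c in
     "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"}
)


class ParseError(ValueError):
    """A malformed input file."""


def normalize_seq(seq: str) -> str:
    """Uppercase and collapse any non-ACGT letter to N.

    Characters outside the alphabet (digits, punctuation) raise ParseError.
    """
    out = seq.translate(_NORMALIZE)
    for ch in set(out) - ALPHABET:
        raise ParseError(f"illegal character {ch!r} in sequence")
    return out


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence record id must be non-empty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadRecord:
    """A sequencing read; ``mate`` is 1 or 2 for paired reads, 0 otherwise."""

    id: str
    seq: str
    qual: str | None = None
    mate: int = 0

    def __post_init__(self):
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class TranscriptModel:
    """A transcript as a sorted list of non-overlapping exon intervals.

    Exon coordinates are 0-based half-open on ``chrom``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def mature_length(self) -> int:
        """Summed exon length of the mature transcript, in nt."""
        return sum(e - s for s, e in self.exons)

    @property
    def short(self) -> bool:
        """True when the mature transcript is at most 200 nt (flagged here,
        filtered downstream by the unified gene model)."""
        return self.mature_length <= 200


@dataclass
class AlignmentRecord:
    """Minimal view of one aligned read from a SAM file.

    ``mismatches`` is None when the aligner did not report an NM tag.
    ``n_hits`` counts reported placements of the same read.
    """

    read_id: str
    target: str
    pos: int
    mismatches: int | None
    n_hits: int


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized SequenceRecords, in file order."""
    records: list[SequenceRecord] = []
    cur_id: str | None = None
    chunks: list[str] = []
    seen_any = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if cur_id is not None:
                    records.append(SequenceRecord(cur_id, "".join(chunks)))
                header = line[1:].strip()
                if not header:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                cur_id = header.split()[0]
                chunks = []
                seen_any = True
            else:
                if not seen_any:
                    raise ParseError(
                        f"{path}: expected FASTA header ('>') at line {lineno}"
                    )
                chunks.append(normalize_seq(line.strip()))
    if cur_id is not None:
        records.append(SequenceRecord(cur_id, "".join(chunks)))
    return records


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")
            if not rec.seq:
                fh.write("\n")


# ---------------------------------------------------------------------------
# FASTQ

_MATE_SUFFIX = re.compile(r"/([12])$")


def read_fastq(path) -> list[ReadRecord]:
    """Read 4-line-block FASTQ into normalized ReadRecords.

    A ``/1`` or ``/2`` id suffix sets the mate flag (the suffix is kept so
    that write∘read round-trips).
    """
    reads: list[ReadRecord] = []
    try:
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                rid = title.split()[0]
                m = _MATE_SUFFIX.search(rid)
                mate = int(m.group(1)) if m else 0
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: read {rid!r} sequence/quality length mismatch"
                    )
                reads.append(ReadRecord(rid, normalize_seq(seq), qual, mate))
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads, path) -> None:
    """Write reads as 4-line FASTQ; missing qualities become 'I' runs."""
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GTF (Ensembl dialect, exon features)

_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> list[TranscriptModel]:
    """Read exon features from a GTF into TranscriptModels.

    GTF 1-based inclusive coordinates become 0-based half-open.  Exons are
    grouped by transcript_id and sorted; overlapping exons within one
    transcript are a parse error.
    """
    transcripts: "OrderedDict[str, TranscriptModel]" = OrderedDict()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end_i < start_i:
                raise ParseError(f"{path}:{lineno}: exon end {end_i} < start {start_i}")
            attr = dict(_ATTR.findall(attrs))
            if "transcript_id" not in attr:
                raise ParseError(f"{path}:{lineno}: missing transcript_id attribute")
            if "gene_id" not in attr:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            tid = attr["transcript_id"]
            tm = transcripts.get(tid)
            if tm is None:
                tm = TranscriptModel(tid, attr["gene_id"], chrom, strand)
                transcripts[tid] = tm
            tm.exons.append((start_i - 1, end_i))
    for tm in transcripts.values():
        tm.exons.sort()
        for (s1, e1), (s2, _e2) in zip(tm.exons, tm.exons[1:]):
            if s2 < e1:
                raise ParseError(
                    f"transcript {tm.transcript_id!r}: overlapping exons "
                    f"[{s1},{e1}) and starting at {s2}"
                )
    return list(transcripts.values())


def write_gtf(transcripts, path, source: str = "pseudoref") -> None:
    """Write exon features; internal half-open becomes 1-based inclusive."""
    with open(path, "w") as fh:
        for tm in transcripts:
            for s, e in tm.exons:
                attrs = (f'gene_id "{tm.gene_id}"; '
                         f'transcript_id "{tm.transcript_id}";')
                fh.write("\t".join([
                    tm.chrom, source, "exon", str(s + 1), str(e),
                    ".", tm.strand, ".", attrs,
                ]) + "\n")


# ---------------------------------------------------------------------------
# SAM (minimal subset: FLAG, RNAME, POS, NM, NH)

def read_sam_min(path) -> list[AlignmentRecord]:
    """Read mapped alignment lines from a plain SAM file.

    Unmapped records (FLAG 0x4) are dropped.  n_hits comes from the NH tag
    when present, otherwise from counting lines per read id.  A missing NM
    tag leaves ``mismatches`` as None with a logged warning.
    """
    records: list[AlignmentRecord] = []
    missing_nh: list[int] = []
    id_counts: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            if aln.has_tag("NM"):
                nm = int(aln.get_tag("NM"))
            else:
                nm = None
                logger.warning("read %s: missing NM tag, mismatches unknown",
                               aln.query_name)
            if aln.has_tag("NH"):
                n_hits = int(aln.get_tag("NH"))
            else:
                n_hits = 0  # fill in afterwards from line counts
                missing_nh.append(len(records))
            records.append(AlignmentRecord(
                read_id=aln.query_name,
                target=aln.reference_name,
                pos=aln.reference_start,
                mismatches=nm,
                n_hits=n_hits,
            ))
            id_counts[aln.query_name] = id_counts.get(aln.query_name, 0) + 1
    for i in missing_nh:
        records[i].n_hits = id_counts[records[i].read_id]
    return records


# ---------------------------------------------------------------------------
# Read QC

def ambiguous_fraction(reads) -> float:
    """Fraction of bases that are N across a read set.

    A high value (> ~0.05) flags inputs whose observed mapping optimum can
    exceed the model prediction, because Ns never match and so inflate the
    required mismatch allowance.
    """
    seqs = [r.seq if hasattr(r, "seq") else str(r) for r in reads]
    if not seqs:
        raise ValueError("ambiguous_fraction: empty read set")
    total = sum(len(s) for s in seqs)
    if total == 0:
        raise ValueError("ambiguous_fraction: reads contain no bases")
    n_count = sum(s.count("N") for s in seqs)
    return n_count / total


# ---------------------------------------------------------------------------
# BED6 intervals

def read_bed6(path) -> list[tuple]:
    """Read BED6 rows as (chrom, start, end, name, score, strand);
    coordinates are already 0-based half-open in BED."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED fields")
            start, end = int(f[1]), int(f[2])
            if end < start:
                raise ParseError(f"{path}:{lineno}: end {end} < start {start}")
            rows.append((f[0], start, end, f[3], f[4], f[5]))
    return rows


def write_bed6(rows, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")
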