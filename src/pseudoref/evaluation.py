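"""Scoring a transcriptome assembly against a unified reference gene model.

The reference for evaluation is the *unified gene model*: per gene, the
interval union of the exons of its expressed isoforms (RPM ≥ 0.1 by
default) whose mature transcript exceeds 200 nt.  Per-gene coverage is the
fraction of unified exonic bases aligned by assembled transcripts; the
reconstruction rate is the fraction of genes with non-zero coverage; and
the cumulative curve C(t) — the fraction of genes with coverage ≥ t —
summarizes the whole distribution, with its AUC equal to the mean gene
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mutagenesis import encode

FPM_BINS = {"low": (0.1, 1.0), "mid": (1.0, 10.0), "high": (10.0, float("inf"))}


@dataclass(frozen=True)
class ExpressionRecord:
    """Depth-normalized expression: reads (fragments) per million mapped."""

    transcript_id: str
    rpm: float

    def __post_init__(self):
        if self.rpm < 0:
            raise ValueError("rpm must be >= 0")


@dataclass
class UnifiedGene:
    """Per-gene union of kept isoforms' exons (disjoint, sorted)."""

    gene_id: str
    unified_exons: list[tuple[int, int]]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.unified_exons)


@dataclass(frozen=True)
class GeneCoverage:
    gene_id: str
    coverage: float


@dataclass
class ReconstructionReport:
    """Per-gene coverages with summary statistics.

    ``curve`` is C(t) on the fixed grid t = 0, 0.01, ..., 1; ``auc`` is
    the exact integral of the step function C, which equals the mean of
    the coverages.
    """

    coverages: dict[str, float]
    reconstruction_rate: float
    curve_t: np.ndarray = field(repr=False, default=None)
    curve_c: np.ndarray = field(repr=False, default=None)
    auc: float = 0.0


def merge_intervals(intervals):
    """Union of half-open intervals as a sorted disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_length(a, b) -> int:
    """Total overlap length between two disjoint sorted interval lists."""
    total = 0
    i = j = 0
    a, b = list(a), list(b)
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if hi > lo:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def compute_rpm(read_counts: dict, total_mapped_reads: int) -> list[ExpressionRecord]:
    """rpm = count / total_mapped_reads × 1e6, per transcript."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    return [ExpressionRecord(tid, count / total_mapped_reads * 1e6)
            for tid, count in read_counts.items()]


def unify_gene_model(transcripts, expression, min_rpm: float = 0.1,
                     min_mature_len: int = 200) -> list[UnifiedGene]:
    """Build unified gene models from expressed, long-enough isoforms.

    Keeps isoforms with rpm ≥ min_rpm and mature length > min_mature_len;
    per gene, unified exons are the interval union over kept isoforms.
    Genes with no kept isoform are excluded.
    """
    if isinstance(expression, list):
        expression = {e.transcript_id: e.rpm for e in expression}
    genes: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for tm in transcripts:
        if not tm.gene_id:
            raise ValueError(f"transcript {tm.transcript_id!r} has no gene_id")
        if tm.transcript_id not in expression:
            raise ValueError(
                f"no expression value for transcript {tm.transcript_id!r}"
            )
        if expression[tm.transcript_id] < min_rpm:
            continue
        if tm.mature_length <= min_mature_len:
            continue
        if tm.gene_id not in genes:
            genes[tm.gene_id] = []
            order.append(tm.gene_id)
        genes[tm.gene_id].extend(tm.exons)
    return [UnifiedGene(g, merge_intervals(genes[g])) for g in order]


def gene_coverage(gene: UnifiedGene, transcript_alignments) -> GeneCoverage:
    """coverage = |union(alignments) ∩ unified_exons| / exonic_length."""
    if gene.exonic_length == 0:
        raise ValueError(f"gene {gene.gene_id!r} has zero exonic length")
    aligned = merge_intervals(transcript_alignments)
    cov = intersect_length(aligned, gene.unified_exons) / gene.exonic_length
    return GeneCoverage(gene.gene_id, cov)


def align_contigs_to_genes(contigs, genes, min_identity: float = 0.95,
                           min_length: int = 50, k: int = 16) -> dict:
    """Seed-anchored ungapped local alignment of contigs onto gene sequences.

    For every seeded diagonal the maximal segments whose score
    (matches − w·mismatches, w chosen so a non-negative score implies the
    identity floor) are reported as intervals on the gene sequence.  Both
    contig orientations are searched.  Returns gene_id → interval list.
    """
    genes = list(genes)
    contigs = list(contigs)
    w = int(np.ceil(min_identity / (1.0 - min_identity)))
    out = {g.id: [] for g in genes}
    for gene in genes:
        if not gene.seq:
            continue
        gcodes = encode(gene.seq)
        index = {}
        glen = len(gcodes)
        if glen >= k:
            vals = np.zeros(glen - k + 1, np.uint64)
            two = (gcodes & 3).astype(np.uint64)
            valid = np.ones(glen - k + 1, bool)
            for j in range(k):
                vals |= two[j:j + glen - k + 1] << np.uint64(2 * j)
                valid &= gcodes[j:j + glen - k + 1] != 4
            for p in np.flatnonzero(valid):
                index.setdefault(int(vals[p]), []).append(int(p))
        for contig in contigs:
            ccodes_f = encode(contig.seq)
            for ccodes in (ccodes_f, _revcomp(ccodes_f)):
                clen = len(ccodes)
                if clen < k or glen < k:
                    continue
                cvals = np.zeros(clen - k + 1, np.uint64)
                ctwo = (ccodes & 3).astype(np.uint64)
                cvalid = np.ones(clen - k + 1, bool)
                for j in range(k):
                    cvals |= ctwo[j:j + clen - k + 1] << np.uint64(2 * j)
                    cvalid &= ccodes[j:j + clen - k + 1] != 4
                diagonals = set()
                for cp in np.flatnonzero(cvalid):
                    for gp in index.get(int(cvals[cp]), ()):
                        diagonals.add(gp - int(cp))
                for d in diagonals:
                    g_lo = max(0, d)
                    g_hi = min(glen, d + clen)
                    if g_hi - g_lo < min_length:
                        continue
                    gseg = gcodes[g_lo:g_hi]
                    cseg = ccodes[g_lo - d:g_hi - d]
                    match = (gseg == cseg) & (gseg != 4) & (cseg != 4)
                    for s, e in _max_scoring_segments(match, w):
                        seg_len = e - s
                        ident = match[s:e].mean()
                        if seg_len >= min_length and ident >= min_identity:
                            out[gene.id].append((g_lo + s, g_lo + e))
    return {gid: merge_intervals(ivs) for gid, ivs in out.items()}


def _revcomp(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out != 4
    out[acgt] = 3 - out[acgt]
    return out


def _max_scoring_segments(match: np.ndarray, w: int):
    """Disjoint maximal positive-score segments of a ±score sequence
    (match +1, mismatch −w), Kadane-style."""
    segments = []
    score = 0
    start = 0
    best = 0
    best_end = -1
    best_start = 0
    for i, m in enumerate(match):
        score += 1 if m else -w
        if score > best:
            best = score
            best_end = i
            best_start = start
        if score <= 0:
            if best_end >= best_start:
                segments.append((best_start, best_end + 1))
            score = 0
            best = 0
            start = i + 1
            best_end = -1
            best_start = start
    if best_end >= best_start:
        segments.append((best_start, best_end + 1))
    # trim leading mismatches (a maximal segment never starts/ends on one,
    # but guard against degenerate inputs)
    return [(s, e) for s, e in segments if e > s]


def read_alignment_tab(path, min_identity: float = 0.95, min_length: int = 50):
    """Ingest precomputed tabular alignments (qseqid, sseqid, pident,
    length, sstart, send; 1-based inclusive subject coordinates, as in
    BLAST outfmt 6) into gene_id → interval lists."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            _q, s, pident, length, sstart, send = f[0], f[1], float(f[2]), \
                int(f[3]), int(f[4]), int(f[5])
            if pident < 100 * min_identity or length < min_length:
                continue
            lo, hi = sorted((sstart, send))
            out.setdefault(s, []).append((lo - 1, hi))
    return {gid: merge_intervals(ivs) for gid, ivs in out.items()}


def reconstruction_stats(coverages) -> ReconstructionReport:
    """Reconstruction rate, cumulative curve and AUC from per-gene coverage.

    AUC is computed exactly as the integral of the step function
    C(t) = fraction(coverage ≥ t), which equals the mean coverage; the
    reported grid curve (step 0.01) is for plotting/reporting.
    """
    if isinstance(coverages, dict):
        cov_map = dict(coverages)
    else:
        cov_map = {c.gene_id: c.coverage for c in coverages}
    if not cov_map:
        raise ValueError("reconstruction_stats: no genes")
    vals = np.array(list(cov_map.values()), dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("coverages must lie in [0, 1]")
    rate = float((vals > 0).mean())
    t = np.round(np.arange(0, 101) / 100.0, 2)
    c = np.array([(vals >= ti).mean() for ti in t])
    auc = float(vals.mean())  # exact integral of the step function C(t)
    return ReconstructionReport(
        coverages=cov_map, reconstruction_rate=rate,
        curve_t=t, curve_c=c, auc=auc,
    )


def bin_by_expression(fpm: dict) -> dict:
    """Partition genes into low/mid/high FPM bins.

    low: [0.1, 1), mid: [1, 10), high: [10, ∞); genes below the 0.1
    inclusion floor are excluded.
    """
    out = {name: [] for name in FPM_BINS}
    for gene, value in fpm.items():
        for name, (lo, hi) in FPM_BINS.items():
            if lo <= value < hi:
                out[name].append(gene)
                break
    return out


def count_reads_per_transcript(truth) -> dict:
    """Transcript read counts from simulation truth (mates count once)."""
    counts: dict[str, set] = {}
    for rid, entry in truth.entries.items():
        frag = rid[:-2] if rid.endswith(("/1", "/2")) else rid
        counts.setdefault(entry.source_id, set()).add(frag)
    return {tid: len(frags) for tid, frags in counts.items()}
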