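"""Mismatch-bounded unique-mapping engine and the optimal-mismatch search.

The mapper finds *all* ungapped placements of a read (either strand) with
Hamming mismatches ≤ N; a read is uniquely mapped when exactly one
placement qualifies.  Counting all placements within the allowance — not
just the best stratum — is what produces the characteristic unique-rate
peak as N grows: raising N first rescues reads from divergent loci and
then pushes reads into multi-mapping once paralogous copies fall inside
the allowance.  The optimal mismatch rate is 100·N*/L where N* maximizes
the unique mapping rate (smallest N on ties).

Two complete search strategies back ``map_read``:

* pigeonhole seeding — the read is split into N+1 segments; any placement
  with ≤ N mismatches contains at least one exact segment, so seeding with
  the k-prefix of every segment finds every qualifying placement.  Valid
  whenever floor(L/(N+1)) ≥ k.
* packed full scan — every genome offset is screened with a 2-bit-packed
  SWAR mismatch counter over the first 64 read bases (a provable lower
  bound on the true mismatch count, so no qualifying placement is ever
  screened out), and survivors are verified byte-exactly, with N counting
  as a mismatch against everything.

``optimal_mismatch_search`` scans each read once at max(N_grid) and derives
the whole profile from the best and second-best placement mismatch counts,
which is equivalent to re-mapping at every N.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from llvmlite import ir
from numba import njit, types
from numba.extending import intrinsic

from .formats_io import SequenceRecord
from .mutagenesis import encode

logger = logging.getLogger(__name__)

UNIQUE = "unique"
MULTI = "multi"
UNMAPPED = "unmapped"

_M55 = np.uint64(0x5555555555555555)
_M33 = np.uint64(0x3333333333333333)
_M0F = np.uint64(0x0F0F0F0F0F0F0F0F)
_M01 = np.uint64(0x0101010101010101)
_FULL = np.uint64(0xFFFFFFFFFFFFFFFF)


@intrinsic
def _popcnt64(typingctx, x):
    sig = types.uint64(types.uint64)

    def codegen(context, builder, signature, args):
        fn = builder.module.declare_intrinsic("llvm.ctpop", [ir.IntType(64)])
        return builder.call(fn, args)

    return sig, codegen


@njit(cache=True)
def _scan_two_words(W, npos, r0, r1, mask1, nmax, cand):
    """Candidate genome offsets whose packed mismatch count over the first
    min(L, 64) read bases is ≤ nmax.  Branch-free SWAR popcount so the loop
    vectorizes; returns the candidate count."""
    cnt = 0
    for p in range(npos):
        x = W[p] ^ r0
        x = (x | (x >> np.uint64(1))) & _M55
        y = (W[p + 32] ^ r1) & mask1
        y = (y | (y >> np.uint64(1))) & _M55
        v = x + y
        v = (v & _M33) + ((v >> np.uint64(2)) & _M33)
        v = (v + (v >> np.uint64(4))) & _M0F
        mm = (v * _M01) >> np.uint64(56)
        if mm <= nmax:
            cand[cnt] = p
            cnt += 1
    return cnt


@njit(cache=True)
def _scan_one_word(W, npos, r0, mask0, nmax, cand):
    """Single-word variant for reads of ≤ 32 bases."""
    cnt = 0
    for p in range(npos):
        x = (W[p] ^ r0) & mask0
        x = (x | (x >> np.uint64(1))) & _M55
        v = (x & _M33) + ((x >> np.uint64(2)) & _M33)
        v = (v + (v >> np.uint64(4))) & _M0F
        mm = (v * _M01) >> np.uint64(56)
        if mm <= nmax:
            cand[cnt] = p
            cnt += 1
    return cnt


def _pack_words(codes: np.ndarray) -> np.ndarray:
    """W[p] = 2-bit codes of bases p..p+31 (N packed as A; see callers)."""
    n = len(codes)
    two_bit = (codes & 3).astype(np.uint64)
    padded = np.concatenate([two_bit, np.zeros(31, np.uint64)])
    W = np.zeros(n, np.uint64)
    for j in range(32):
        W |= padded[j:j + n] << np.uint64(2 * j)
    return W


_SHIFTS = np.arange(32, dtype=np.uint64) * np.uint64(2)


def _read_words(codes: np.ndarray) -> tuple[np.uint64, np.uint64]:
    two_bit = (codes[:64] & 3).astype(np.uint64)
    w0 = two_bit[:32]
    w1 = two_bit[32:64]
    r0 = np.bitwise_or.reduce(w0 << _SHIFTS[:len(w0)]) if len(w0) else np.uint64(0)
    r1 = np.bitwise_or.reduce(w1 << _SHIFTS[:len(w1)]) if len(w1) else np.uint64(0)
    return np.uint64(r0), np.uint64(r1)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out != 4
    out[acgt] = 3 - out[acgt]
    return out


@dataclass(frozen=True)
class Placement:
    """One qualifying ungapped placement of a read."""

    target: str
    pos: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class MappingParams:
    """Maximum allowed mismatch count N for reads of length L."""

    N: int
    L: int

    def __post_init__(self):
        if not 0 <= self.N <= self.L:
            raise ValueError(f"N={self.N} outside [0, L={self.L}]")

    @property
    def mismatch_rate(self) -> float:
        """Allowed mismatch rate in percent, 100·N/L."""
        return 100.0 * self.N / self.L


class MapperIndex:
    """k-mer index plus packed representation of a (multi-contig) genome.

    Contigs are concatenated internally; placements whose window would
    cross a contig boundary are rejected during verification, and reported
    positions are global offsets into the concatenation (``to_local``
    recovers (contig, offset)).
    """

    def __init__(self, genome, k: int = 12):
        if isinstance(genome, SequenceRecord):
            records = [genome]
        else:
            records = list(genome)
        if not records or all(len(r.seq) == 0 for r in records):
            raise ValueError("build_index: empty genome")
        if k < 8:
            raise ValueError(f"seed length k={k} must be >= 8")
        if k > 32:
            raise ValueError(f"seed length k={k} must be <= 32")
        min_contig = min(len(r.seq) for r in records)
        if k > min_contig:
            raise ValueError(
                f"seed length k={k} exceeds shortest contig ({min_contig} nt)"
            )
        self.k = k
        self.records = records
        self.names = [r.id for r in records]
        self.codes = np.concatenate([encode(r.seq) for r in records])
        self.n = len(self.codes)
        starts = np.cumsum([0] + [len(r.seq) for r in records])
        self.contig_starts = starts[:-1]
        self.contig_ends = starts[1:]
        self.isn = (self.codes == 4)
        self.n_prefix = np.concatenate([[0], np.cumsum(self.isn)])
        self.W = _pack_words(self.codes)
        self._cand_buf = np.empty(self.n, np.int64)
        self._build_kmer_table()

    # -- k-mer table -------------------------------------------------------

    def _build_kmer_table(self):
        k, n = self.k, self.n
        npos = n - k + 1
        if npos <= 0:
            self._kmer_sorted = np.empty(0, np.uint64)
            self._kmer_pos = np.empty(0, np.int64)
            return
        vals = np.zeros(npos, np.uint64)
        two_bit = (self.codes & 3).astype(np.uint64)
        for j in range(k):
            vals |= two_bit[j:j + npos] << np.uint64(2 * j)
        # windows containing N or crossing a contig boundary are invalid
        has_n = (self.n_prefix[k:] - self.n_prefix[:-k]) > 0
        pos = np.arange(npos)
        end_contig = np.searchsorted(self.contig_ends, pos, side="right")
        start_contig = np.searchsorted(self.contig_ends, pos + k - 1, side="right")
        valid = (~has_n) & (end_contig == start_contig)
        pos = pos[valid]
        vals = vals[valid]
        order = np.argsort(vals, kind="stable")
        self._kmer_sorted = vals[order]
        self._kmer_pos = pos[order]

    def _encode_kmer(self, codes: np.ndarray) -> np.uint64 | None:
        if len(codes) != self.k or (codes == 4).any():
            return None
        val = np.uint64(0)
        for j, c in enumerate(codes & 3):
            val |= np.uint64(c) << np.uint64(2 * j)
        return val

    def lookup(self, kmer) -> np.ndarray:
        """Forward-text occurrence positions of an exact k-mer (global
        offsets).  Reverse-strand search is done by the caller querying the
        reverse complement."""
        codes = encode(kmer) if isinstance(kmer, str) else np.asarray(kmer)
        if len(codes) != self.k:
            raise ValueError(f"lookup expects a {self.k}-mer")
        val = self._encode_kmer(codes)
        if val is None:
            return np.empty(0, np.int64)
        lo = np.searchsorted(self._kmer_sorted, val, side="left")
        hi = np.searchsorted(self._kmer_sorted, val, side="right")
        return np.sort(self._kmer_pos[lo:hi])

    def to_local(self, pos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self.contig_ends, pos, side="right"))
        return self.names[ci], int(pos - self.contig_starts[ci])

    # -- exact verification ------------------------------------------------

    def verify(self, rcodes: np.ndarray, positions, nmax: int):
        """Exact mismatch counts at candidate offsets.  N (in genome or
        read) never matches.  Windows crossing a contig boundary are
        dropped.  Returns (positions, mismatch counts) with mm ≤ nmax."""
        L = len(rcodes)
        out_pos, out_mm = [], []
        r_isn = rcodes == 4
        for p in positions:
            p = int(p)
            if p < 0 or p + L > self.n:
                continue
            ci = np.searchsorted(self.contig_ends, p, side="right")
            if p + L > self.contig_ends[ci]:
                continue
            g = self.codes[p:p + L]
            mm = int(np.count_nonzero((g != rcodes) | (g == 4) | r_isn))
            if mm <= nmax:
                out_pos.append(p)
                out_mm.append(mm)
        return out_pos, out_mm

    # -- full scan ---------------------------------------------------------

    def scan_candidates(self, rcodes: np.ndarray, nmax: int) -> np.ndarray:
        """Complete candidate set for placements with ≤ nmax mismatches of
        the forward read text, via the packed lower-bound screen."""
        L = len(rcodes)
        npos = self.n - L + 1
        if npos <= 0:
            return np.empty(0, np.int64)
        cand = self._cand_buf
        nmax_u = np.uint64(min(nmax, L))
        if L <= 32:
            r0, _ = _read_words(rcodes)
            mask0 = _FULL if L == 32 else np.uint64((1 << (2 * L)) - 1)
            cnt = _scan_one_word(self.W, npos, r0, mask0, nmax_u, cand)
        else:
            r0, r1 = _read_words(rcodes)
            m = min(L, 64) - 32
            mask1 = _FULL if m == 32 else np.uint64((1 << (2 * m)) - 1)
            cnt = _scan_two_words(self.W, npos, r0, r1, mask1, nmax_u, cand)
        return cand[:cnt].copy()

    def placements(self, read, nmax: int) -> list[Placement]:
        """All placements of the read (either strand) with ≤ nmax
        mismatches; a locus found in both orientations counts once."""
        rcodes = read if isinstance(read, np.ndarray) else encode(
            read.seq if hasattr(read, "seq") else str(read))
        found: dict[int, Placement] = {}
        for strand, codes in (("+", rcodes), ("-", _revcomp_codes(rcodes))):
            cand = self.scan_candidates(codes, nmax)
            pos, mms = self.verify(codes, cand, nmax)
            for p, mm in zip(pos, mms):
                if p not in found:
                    name, local = self.to_local(p)
                    found[p] = Placement(name, local, strand, mm)
        return [found[p] for p in sorted(found)]


def build_index(genome, k: int = 12) -> MapperIndex:
    """Build a k-mer index of the genome (k ≥ 8)."""
    return MapperIndex(genome, k=k)


def _read_codes(read) -> np.ndarray:
    if isinstance(read, np.ndarray):
        return read
    return encode(read.seq if hasattr(read, "seq") else str(read))


def map_read(read, index: MapperIndex, N: int):
    """Map one read with at most N mismatches.

    Returns (status, placements) with status unique / multi / unmapped.
    Uses pigeonhole seeding when the segment length floor(L/(N+1)) allows
    an exact k-seed per segment, otherwise the packed full scan; both are
    complete, so the placement set equals the brute-force Hamming scan.
    """
    rcodes = _read_codes(read)
    L = len(rcodes)
    if L < index.k:
        warnings.warn(f"read shorter than seed length {index.k}; unmapped")
        return UNMAPPED, []
    if N < 0 or N > L:
        raise ValueError(f"N={N} outside [0, {L}]")
    seg_len = L // (N + 1)
    if seg_len >= index.k and not (rcodes == 4).any():
        found: dict[int, Placement] = {}
        for strand, codes in (("+", rcodes), ("-", _revcomp_codes(rcodes))):
            offsets = [i * seg_len for i in range(N + 1)]
            cand = set()
            for off in offsets:
                seed = codes[off:off + index.k]
                for hit in index.lookup(seed):
                    cand.add(int(hit) - off)
            pos, mms = index.verify(codes, sorted(cand), N)
            for p, mm in zip(pos, mms):
                if p not in found:
                    name, local = index.to_local(p)
                    found[p] = Placement(name, local, strand, mm)
        placements = [found[p] for p in sorted(found)]
    else:
        placements = index.placements(rcodes, N)
    if len(placements) == 0:
        return UNMAPPED, placements
    if len(placements) == 1:
        return UNIQUE, placements
    return MULTI, placements


def _as_index(genome_or_index, k: int = 12) -> MapperIndex:
    if isinstance(genome_or_index, MapperIndex):
        return genome_or_index
    return MapperIndex(genome_or_index, k=k)


def unique_mapping_rate(reads, genome, N: int, k: int = 12) -> float:
    """Fraction of reads with exactly one placement at allowance N."""
    reads = list(reads)
    if not reads:
        raise ValueError("unique_mapping_rate: empty read set")
    index = _as_index(genome, k)
    n_unique = 0
    for read in reads:
        status, _ = map_read(read, index, N)
        if status == UNIQUE:
            n_unique += 1
    return n_unique / len(reads)


@dataclass
class MismatchProfile:
    """Unique-mapping-rate curve over allowed mismatch counts N.

    ``grid`` holds (N, unique_rate, mapped_rate); N_star is the argmax of
    unique_rate (smallest N on ties) and optimal_mismatch_rate is
    100·N_star/L (%).
    """

    grid: list[tuple[int, float, float]]
    N_star: int
    optimal_mismatch_rate: float | None
    read_length: float | None = None
    n_reads: int = 0

    @classmethod
    def from_counts(cls, Ns, unique_counts, mapped_counts, total, read_length):
        Ns = list(Ns)
        grid = [(int(N), u / total, m / total)
                for N, u, m in zip(Ns, unique_counts, mapped_counts)]
        best = max(unique_counts)
        N_star = int(Ns[min(i for i, u in enumerate(unique_counts) if u == best)])
        rate = 100.0 * N_star / read_length if read_length else None
        return cls(grid=grid, N_star=N_star, optimal_mismatch_rate=rate,
                   read_length=read_length, n_reads=total)

    def unique_rate(self, N: int) -> float:
        for n, u, _ in self.grid:
            if n == N:
                return u
        raise KeyError(f"N={N} not in profile grid")

    def to_rows(self):
        return [{"N": n, "unique_rate": u, "mapped_rate": m}
                for n, u, m in self.grid]


def default_n_grid(L: int):
    """0..ceil(0.25·L), the default allowance sweep."""
    return list(range(0, int(np.ceil(0.25 * L)) + 1))


def best_and_second(reads, genome, nmax: int, k: int = 12):
    """Per-read best and second-best placement mismatch counts ≤ nmax.

    Returns (d1, d2) int arrays with sentinel nmax+1 for "none".  The
    status of a read at any N ≤ nmax follows: mapped iff d1 ≤ N, unique
    iff d1 ≤ N < d2.
    """
    index = _as_index(genome, k)
    reads = list(reads)
    sentinel = nmax + 1
    d1 = np.full(len(reads), sentinel, np.int64)
    d2 = np.full(len(reads), sentinel, np.int64)
    for i, read in enumerate(reads):
        rcodes = _read_codes(read)
        if len(rcodes) < index.k:
            warnings.warn("read shorter than seed length; treated as unmapped")
            continue
        pl = index.placements(rcodes, nmax)
        if pl:
            mms = sorted(p.mismatches for p in pl)
            d1[i] = mms[0]
            if len(mms) > 1:
                d2[i] = mms[1]
    return d1, d2


def optimal_mismatch_search(reads, genome, N_grid=None, k: int = 12) -> MismatchProfile:
    """Sweep the allowed mismatch count and locate the unique-rate optimum.

    Each read is scanned once at max(N_grid); the per-N statuses derive
    from its best and second-best placement mismatch counts.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("optimal_mismatch_search: empty read set")
    lengths = {len(r.seq if hasattr(r, "seq") else r) for r in reads}
    L = float(np.mean([len(r.seq if hasattr(r, "seq") else r) for r in reads]))
    if len(lengths) > 1:
        warnings.warn(
            "mixed read lengths: mismatch rates use the mean read length"
        )
    if N_grid is None:
        N_grid = default_n_grid(int(round(L)))
    N_grid = sorted(int(n) for n in N_grid)
    if not N_grid:
        raise ValueError("optimal_mismatch_search: empty N grid")
    nmax = N_grid[-1]
    d1, d2 = best_and_second(reads, genome, nmax, k=k)
    Ns = np.array(N_grid)
    unique_counts = [int(np.count_nonzero((d1 <= N) & (d2 > N))) for N in Ns]
    mapped_counts = [int(np.count_nonzero(d1 <= N)) for N in Ns]
    return MismatchProfile.from_counts(Ns, unique_counts, mapped_counts,
                                       len(reads), L)


def profile_from_sam(sam_runs, read_length: float | None = None) -> MismatchProfile:
    """Build a profile from external aligner runs.

    ``sam_runs`` is a list of (N, alignment records, total_reads); a read
    is unique when its NH-derived hit count is 1.
    """
    runs = list(sam_runs)
    if not runs:
        raise ValueError("profile_from_sam: no runs")
    seen_N = set()
    rows = []
    for N, records, total in runs:
        if N in seen_N:
            raise ValueError(f"duplicate N={N} in SAM runs")
        seen_N.add(N)
        if total is None or total <= 0:
            raise ValueError(f"run N={N}: total_reads missing or non-positive")
        by_read: dict[str, int] = {}
        for rec in records:
            by_read[rec.read_id] = max(by_read.get(rec.read_id, 0), rec.n_hits)
        unique = sum(1 for v in by_read.values() if v == 1)
        mapped = len(by_read)
        rows.append((int(N), unique, mapped, total))
    rows.sort()
    totals = {t for *_x, t in rows}
    if len(totals) > 1:
        warnings.warn("profile_from_sam: runs report different total_reads")
    total = rows[0][3]
    Ns = [r[0] for r in rows]
    uniq = [r[1] for r in rows]
    mapped = [r[2] for r in rows]
    return MismatchProfile.from_counts(Ns, uniq, mapped, total, read_length)
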