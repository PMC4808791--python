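"""RNA-seq-like read simulation with known truth, and depth subsampling.

Reads are drawn from source sequences (normally transcripts, so that the
unspliced mapper faces no introns): source ∝ expression weights (uniform if
absent), start uniform over valid starts, strand uniform.  Sequencing
errors are independent per-base substitutions logged in the truth table.
Paired-end fragments draw their insert from a normal truncated at 2L.

Subsampling keeps each read (or read pair, together) independently with
the given probability — the depth-titration device used to ask how much
sequencing a reconstruction needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats_io import ReadRecord
from .mutagenesis import decode, encode

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


@dataclass(frozen=True)
class SimSpec:
    """Read-simulation parameters.

    read_length L is also what converts a mismatch count N to a mismatch
    rate 100·N/L (%) downstream.
    """

    n_reads: int
    read_length: int = 100
    error_rate: float = 0.0
    paired: bool = False
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    weights: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.weights is not None:
            w = np.array(list(self.weights.values()), dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("weights must be non-negative and not all zero")


@dataclass(frozen=True)
class TruthEntry:
    source_id: str
    position: int
    strand: str
    error_positions: tuple[int, ...]


@dataclass
class SimReadTruth:
    """read_id → (source, position, strand, seeded error positions).

    Error positions are in read coordinates (after reverse complementing,
    for minus-strand reads).
    """

    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def __getitem__(self, read_id: str) -> TruthEntry:
        return self.entries[read_id]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, read_id: str) -> bool:
        return read_id in self.entries


def _apply_errors(codes: np.ndarray, rng, error_rate: float):
    if error_rate == 0.0:
        return codes, ()
    hit = rng.random(len(codes)) < error_rate
    pos = np.flatnonzero(hit)
    if len(pos) == 0:
        return codes, ()
    out = codes.copy()
    shift = rng.integers(1, 4, len(pos)).astype(np.uint8)
    out[pos] = (out[pos] + shift) % 4
    return out, tuple(int(p) for p in pos)


def simulate_reads(sources, spec: SimSpec):
    """Simulate reads; returns (reads, truth).

    Every source must be at least read_length long (paired: at least the
    truncated-normal insert floor of 2L).  Sources containing N are allowed;
    Ns propagate into reads.
    """
    sources = list(sources)
    if not sources:
        raise ValueError("simulate_reads: no sources")
    L = spec.read_length
    min_len = 2 * L if spec.paired else L
    for src in sources:
        if len(src.seq) < min_len:
            raise ValueError(
                f"source {src.id!r} ({len(src.seq)} nt) shorter than "
                f"required {min_len} nt"
            )
    rng = np.random.default_rng(spec.seed)
    if spec.weights is not None:
        ids = [s.id for s in sources]
        missing = [i for i in ids if i not in spec.weights]
        if missing:
            raise ValueError(f"weights missing for sources {missing}")
        w = np.array([spec.weights[i] for i in ids], dtype=float)
    else:
        w = np.ones(len(sources))
    prob = w / w.sum()
    src_codes = [encode(s.seq) for s in sources]
    picks = rng.choice(len(sources), size=spec.n_reads, p=prob)
    reads: list[ReadRecord] = []
    truth = SimReadTruth()
    width = len(str(spec.n_reads))
    for i, si in enumerate(picks):
        src = sources[si]
        codes = src_codes[si]
        if spec.paired:
            insert = 0
            while insert < 2 * L:
                insert = int(round(rng.normal(spec.insert_mean, spec.insert_sd)))
            insert = min(insert, len(codes))
            start = int(rng.integers(0, len(codes) - insert + 1))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            frag = codes[start:start + insert]
            # FR layout: mate 1 reads inward from the fragment's 5' end on
            # the sampled strand, mate 2 from the opposite end.
            if strand == "+":
                mates = (
                    (1, frag[:L], "+", start),
                    (2, _revcomp_codes(frag[insert - L:]), "-", start + insert - L),
                )
            else:
                mates = (
                    (1, _revcomp_codes(frag[insert - L:]), "-", start + insert - L),
                    (2, frag[:L], "+", start),
                )
            base = f"r{i:0{width}d}"
            for mate, mcodes, mate_strand, mate_pos in mates:
                mcodes, errs = _apply_errors(mcodes, rng, spec.error_rate)
                rid = f"{base}/{mate}"
                reads.append(ReadRecord(rid, decode(mcodes), "I" * L, mate))
                truth.entries[rid] = TruthEntry(src.id, mate_pos, mate_strand, errs)
        else:
            start = int(rng.integers(0, len(codes) - L + 1))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            rcodes = codes[start:start + L]
            if strand == "-":
                rcodes = _revcomp_codes(rcodes)
            rcodes, errs = _apply_errors(rcodes, rng, spec.error_rate)
            rid = f"r{i:0{width}d}"
            reads.append(ReadRecord(rid, decode(rcodes), "I" * L, 0))
            truth.entries[rid] = TruthEntry(src.id, start, strand, errs)
    return reads, truth


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out != 4
    out[acgt] = 3 - out[acgt]
    return out


def subsample_reads(reads, fraction: float, seed: int = 0):
    """Keep each read (pair) independently with probability ``fraction``.

    Mates (ids differing only in a /1 vs /2 suffix, or the mate field) are
    kept or dropped together.  Order is preserved; deterministic per seed.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    reads = list(reads)
    rng = np.random.default_rng(seed)

    def pair_key(r):
        rid = r.id
        if r.mate in (1, 2) and rid.endswith(f"/{r.mate}"):
            return rid[:-2]
        return rid

    keys = []
    seen = {}
    for r in reads:
        k = pair_key(r)
        if k not in seen:
            seen[k] = len(seen)
        keys.append(k)
    keep_group = rng.random(len(seen)) < fraction
    return [r for r, k in zip(reads, keys) if keep_group[seen[k]]]
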