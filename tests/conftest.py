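import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from pseudoref.mutagenesis import encode


def brute_force_placements(genome_codes: np.ndarray, read_codes: np.ndarray,
                           N: int) -> dict[int, int]:
    """All-positions Hamming scan oracle: position → mismatch count for
    every ungapped placement (either strand) with ≤ N mismatches.  N bases
    never match.  A locus found in both orientations counts once."""
    L = len(read_codes)
    n = len(genome_codes)
    if n < L:
        return {}
    win = sliding_window_view(genome_codes, L)
    out: dict[int, int] = {}
    for strand in ("+", "-"):
        rc = read_codes.copy()
        if strand == "-":
            rc = rc[::-1].copy()
            acgt = rc != 4
            rc[acgt] = 3 - rc[acgt]
        mm = ((win != rc) | (win == 4) | (rc == 4)).sum(axis=1)
        for p in np.flatnonzero(mm <= N):
            out.setdefault(int(p), int(mm[p]))
    return out


@pytest.fixture(scope="session")
def small_fixture():
    from pseudoref.fixtures import make_fixtures
    return make_fixtures(seed=11, genome_length=30_000, n_genes=15,
                         pseudo_rate=0.05, n_reads=600)


def seq_from_codes(codes):
    return "".join("ACGTN"[c] for c in codes)


__all__ = ["brute_force_placements", "seq_from_codes", "encode"]
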