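"""Virtual genomes by random per-residue substitution.

Each non-N base is substituted independently with probability ``rate``;
given a substitution, a transition (A↔G, C↔T) is chosen with probability
κ/(κ+1) and otherwise one of the two transversions uniformly, so the
expected transition/transversion ratio of the realized substitutions is κ.
N bases are never mutated.  Everything is reproducible from the seed
(numpy default_rng, i.e. PCG64).

The default series mirrors the fifteen-step design: rates 1%..15% in 1%
steps, one genome per rate, with seeds derived as ``base_seed + 1 + index``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .formats_io import SequenceRecord

DEFAULT_RATES = tuple(r / 100 for r in range(1, 16))
DEFAULT_TSTV = 2.0

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASE = np.array(list("ACGTN"))


@dataclass(frozen=True)
class MutationSpec:
    """Per-residue substitution rate, Ts/Tv ratio κ, and RNG seed."""

    rate: float
    tstv: float = DEFAULT_TSTV
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"mutation rate {self.rate} outside [0, 1]")
        if not self.tstv > 0:
            raise ValueError(f"Ts/Tv ratio must be > 0, got {self.tstv}")


@dataclass
class MutatedGenome:
    """A mutated copy of a genome plus the truth log of substitutions."""

    genome: SequenceRecord
    truth: list[tuple[int, str, str]]
    realized_rate: float
    realized_tstv: float
    spec: MutationSpec = field(repr=False, default=None)


def encode(seq: str) -> np.ndarray:
    """A/C/G/T/N → 0/1/2/3/4 as uint8."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.full(256, 255, np.uint8)
    for b, c in _CODE.items():
        lut[ord(b)] = c
    codes = lut[arr]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T,N}")
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(_BASE[codes])


def mutate_genome(g: SequenceRecord, spec: MutationSpec) -> MutatedGenome:
    """Apply the substitution model to a genome.

    With the A=0, C=1, G=2, T=3 encoding the transition partner is
    ``code ^ 2`` and the two transversions are ``code ^ 1`` and
    ``code ^ 3``.
    """
    if not g.seq:
        raise ValueError("mutate_genome: empty genome")
    rng = np.random.default_rng(spec.seed)
    codes = encode(g.seq)
    eligible = codes != 4
    n_eligible = int(eligible.sum())
    hit = (rng.random(len(codes)) < spec.rate) & eligible
    positions = np.flatnonzero(hit)
    n_sub = len(positions)
    p_ts = spec.tstv / (spec.tstv + 1.0)
    is_ts = rng.random(n_sub) < p_ts
    tv_pick = rng.integers(0, 2, n_sub)  # 0 → ^1, 1 → ^3
    mutated = codes.copy()
    ref = codes[positions]
    alt = np.where(is_ts, ref ^ 2, np.where(tv_pick == 0, ref ^ 1, ref ^ 3))
    mutated[positions] = alt
    truth = [(int(p), _BASE[r], _BASE[a]) for p, r, a in zip(positions, ref, alt)]
    n_ts = int(is_ts.sum())
    n_tv = n_sub - n_ts
    if n_tv > 0:
        realized_tstv = n_ts / n_tv
    elif n_ts > 0:
        realized_tstv = float("inf")
    else:
        realized_tstv = float("nan")
    return MutatedGenome(
        genome=SequenceRecord(g.id + f"|mut{spec.rate:g}", decode(mutated)),
        truth=truth,
        realized_rate=(n_sub / n_eligible) if n_eligible else 0.0,
        realized_tstv=realized_tstv,
        spec=spec,
    )


def make_virtual_series(g: SequenceRecord, rates=None, tstv: float = DEFAULT_TSTV,
                        base_seed: int = 100) -> list[MutatedGenome]:
    """One mutated genome per rate; seeds are ``base_seed + 1 + index``.

    Defaults produce the fifteen-genome 1%..15% series.
    """
    if rates is None:
        rates = DEFAULT_RATES
    rates = list(rates)
    if not rates:
        raise ValueError("make_virtual_series: empty rate list")
    if len(set(rates)) != len(rates):
        warnings.warn("make_virtual_series: duplicate rates in series")
    return [
        mutate_genome(g, MutationSpec(rate=r, tstv=tstv, seed=base_seed + 1 + i))
        for i, r in enumerate(rates)
    ]


def write_truth_tsv(mut: MutatedGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("# pos\tref\talt\n")
        for p, r, a in mut.truth:
            fh.write(f"{p}\t{r}\t{a}\n")
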