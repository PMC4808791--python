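"""Genetic distances between a query species and a candidate pseudo-reference.

The distance between two homologous sequences is 1 − nucleotide identity of
their global pairwise alignment.  Identity is, by default, the fraction of
matching columns among columns where *both* sequences carry a residue (gap
columns excluded); the alternative convention (denominator = full alignment
length) is available via ``identity_denominator``.  For a genome-wide
ortholog set the species-level distance is the median of per-pair distances.

Neighbor-joining trees over a distance matrix, with tree-path distances
(sum of branch lengths along the path between two leaves), support the
marker-tree views of divergence.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
import skbio
from skbio.tree import nj as _skbio_nj

from .formats_io import SequenceRecord


@dataclass(frozen=True)
class AlignmentScoring:
    """Scores for global alignment with affine gaps.

    A gap of length g scores ``gap_open + (g − 1) * gap_extend``.  Match
    and mismatch follow EDNAFULL (+5/−4); the gap opening penalty is
    deliberately stiff so that sequence pairs differing only by
    substitutions align gaplessly up to ~35% divergence (a double gap must
    buy back two openings before it beats aligned mismatches), while long
    genuine indels still gap out cheaply per extended base.  N never
    matches any base, including another N.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -20.0
    gap_extend: float = -1.0


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class PairwiseDistance:
    """Identity/distance between two sequences; the model's x-axis."""

    id_a: str
    id_b: str
    identity: float
    distance: float
    aligned_columns: int


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("negative off-diagonal distance entry")


@dataclass
class PhyloTree:
    """An unrooted NJ tree; negative branch-length estimates are clamped
    to zero (and flagged via ``clamped``)."""

    tree: "skbio.TreeNode"
    taxa: list[str] = field(default_factory=list)
    clamped: int = 0

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                mat[a, b] = scoring.match
            else:
                mat[a, b] = scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _as_seq(x) -> tuple[str, str]:
    if isinstance(x, SequenceRecord):
        return x.id, x.seq
    return "seq", str(x)


def align_pair(a, b, scoring: AlignmentScoring = DEFAULT_SCORING) -> tuple[str, str]:
    """Globally align two sequences; returns the two gapped strings.

    The alignment maximizes the affine-gap score; ties are resolved
    deterministically (the aligner's first reported alignment is taken).
    """
    _, sa = _as_seq(a)
    _, sb = _as_seq(b)
    if not sa or not sb:
        raise ValueError("align_pair: sequences must be non-empty")
    aln = _aligner(scoring).align(sa, sb)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb


def genetic_distance(a, b, scoring: AlignmentScoring = DEFAULT_SCORING,
                     identity_denominator: str = "residue_pairs") -> PairwiseDistance:
    """Identity and distance (1 − identity) from a global alignment.

    identity_denominator:
        "residue_pairs" (default) — columns where both sequences have a
        residue; "alignment_length" — every alignment column.
    """
    ida, sa = _as_seq(a)
    idb, sb = _as_seq(b)
    ga, gb = align_pair(sa, sb, scoring)
    matches = 0
    both = 0
    for ca, cb in zip(ga, gb):
        if ca != "-" and cb != "-":
            both += 1
            if ca == cb and ca != "N":
                matches += 1
    if identity_denominator == "residue_pairs":
        denom = both
    elif identity_denominator == "alignment_length":
        denom = len(ga)
    else:
        raise ValueError(f"unknown identity denominator {identity_denominator!r}")
    if denom == 0:
        raise ValueError("alignment has no aligned residue pairs")
    identity = matches / denom
    return PairwiseDistance(ida, idb, identity, 1.0 - identity, both)


def ortholog_set_distance(pairs, scoring: AlignmentScoring = DEFAULT_SCORING) -> float:
    """Median per-pair distance over a set of one-to-one ortholog pairs.

    With an even number of pairs the mean of the two middle values is
    returned (numpy median convention).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("ortholog_set_distance: empty pair list")
    dists = [genetic_distance(a, b, scoring).distance for a, b in pairs]
    return float(np.median(dists))


def nj_tree(m: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.  For an additive input matrix the
    tree-path distances reproduce the matrix to machine precision."""
    if len(m.taxa) < 3:
        raise ValueError("nj_tree requires at least 3 taxa")
    dm = skbio.DistanceMatrix(m.d, ids=m.taxa)
    tree = _skbio_nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"nj_tree: clamped {clamped} negative branch length(s) to 0")
    return PhyloTree(tree=tree, taxa=list(m.taxa), clamped=clamped)


def tree_path_distance(t: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths on the tree path between leaves a and b."""
    if a == b:
        if a not in t.taxa:
            raise KeyError(f"unknown leaf {a!r}")
        return 0.0
    try:
        na = t.tree.find(a)
        nb = t.tree.find(b)
    except skbio.tree.MissingNodeError as exc:
        raise KeyError(str(exc)) from exc
    return float(na.distance(nb))
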