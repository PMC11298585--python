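"""Pairwise protein alignment and reference-to-query residue mapping.

Global and local alignment with affine gap costs (Gotoh), scored with an
NCBI-format substitution matrix (BLOSUM62 by default). A gap of length ``L``
costs ``gap_open + L * gap_extend`` (the BLAST convention, default 11/1).

Every sequence-level screening criterion in this package is anchored through
:func:`map_positions`: residue numbers on a reference protein (e.g. the
catalytic triad of a thioesterase domain) are carried through an alignment
onto the query, so queries are always interrogated in the reference
coordinate frame.

The alignment engine is ``Bio.Align.PairwiseAligner``; the test suite checks
its scores against an independent exhaustive enumeration of all alignments on
short sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import ALPHABET

UNALIGNED = "unaligned"
OUTSIDE = "outside"


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters. ``gap_open >= gap_extend > 0`` (positive costs)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    mode: str = "global"

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.mode not in ("global", "local"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise alignment between a reference (``ref``) and a query.

    ``ref_span``/``query_span`` are 1-based inclusive intervals of the
    ungapped sequences covered by the alignment; ``identity`` and
    ``similarity`` are fractions over all alignment columns, a column being
    "similar" when both residues are present and their substitution score is
    positive (or they are identical).
    """

    score: float
    aligned_ref: str
    aligned_query: str
    ref_span: tuple[int, int]
    query_span: tuple[int, int]
    identity: float
    similarity: float
    params: AlignmentParams = AlignmentParams()

    def __post_init__(self):
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("gapped strings must have equal length")


@lru_cache(maxsize=8)
def load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=16)
def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = load_matrix(params.matrix)
    # biopython charges open_gap_score for the first gap column and
    # extend_gap_score afterwards; shifting by one extension reproduces the
    # open + L*extend convention.
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = params.mode
    return aligner


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"{name}: illegal residues {sorted(bad)}")


def align(a: str, b: str, params: AlignmentParams | None = None) -> AlignmentResult:
    """Align reference ``a`` against query ``b``; optimal affine-gap score."""
    params = params or AlignmentParams()
    _check_sequence(a, "ref")
    _check_sequence(b, "query")
    aligner = _aligner(params)
    try:
        aln = aligner.align(a, b)[0]
    except IndexError:
        # local mode with no positive-scoring subalignment: empty alignment
        return AlignmentResult(score=0.0, aligned_ref="", aligned_query="",
                               ref_span=(1, 0), query_span=(1, 0),
                               identity=0.0, similarity=0.0, params=params)
    aligned_ref, aligned_query = str(aln[0]), str(aln[1])
    coords = aln.coordinates
    ref_span = (int(coords[0, 0]) + 1, int(coords[0, -1]))
    query_span = (int(coords[1, 0]) + 1, int(coords[1, -1]))

    matrix = load_matrix(params.matrix)
    ncols = len(aligned_ref)
    ident = simil = 0
    for x, y in zip(aligned_ref, aligned_query):
        if x == "-" or y == "-":
            continue
        if x == y:
            ident += 1
            simil += 1
        elif matrix[x, y] > 0:
            simil += 1
    return AlignmentResult(
        score=float(aln.score),
        aligned_ref=aligned_ref,
        aligned_query=aligned_query,
        ref_span=ref_span,
        query_span=query_span,
        identity=ident / ncols if ncols else 0.0,
        similarity=simil / ncols if ncols else 0.0,
        params=params,
    )


class PositionMap:
    """Mapping from reference residue numbers onto query residue numbers.

    Built from one alignment; a reference number resolves to the 1-based
    query position sharing its alignment column, to ``"unaligned"`` when the
    column holds a query gap, or to ``"outside"`` when the number falls
    outside the aligned reference span. Mapped positions are strictly
    increasing in both coordinates.
    """

    def __init__(self, mapping: dict[int, int | None], span: tuple[int, int]):
        self._map = mapping
        self.span = span

    def resolve(self, ref_number: int) -> int | str:
        if not (self.span[0] <= ref_number <= self.span[1]):
            return OUTSIDE
        q = self._map.get(ref_number)
        return UNALIGNED if q is None else q

    def residue(self, ref_number: int, query_sequence: str) -> str | None:
        """Query residue aligned to ``ref_number`` (None if unaligned)."""
        q = self.resolve(ref_number)
        if isinstance(q, int):
            return query_sequence[q - 1]
        return None

    def mapped_items(self) -> list[tuple[int, int]]:
        return sorted((r, q) for r, q in self._map.items() if q is not None)


def full_position_map(aln: AlignmentResult, ref_start: int = 1) -> PositionMap:
    """Map every aligned reference number (offset by ``ref_start``) to the query.

    ``ref_start`` is the residue number of position 1 of the ungapped
    reference sequence (e.g. 2723 when the reference is a thioesterase domain
    excised from a longer protein).
    """
    mapping: dict[int, int | None] = {}
    ref_pos = aln.ref_span[0] - 1
    query_pos = aln.query_span[0] - 1
    for x, y in zip(aln.aligned_ref, aln.aligned_query):
        if x != "-":
            ref_pos += 1
        if y != "-":
            query_pos += 1
        if x != "-":
            mapping[ref_start + ref_pos - 1] = query_pos if y != "-" else None
    span = (ref_start + aln.ref_span[0] - 1, ref_start + aln.ref_span[1] - 1)
    return PositionMap(mapping, span)


def map_positions(aln: AlignmentResult, ref_numbers: list[int],
                  ref_start: int = 1) -> dict[int, int | str]:
    """Resolve selected reference residue numbers through an alignment."""
    pmap = full_position_map(aln, ref_start=ref_start)
    return {n: pmap.resolve(n) for n in ref_numbers}
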