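"""Shared pairwise-alignment primitives.

One scoring scheme is used throughout the toolkit (clustering, 5.8S anchoring
and chimera scoring): match +1, mismatch -1, gap open -2, gap extension -1.
A gap of length L therefore costs 2 + (L - 1).  Ambiguity codes are kept
as-is and match only themselves; this makes every comparison parameter-free
and exactly reproducible.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -2.0
GAP_EXTEND = -1.0


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


@lru_cache(maxsize=None)
def _global_aligner() -> Align.PairwiseAligner:
    return _make_aligner("global")


@lru_cache(maxsize=None)
def _anchor_aligner() -> Align.PairwiseAligner:
    # Glocal: the (short) probe must align end to end, the (long) record may
    # overhang freely on either side.  align(record, probe) with free
    # terminal insertions in the record achieves this.
    aligner = _make_aligner("global")
    aligner.end_deletion_score = 0.0  # free gaps over the record's overhangs
    return aligner


def global_alignment(a: str, b: str) -> tuple[str, str, float]:
    """Globally align two sequences; return (gapped_a, gapped_b, score)."""
    aln = _global_aligner().align(a, b)[0]
    return aln[0], aln[1], aln.score


def anchor_alignment(record: str, probe: str) -> tuple[int, int, float]:
    """Align ``probe`` end-to-end against ``record`` with free record overhangs.

    Returns ``(start, end, score)`` where ``[start, end)`` is the span of the
    record covered by the probe and ``score`` excludes the free end gaps.
    """
    aln = _anchor_aligner().align(record, probe)[0]
    blocks = aln.aligned[0]
    start = int(blocks[0][0])
    end = int(blocks[-1][1])
    return start, end, float(aln.score)


def identity_from_alignment(gapped_a: str, gapped_b: str) -> float:
    """Fraction of matching columns after trimming terminal gap columns."""
    n = len(gapped_a)
    lo = 0
    while lo < n and (gapped_a[lo] == "-" or gapped_b[lo] == "-"):
        lo += 1
    hi = n
    while hi > lo and (gapped_a[hi - 1] == "-" or gapped_b[hi - 1] == "-"):
        hi -= 1
    if hi <= lo:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if gapped_a[i] == gapped_b[i])
    return matches / (hi - lo)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences.

    Identity is the fraction of matching columns over all alignment columns
    after trimming terminal gap columns.  The argument order is canonicalised
    before aligning, so the function is exactly symmetric even when several
    co-optimal alignments exist.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    if b < a:
        a, b = b, a
    ga, gb, _ = global_alignment(a, b)
    return identity_from_alignment(ga, gb)


def project_to_query(query: str, parent: str) -> str:
    """Parent characters at each query position, via global alignment.

    Returns a string of ``len(query)`` characters: the parent residue aligned
    to each query base, or ``'-'`` where the parent has a deletion.  Alignment
    columns in which the query has a gap (parent insertions) carry no query
    coordinate and are dropped.
    """
    gq, gp, _ = global_alignment(query, parent)
    out = []
    for cq, cp in zip(gq, gp):
        if cq != "-":
            out.append(cp)
    assert len(out) == len(query)
    return "".join(out)
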