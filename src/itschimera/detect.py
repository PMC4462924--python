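"""Reference-mode chimera detection.

A query is compared against a trusted, chimera-free reference set.  The
query is cleaved into four (default) segments, each segment retrieves its
best-matching references by shared-word counting, and every promising pair
of candidate parents is scored with a vote-based crossover search:

Both putative parents are globally aligned to the query and projected onto
query coordinates.  Ignoring columns where query and both parents agree,
each remaining column casts a vote — for the model "parent A left of the
crossover, parent B right of it", a column left of the crossover is a *yes*
(query matches A but not B), a *no* (query matches B but not A) or an
*abstain* (query matches neither); the right side swaps the roles.  With
vote counts (Y_L, N_L, A_L) and (Y_R, N_R, A_R) each side earns a support
factor, and the score of a crossover is set by the weaker side:

    f_side = Y_side / (beta*N_side + alpha*A_side + reg)
    h      = min(f_left, f_right) ** 2

maximised over every crossover between informative columns and over both
parent orientations.  A genuine chimera has many yes votes and essentially
no no-votes on *both* sides, so both factors — and h, which is unbounded
above — are large; a clean sequence lying between two relatives accumulates
no-votes symmetrically and is crushed by the heavily weighted denominators,
while a chance run of agreement at one sequence end cannot carry the call
because the weaker side limits the score.  Two plausibility gates (in the
spirit of reference-mode bimera detectors) must additionally hold at the
optimum: each side needs at least ``min_diffs`` yes votes, and the
two-parent model must fit the query better than the best single parent by
at least ``min_div`` percentage points of sequence length.  Queries whose
best score exceeds the threshold (default 0.28) are flagged as putative
chimeras.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .align import project_to_query
from .cluster import ReferenceSet
from .io import ItsRecord, ResultsRow


@dataclass(frozen=True)
class DetectorParams:
    """Tunable knobs of the reference-mode detector."""

    n_segments: int = 4
    threshold: float = 0.28
    word_size: int = 8
    hits_per_segment: int = 4
    max_pairs: int = 24
    beta: float = 8.0  # weight of a no vote in the denominator
    alpha: float = 0.5  # weight of an abstain vote
    reg: float = 1.0  # denominator regulariser
    min_diffs: int = 10  # minimum yes votes required on each side
    min_div: float = 0.8  # minimum model improvement, % of query length
    self_exclude: bool = False

    def __post_init__(self) -> None:
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")
        if self.threshold <= 0 or self.beta <= 0:
            raise ValueError("threshold and beta must be positive")
        if self.word_size < 1 or self.hits_per_segment < 1 or self.max_pairs < 1:
            raise ValueError("word_size, hits_per_segment, max_pairs must be >= 1")
        if self.reg <= 0 or self.alpha < 0:
            raise ValueError("reg must be positive and alpha non-negative")


@dataclass(frozen=True)
class ChimeraCall:
    """Result of screening one query."""

    query_id: str
    score: float
    parent_a_id: str  # best left-side parent ("" when no pair was scorable)
    parent_b_id: str
    crossover: int  # query position of the first right-side informative column; -1 if none
    votes: tuple[int, int, int, int, int, int]  # (Y_L, N_L, A_L, Y_R, N_R, A_R)
    flag: bool

    def to_results_row(self) -> ResultsRow:
        return ResultsRow(
            score=self.score,
            query_id=self.query_id,
            parent_a_id=self.parent_a_id or "*",
            parent_b_id=self.parent_b_id or "*",
            crossover=self.crossover,
            flag=self.flag,
        )


def segment_query(seq: str, n_segments: int) -> list[str]:
    """Cleave a sequence into ``n_segments`` contiguous near-equal pieces.

    Lengths differ by at most one, longer segments first; the concatenation
    of the segments is exactly the input.
    """
    n = len(seq)
    if n < n_segments:
        raise ValueError(f"sequence of length {n} cannot form {n_segments} segments")
    base, extra = divmod(n, n_segments)
    out, pos = [], 0
    for i in range(n_segments):
        size = base + (1 if i < extra else 0)
        out.append(seq[pos : pos + size])
        pos += size
    return out


def kmer_set(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def build_kmer_index(
    refs: Sequence[ItsRecord], word_size: int
) -> dict[str, frozenset[str]]:
    """Precomputed word sets of a reference collection (id -> k-mer set)."""
    return {rec.id: kmer_set(rec.seq, word_size) for rec in refs}


def _ref_records(refs: ReferenceSet | Sequence[ItsRecord]) -> list[ItsRecord]:
    return list(refs.records) if isinstance(refs, ReferenceSet) else list(refs)


def find_candidate_parents(
    query: ItsRecord,
    refs: ReferenceSet | Sequence[ItsRecord],
    params: DetectorParams = DetectorParams(),
    index: Mapping[str, frozenset[str]] | None = None,
) -> list[str]:
    """Candidate parent ids: per-segment top shared-word hits, unioned.

    Each query segment ranks the references by the number of distinct shared
    ``word_size``-mers (ties broken by id); the top ``hits_per_segment``
    references with at least one shared word per segment are pooled.  The
    result is ordered by total shared words with the full query (descending,
    ties by id), which downstream pair enumeration relies on.
    """
    records = _ref_records(refs)
    if params.self_exclude:
        records = [r for r in records if r.id != query.id]
    if not records:
        return []
    if index is None:
        index = build_kmer_index(records, params.word_size)
    candidates: set[str] = set()
    for segment in segment_query(query.seq, params.n_segments):
        seg_kmers = kmer_set(segment, params.word_size)
        scored = sorted(
            ((len(seg_kmers & index[r.id]), r.id) for r in records),
            key=lambda t: (-t[0], t[1]),
        )
        candidates.update(rid for cnt, rid in scored[: params.hits_per_segment] if cnt > 0)
    full_kmers = kmer_set(query.seq, params.word_size)
    return sorted(candidates, key=lambda rid: (-len(full_kmers & index[rid]), rid))


@dataclass(frozen=True)
class PairScore:
    score: float
    crossover: int
    votes: tuple[int, int, int, int, int, int]
    a_is_left: bool


def _score_profiles(
    query: str, prof_a: str, prof_b: str, params: DetectorParams
) -> PairScore:
    """Crossover-optimised vote score given parent profiles in query coordinates."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    a = np.frombuffer(prof_a.encode(), dtype=np.uint8)
    b = np.frombuffer(prof_b.encode(), dtype=np.uint8)
    informative = ~((q == a) & (q == b))
    pos = np.flatnonzero(informative)
    ya = ((q == a) & (q != b))[pos].astype(np.int64)  # query sides with A
    yb = ((q == b) & (q != a))[pos].astype(np.int64)  # query sides with B
    ab = ((q != a) & (q != b))[pos].astype(np.int64)  # query matches neither
    K = len(pos)
    if K == 0:
        return PairScore(0.0, -1, (0, 0, 0, 0, 0, 0), True)

    CA = np.concatenate(([0], np.cumsum(ya)))
    CB = np.concatenate(([0], np.cumsum(yb)))
    CN = np.concatenate(([0], np.cumsum(ab)))
    mism_a = CB[-1] + CN[-1]  # query-parentA mismatching columns
    mism_b = CA[-1] + CN[-1]
    best_single = min(mism_a, mism_b)
    gain_needed = params.min_div / 100.0 * len(query)

    best = PairScore(0.0, -1, (0, 0, 0, 0, 0, 0), True)
    for a_is_left in (True, False):
        L_yes, L_no = (CA, CB) if a_is_left else (CB, CA)
        YL, NL, AL = L_yes, L_no, CN
        YR = L_no[-1] - L_no
        NR = L_yes[-1] - L_yes
        AR = CN[-1] - CN
        # model mismatches: no+abstain on the left, with roles swapped on the right
        model_mism = (NL + AL) + (NR + AR)
        f_left = YL / (params.beta * NL + params.alpha * AL + params.reg)
        f_right = YR / (params.beta * NR + params.alpha * AR + params.reg)
        # symmetric-evidence score: the weaker side limits the call
        score = np.minimum(f_left, f_right) ** 2
        ok = (
            (YL >= params.min_diffs)
            & (YR >= params.min_diffs)
            & (best_single - model_mism >= gain_needed)
        )
        score = np.where(ok, score, 0.0)
        k = int(np.argmax(score))
        if score[k] > best.score:
            best = PairScore(
                score=float(score[k]),
                crossover=int(pos[k]) if k < K else int(pos[-1]) + 1,
                votes=(
                    int(YL[k]), int(NL[k]), int(AL[k]),
                    int(YR[k]), int(NR[k]), int(AR[k]),
                ),
                a_is_left=a_is_left,
            )
    return best


def score_pair(
    query: str, parent_a: str, parent_b: str, params: DetectorParams = DetectorParams()
) -> PairScore:
    """Score one (query, parentA, parentB) triple.

    Aligns both parents to the query, projects them onto query coordinates
    and runs the crossover-optimised vote score over both orientations.
    ``PairScore.a_is_left`` reports the winning orientation.
    """
    if not (query and parent_a and parent_b):
        raise ValueError("all three sequences must be non-empty")
    prof_a = project_to_query(query, parent_a)
    prof_b = project_to_query(query, parent_b)
    return _score_profiles(query, prof_a, prof_b, params)


def detect_one(
    query: ItsRecord,
    refs: ReferenceSet | Sequence[ItsRecord],
    params: DetectorParams = DetectorParams(),
    index: Mapping[str, frozenset[str]] | None = None,
) -> ChimeraCall:
    """Screen one query against the reference set and return the best call."""
    records = _ref_records(refs)
    by_id = {r.id: r for r in records}
    cand = find_candidate_parents(query, records, params, index=index)
    pairs = [
        (i, j) for i in range(len(cand)) for j in range(i + 1, len(cand))
    ][: params.max_pairs]

    profiles: dict[str, str] = {}
    best_score: PairScore | None = None
    best_pair: tuple[str, str] = ("", "")
    for i, j in pairs:
        rid_a, rid_b = cand[i], cand[j]
        for rid in (rid_a, rid_b):
            if rid not in profiles:
                profiles[rid] = project_to_query(query.seq, by_id[rid].seq)
        ps = _score_profiles(query.seq, profiles[rid_a], profiles[rid_b], params)
        if best_score is None or ps.score > best_score.score:
            best_score = ps
            best_pair = (rid_a, rid_b) if ps.a_is_left else (rid_b, rid_a)
    if best_score is None:
        best_score = PairScore(0.0, -1, (0, 0, 0, 0, 0, 0), True)
    return ChimeraCall(
        query_id=query.id,
        score=best_score.score,
        parent_a_id=best_pair[0] if best_score.score > 0 else "",
        parent_b_id=best_pair[1] if best_score.score > 0 else "",
        crossover=best_score.crossover,
        votes=best_score.votes,
        flag=best_score.score > params.threshold,
    )


def screen_corpus(
    queries: Sequence[ItsRecord],
    refs: ReferenceSet | Sequence[ItsRecord],
    params: DetectorParams = DetectorParams(),
) -> tuple[list[ChimeraCall], list[ResultsRow]]:
    """Screen every query; returns the calls and their results-table rows."""
    records = _ref_records(refs)
    index = build_kmer_index(records, params.word_size)
    calls: list[ChimeraCall] = []
    for query in queries:
        pool = records
        idx = index
        if params.self_exclude and query.id in index:
            pool = [r for r in records if r.id != query.id]
        calls.append(detect_one(query, pool, params, index=idx))
    rows = [c.to_results_row() for c in calls]
    return calls, rows
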