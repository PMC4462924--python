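import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itschimera import (
    DetectorParams,
    ItsRecord,
    detect_one,
    find_candidate_parents,
    score_pair,
    screen_corpus,
    segment_query,
)
from itschimera.align import project_to_query
from itschimera.detect import _score_profiles
from oracles import brute_force_pair_score


def test_segment_even_split():
    assert [len(s) for s in segment_query("A" * 400, 4)] == [100] * 4


def test_segment_uneven_split_longer_first():
    assert [len(s) for s in segment_query("ABCDEFGHIJ", 4)] == [3, 3, 2, 2]


def test_segment_too_short_rejected():
    with pytest.raises(ValueError):
        segment_query("ACG", 4)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=4, max_size=200), st.integers(2, 4))
def test_segments_cover_sequence_exactly(seq, n):
    segments = segment_query(seq, n)
    assert "".join(segments) == seq
    lengths = [len(s) for s in segments]
    assert max(lengths) - min(lengths) <= 1
    assert lengths == sorted(lengths, reverse=True)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate_at(seq, positions):
    chars = list(seq)
    for pos in positions:
        chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
    return "".join(chars)


def _perfect_chimera(rng, length=400, per_side=10):
    """Query = left half of A + right half of B; A and B differ from each
    other at exactly ``per_side`` diagnostic positions on each side."""
    base = _random_seq(rng, length)
    half = length // 2
    left_pos = sorted(rng.choice(np.arange(5, half - 5), size=per_side, replace=False))
    right_pos = sorted(rng.choice(np.arange(half + 5, length - 5), size=per_side, replace=False))
    a = _mutate_at(base, right_pos)  # A carries the left allele everywhere
    b = _mutate_at(base, left_pos)  # B carries the right allele everywhere
    query = a[:half] + b[half:]
    return query, a, b


def test_query_identical_to_parent_scores_zero(rng):
    a = _random_seq(rng, 300)
    b = _mutate_at(a, range(0, 300, 10))
    result = score_pair(a, a, b)
    assert result.score == 0.0


def test_perfect_chimera_scores_100(rng):
    """Ten clean diagnostic columns per side give votes (10,0,0,10,0,0) and
    score min(10/1, 10/1)^2 = 100 at defaults."""
    query, a, b = _perfect_chimera(rng)
    result = score_pair(query, a, b)
    assert result.votes == (10, 0, 0, 10, 0, 0)
    assert result.score == pytest.approx(100.0)


def test_score_orientation_invariant(rng):
    query, a, b = _perfect_chimera(rng)
    assert score_pair(query, a, b).score == score_pair(query, b, a).score


def test_score_monotone_in_votes(rng):
    """Appending diagnostic yes-columns to both sides never decreases the
    score; turning them into no-columns never increases it."""
    query, a, b = _perfect_chimera(rng)
    base_score = score_pair(query, a, b).score
    tail = "ACGTACGTAC"
    unchanged = score_pair(query + tail, a + tail, b + tail).score  # uninformative
    assert unchanged == pytest.approx(base_score)
    # 5 extra yes-columns per side: query==A!=B prepended, query==B!=A appended
    grown = score_pair(
        "AAAAA" + query + "CCCCC",
        "AAAAA" + a + "GGGGG",
        "TTTTT" + b + "CCCCC",
    ).score
    assert grown >= base_score
    # 5 no-columns on the left (query==B!=A) can only hurt
    shrunk = score_pair("TTTTT" + query, "AAAAA" + a, "TTTTT" + b).score
    assert shrunk <= base_score


def test_score_pair_rejects_empty():
    with pytest.raises(ValueError):
        score_pair("", "ACGT", "ACGT")


def test_crossover_matches_exhaustive_scan(rng):
    """The vectorised crossover optimum equals a brute-force scan over every
    split and both orientations for random noisy triples."""
    params = DetectorParams(min_diffs=1, min_div=0.0)
    for _ in range(50):
        base = _random_seq(rng, 150)
        a = _mutate_at(base, rng.choice(150, size=12, replace=False))
        b = _mutate_at(base, rng.choice(150, size=12, replace=False))
        query = _mutate_at(base, rng.choice(150, size=6, replace=False))
        prof_a = project_to_query(query, a)
        prof_b = project_to_query(query, b)
        got = _score_profiles(query, prof_a, prof_b, params).score
        expected = brute_force_pair_score(query, prof_a, prof_b, params)
        assert got == pytest.approx(expected, abs=1e-12)


def test_candidates_rank_identical_reference_first(rng):
    refs = [ItsRecord(id=f"r{i}", seq=_random_seq(rng, 300)) for i in range(5)]
    query = ItsRecord(id="q", seq=refs[2].seq)
    cand = find_candidate_parents(query, refs)
    assert cand[0] == "r2"


def test_candidates_contain_both_chimera_parents(rng):
    refs = [ItsRecord(id=f"r{i}", seq=_random_seq(rng, 300)) for i in range(6)]
    query_seq = refs[1].seq[:150] + refs[4].seq[150:]
    cand = find_candidate_parents(ItsRecord(id="q", seq=query_seq), refs)
    assert {"r1", "r4"} <= set(cand)


def test_self_exclusion_empties_single_reference_set(rng):
    ref = ItsRecord(id="only", seq=_random_seq(rng, 300))
    cand = find_candidate_parents(ref, [ref], DetectorParams(self_exclude=True))
    assert cand == []
    call = detect_one(ref, [ref], DetectorParams(self_exclude=True))
    assert call.score == 0.0 and not call.flag and call.parent_a_id == ""


def test_detect_one_flags_constructed_chimera(rng):
    refs = [ItsRecord(id=f"r{i}", seq=_random_seq(rng, 400)) for i in range(8)]
    query_seq = refs[0].seq[:200] + refs[5].seq[200:]
    call = detect_one(ItsRecord(id="q", seq=query_seq), refs)
    assert call.flag
    assert {call.parent_a_id, call.parent_b_id} == {"r0", "r5"}
    assert call.parent_a_id == "r0"  # left parent reported on the A side


def test_screen_corpus_empty_queries(small_refset):
    _, annotated, _ = small_refset
    calls, rows = screen_corpus([], annotated)
    assert calls == [] and rows == []


def test_screen_corpus_deterministic(small_refset):
    _, annotated, _ = small_refset
    queries = annotated[:5]
    params = DetectorParams(self_exclude=True)
    calls1, rows1 = screen_corpus(queries, annotated, params)
    calls2, rows2 = screen_corpus(queries, annotated, params)
    assert calls1 == calls2 and rows1 == rows2


def test_detector_params_validation():
    with pytest.raises(ValueError):
        DetectorParams(n_segments=1)
    with pytest.raises(ValueError):
        DetectorParams(threshold=0.0)
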