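"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (plain Python,
no calls into the package's alignment or scoring paths beyond sequence
projection where stated) so that agreement with the package is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, inf

MATCH = 1.0
MISMATCH = -1.0
OPEN = -2.0
EXTEND = -1.0


def gotoh_score(a: str, b: str) -> float:
    """Optimal global affine-gap alignment score (gap of length L costs
    ``|OPEN| + (L-1)*|EXTEND|``), computed with a plain three-matrix DP."""
    n, m = len(a), len(b)
    M = [[-inf] * (m + 1) for _ in range(n + 1)]
    X = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in b (a_i unmatched)
    Y = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = OPEN + (i - 1) * EXTEND
    for j in range(1, m + 1):
        Y[0][j] = OPEN + (j - 1) * EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + OPEN, X[i - 1][j] + EXTEND, Y[i - 1][j] + OPEN)
            Y[i][j] = max(M[i][j - 1] + OPEN, Y[i][j - 1] + EXTEND, X[i][j - 1] + OPEN)
    return max(M[n][m], X[n][m], Y[n][m])


def _gotoh_tables(a: str, b: str):
    n, m = len(a), len(b)
    M = [[-inf] * (m + 1) for _ in range(n + 1)]
    X = [[-inf] * (m + 1) for _ in range(n + 1)]
    Y = [[-inf] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = OPEN + (i - 1) * EXTEND
    for j in range(1, m + 1):
        Y[0][j] = OPEN + (j - 1) * EXTEND
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + OPEN, X[i - 1][j] + EXTEND, Y[i - 1][j] + OPEN)
            Y[i][j] = max(M[i][j - 1] + OPEN, Y[i][j - 1] + EXTEND, X[i][j - 1] + OPEN)
    return M, X, Y


def enumerate_optimal_alignments(a: str, b: str, cap: int = 20000) -> list[tuple[str, str]]:
    """All *optimal* global alignments, by exhaustive traceback of the DP."""
    n, m = len(a), len(b)
    M, X, Y = _gotoh_tables(a, b)
    best = max(M[n][m], X[n][m], Y[n][m])
    out: list[tuple[str, str]] = []

    def rec(i, j, mat, ga, gb):
        if len(out) >= cap:
            return
        if i == 0 and j == 0:
            if mat == "M":
                out.append((ga, gb))
            return
        if mat == "M":
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            target = M[i][j] - s
            for prev in ("M", "X", "Y"):
                tab = {"M": M, "X": X, "Y": Y}[prev]
                if i >= 1 and j >= 1 and tab[i - 1][j - 1] == target:
                    rec(i - 1, j - 1, prev, a[i - 1] + ga, b[j - 1] + gb)
        elif mat == "X":  # a[i-1] over a gap
            if i >= 1:
                for prev, cost in (("M", OPEN), ("X", EXTEND), ("Y", OPEN)):
                    tab = {"M": M, "X": X, "Y": Y}[prev]
                    if tab[i - 1][j] + cost == X[i][j]:
                        rec(i - 1, j, prev, a[i - 1] + ga, "-" + gb)
        else:  # Y: b[j-1] over a gap
            if j >= 1:
                for prev, cost in (("M", OPEN), ("Y", EXTEND), ("X", OPEN)):
                    tab = {"M": M, "X": X, "Y": Y}[prev]
                    if tab[i][j - 1] + cost == Y[i][j]:
                        rec(i, j - 1, prev, "-" + ga, b[j - 1] + gb)

    for mat, tab in (("M", M), ("X", X), ("Y", Y)):
        if tab[n][m] == best:
            rec(n, m, mat, "", "")
    return out


def alignment_score(ga: str, gb: str) -> float:
    """Score of one explicit gapped alignment under the shared scheme."""
    score = 0.0
    prev_gap = None  # which row had the previous gap, for affine extension
    for ca, cb in zip(ga, gb):
        if ca == "-" or cb == "-":
            row = 0 if ca == "-" else 1
            score += EXTEND if prev_gap == row else OPEN
            prev_gap = row
        else:
            score += MATCH if ca == cb else MISMATCH
            prev_gap = None
    return score


def alignment_identity(ga: str, gb: str) -> float:
    """Matching columns / columns, after trimming terminal gap columns."""
    lo, hi = 0, len(ga)
    while lo < hi and ("-" in (ga[lo], gb[lo])):
        lo += 1
    while hi > lo and ("-" in (ga[hi - 1], gb[hi - 1])):
        hi -= 1
    if hi <= lo:
        return 0.0
    matches = sum(ga[i] == gb[i] for i in range(lo, hi))
    return matches / (hi - lo)


def optimal_identities(a: str, b: str) -> set[float]:
    """Identities achievable by the optimal alignments of two short seqs."""
    alns = enumerate_optimal_alignments(a, b)
    best = gotoh_score(a, b)
    assert all(alignment_score(ga, gb) == best for ga, gb in alns)
    return {alignment_identity(ga, gb) for ga, gb in alns}


def brute_force_pair_score(query, prof_a, prof_b, params):
    """Maximum gated vote score over every crossover and both orientations.

    Recomputes vote counts per split with explicit loops from the projected
    parent profiles; independent of the package's vectorised scorer.
    """
    cols = [
        (q, pa, pb)
        for q, pa, pb in zip(query, prof_a, prof_b)
        if not (q == pa == pb)
    ]
    K = len(cols)
    n = len(query)
    mism_a = sum(q != pa for q, pa, _ in cols)
    mism_b = sum(q != pb for q, _, pb in cols)
    best = 0.0
    for a_left in (True, False):
        for k in range(K + 1):
            yl = nl = al = yr = nr = ar = 0
            for idx, (q, pa, pb) in enumerate(cols):
                left = idx < k
                if q != pa and q != pb:
                    al, ar = (al + 1, ar) if left else (al, ar + 1)
                    continue
                matches_a = q == pa
                yes_side = matches_a == a_left  # matches the side's own parent
                if left:
                    yl, nl = (yl + 1, nl) if yes_side else (yl, nl + 1)
                else:
                    yr, nr = (yr, nr + 1) if yes_side else (yr + 1, nr)
            if yl < params.min_diffs or yr < params.min_diffs:
                continue
            model_mism = nl + al + nr + ar
            if min(mism_a, mism_b) - model_mism < params.min_div / 100.0 * n:
                continue
            fl = yl / (params.beta * nl + params.alpha * al + params.reg)
            fr = yr / (params.beta * nr + params.alpha * ar + params.reg)
            best = max(best, min(fl, fr) ** 2)
    return best


def exact_rank_sum_p(group_a, group_b) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration (small groups).

    Enumerates every assignment of the pooled midranks to group a and
    compares the achieved U against the exact permutation distribution.
    """
    pooled = sorted(group_a) + sorted(group_b)
    values = sorted(pooled)
    ranks = {}
    i = 0
    assigned = [0.0] * len(values)
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            assigned[k] = mid
        i = j
    for v, r in zip(values, assigned):
        ranks.setdefault(v, r)
    n_a, n_b = len(group_a), len(group_b)
    rank_list = [ranks[v] for v in values]
    obs_r = sum(ranks[v] for v in group_a)
    obs_u = obs_r - n_a * (n_a + 1) / 2.0
    mean_u = n_a * n_b / 2.0
    total = comb(n_a + n_b, n_a)
    extreme = 0
    obs_dev = abs(obs_u - mean_u)
    for idx in combinations(range(n_a + n_b), n_a):
        u = sum(rank_list[i] for i in idx) - n_a * (n_a + 1) / 2.0
        if abs(u - mean_u) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total
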