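"""Naive full-matrix Smith-Waterman-Gotoh: the package's reference aligner.

Everything here is deliberately simple: complete score matrices are
materialized in O(nm) memory and filled with plain Python loops, with no
striping, no banding and no early termination.  This module is the ground
truth against which the striped engine and the banded traceback are
verified, and it is shipped (not test-only) so any alignment the fast path
produces can be independently re-derived.

The begin/end tie rules are the package-wide ones, each realised naively:
the end cell is the one in the leftmost target column attaining the optimum,
then the smallest query row; the begin cell comes from a full reversed DP
(leftmost reversed column, i.e. the largest possible ``ref_begin``); the
CIGAR is the traceback of a full global affine DP over the pinned rectangle,
preferring a diagonal step over a target-consuming gap over a
query-consuming gap, and closing a gap over extending it, at equal score.

Gap convention: a gap of length k costs ``gap_open + (k-1)*gap_extend``.
"""

from __future__ import annotations

import numpy as np

from .alignment import AlignmentResult, Cigar
from .seqio import ScoringScheme

__all__ = ["naive_sw", "naive_column_maxima"]

_NEG = -(1 << 40)


def _codes(seq) -> list[int]:
    return [int(c) for c in np.asarray(seq).ravel()]


def _local_fill(q: list[int], t: list[int], scheme: ScoringScheme):
    """Full local H matrix (n rows x m columns), plain Gotoh recurrences.

    E is the query-consuming gap state (depends on the previous query row),
    F the target-consuming one (depends on the previous target column).
    """
    n, m = len(q), len(t)
    S = scheme.scores.tolist()
    go, ge = int(scheme.gap_open), int(scheme.gap_extend)
    H: list[list[int]] = []
    e_prev = [_NEG] * m
    h_up_row: list[int] | None = None
    for i in range(n):
        Si = S[q[i]]
        h_row = [0] * m
        e_row = [0] * m
        f = _NEG
        h_left = 0
        diag = 0  # H(i-1, k-1), boundary 0
        for k in range(m):
            h_up = h_up_row[k] if i else 0
            e = h_up - go
            alt = e_prev[k] - ge
            if alt > e:
                e = alt
            fo = h_left - go
            fx = f - ge
            f = fo if fo > fx else fx
            h = diag + Si[t[k]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = h_up
            h_left = h
            h_row[k] = h
            e_row[k] = e
        H.append(h_row)
        e_prev = e_row
        h_up_row = h_row
    return H


def naive_column_maxima(query_codes, target_codes,
                        scheme: ScoringScheme) -> list[int]:
    """Per-target-column maximum of H over all query rows."""
    q, t = _codes(query_codes), _codes(target_codes)
    if not q or not t:
        raise ValueError("sequences must be non-empty")
    H = _local_fill(q, t, scheme)
    return [max(col) for col in zip(*H)]


def _global_traceback(q: list[int], t: list[int], scheme: ScoringScheme):
    """Global affine alignment of the whole rectangle: (score, Cigar)."""
    nq, nr = len(q), len(t)
    S = scheme.scores.tolist()
    go, ge = int(scheme.gap_open), int(scheme.gap_extend)
    H = [[_NEG] * (nr + 1) for _ in range(nq + 1)]
    E = [[_NEG] * (nr + 1) for _ in range(nq + 1)]  # query-consuming
    F = [[_NEG] * (nr + 1) for _ in range(nq + 1)]  # target-consuming
    H[0][0] = 0
    for i in range(1, nq + 1):
        H[i][0] = E[i][0] = -(go + (i - 1) * ge)
    for j in range(1, nr + 1):
        H[0][j] = F[0][j] = -(go + (j - 1) * ge)
    for i in range(1, nq + 1):
        Si = S[q[i - 1]]
        Hi, Hu, Ei, Eu, Fi = H[i], H[i - 1], E[i], E[i - 1], F[i]
        for j in range(1, nr + 1):
            e = max(Hu[j] - go, Eu[j] - ge)
            f = max(Hi[j - 1] - go, Fi[j - 1] - ge)
            h = Hu[j - 1] + Si[t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
    i, j = nq, nr
    ops: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            h = H[i][j]
            if (i > 0 and j > 0
                    and h == H[i - 1][j - 1] + S[q[i - 1]][t[j - 1]]):
                ops.append("M")
                i -= 1
                j -= 1
            elif j > 0 and h == F[i][j]:
                state = "F"
            elif i > 0 and h == E[i][j]:
                state = "E"
            else:  # pragma: no cover - would indicate a fill bug
                raise RuntimeError("oracle traceback lost its path")
        elif state == "F":  # target-consuming gap -> D
            ops.append("D")
            if F[i][j] == H[i][j - 1] - go:
                state = "H"
            j -= 1
        else:  # query-consuming gap -> I
            ops.append("I")
            if E[i][j] == H[i - 1][j] - go:
                state = "H"
            i -= 1
    runs: list[tuple[int, str]] = []
    for op in reversed(ops):
        if runs and runs[-1][1] == op:
            runs[-1] = (runs[-1][0] + 1, op)
        else:
            runs.append((1, op))
    return H[nq][nr], Cigar(runs)


def naive_sw(query_codes, target_codes, scheme: ScoringScheme,
             mask_margin: int = 0) -> AlignmentResult:
    """Optimal local alignment by exhaustive dynamic programming.

    Returns the same result object as the fast path: score, begin/end
    coordinates on both sequences, CIGAR, and the second-best column maximum
    outside the (optionally widened) primary target interval.
    """
    q, t = _codes(query_codes), _codes(target_codes)
    if not q or not t:
        raise ValueError("sequences must be non-empty")
    H = _local_fill(q, t, scheme)
    n, m = len(q), len(t)
    col_max = [max(col) for col in zip(*H)]
    best = max(col_max)
    if best <= 0:
        return AlignmentResult(score1=0, score2=0)
    k_end = col_max.index(best)
    i_end = next(i for i in range(n) if H[i][k_end] == best)
    # begin cell: full DP on the reversed prefixes; the leftmost reversed
    # column attaining the optimum is the largest possible ref_begin
    rq = q[:i_end + 1][::-1]
    rt = t[:k_end + 1][::-1]
    Hr = _local_fill(rq, rt, scheme)
    col_max_r = [max(col) for col in zip(*Hr)]
    k_rev = col_max_r.index(best)
    i_rev = next(i for i in range(len(rq)) if Hr[i][k_rev] == best)
    i_beg = i_end - i_rev
    k_beg = k_end - k_rev
    score, cigar = _global_traceback(q[i_beg:i_end + 1], t[k_beg:k_end + 1],
                                     scheme)
    if score != best:  # pragma: no cover - would indicate a fill bug
        raise RuntimeError(
            f"rectangle alignment scored {score}, expected {best}")
    lo = max(0, k_beg - mask_margin)
    hi = min(m - 1, k_end + mask_margin)
    score2, ref_end2 = 0, None
    for k in range(m):
        if lo <= k <= hi:
            continue
        if col_max[k] > score2:
            score2, ref_end2 = col_max[k], k
    if score2 <= 0:
        score2, ref_end2 = 0, None
    return AlignmentResult(score1=best, score2=score2,
                           ref_begin=k_beg, ref_end=k_end,
                           query_begin=i_beg, query_end=i_end,
                           ref_end2=ref_end2, cigar=cigar)
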