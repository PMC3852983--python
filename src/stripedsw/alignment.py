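"""Alignment recovery: begin location, banded traceback, and orchestration.

The forward pass only yields the optimal score and its end cell.  The begin
cell is found by running the same striped fill on the reversed sequence
prefixes, stopping at the first column that attains the known optimum; the
detailed alignment is then produced by a small global affine-gap DP confined
to the located rectangle and restricted to a diagonal band, whose half-width
doubles until the corner-to-corner score reaches the optimum.  :func:`align`
chains the whole procedure and adds the masked second-best score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .engine import (DEFAULT_LANES, build_profile, locate_query_end,
                     second_best, striped_fill)
from .seqio import ScoringScheme, SequenceRecord, encode

__all__ = [
    "Cigar",
    "AlignmentResult",
    "InconsistencyError",
    "locate_begin",
    "banded_fill",
    "score_cigar",
    "align",
]

logger = logging.getLogger(__name__)

_NEG = -(1 << 40)


class InconsistencyError(RuntimeError):
    """The traceback could not reproduce the score the engine reported."""


@dataclass
class Cigar:
    """Run-length encoded alignment: M consumes both sequences, I the query
    only, D the target only (SAM semantics)."""

    runs: list[tuple[int, str]]

    def __str__(self) -> str:
        return "".join(f"{length}{op}" for length, op in self.runs)

    @classmethod
    def from_string(cls, text: str) -> "Cigar":
        runs: list[tuple[int, str]] = []
        num = ""
        for ch in text:
            if ch.isdigit():
                num += ch
            elif ch in "MID" and num:
                runs.append((int(num), ch))
                num = ""
            else:
                raise ValueError(f"malformed CIGAR {text!r}")
        if num:
            raise ValueError(f"malformed CIGAR {text!r}")
        return cls(runs)

    @property
    def query_span(self) -> int:
        return sum(n for n, op in self.runs if op in "MI")

    @property
    def ref_span(self) -> int:
        return sum(n for n, op in self.runs if op in "MD")

    def __eq__(self, other) -> bool:
        if isinstance(other, str):
            return str(self) == other
        if isinstance(other, Cigar):
            return self.runs == other.runs
        return NotImplemented


@dataclass
class AlignmentResult:
    """Optimal local alignment plus the heuristic suboptimal score.

    ``score1`` is the optimal Smith-Waterman score; a value of 0 means the
    empty alignment and leaves every coordinate ``None``.  ``score2`` is the
    best column maximum outside the masked primary target interval and
    ``ref_end2`` the target column where it occurs.  All coordinates are
    0-based inclusive.
    """

    score1: int
    score2: int = 0
    ref_begin: int | None = None
    ref_end: int | None = None
    query_begin: int | None = None
    query_end: int | None = None
    ref_end2: int | None = None
    cigar: Cigar | None = None

    @property
    def is_empty(self) -> bool:
        return self.score1 == 0


def score_cigar(cigar: Cigar, query_codes, target_codes, query_begin: int,
                ref_begin: int, scheme: ScoringScheme) -> int:
    """Re-derive the score of an explicit alignment path.

    Walks the CIGAR from ``(query_begin, ref_begin)``, summing substitution
    scores for M runs and charging ``gap_open + (len-1)*ext`` per gap run,
    where ``ext = min(gap_open, gap_extend)``: when opening is cheaper than
    extending, the Gotoh recurrences let a gap close and reopen at every
    step, so that is the cost a DP path actually pays.  Used to verify that
    any reported alignment reproduces its score.
    """
    q = np.asarray(query_codes, dtype=np.intp).ravel()
    t = np.asarray(target_codes, dtype=np.intp).ravel()
    S = scheme.scores
    ext = min(scheme.gap_open, scheme.gap_extend)
    i, k = query_begin, ref_begin
    total = 0
    for length, op in cigar.runs:
        if op == "M":
            total += int(S[q[i:i + length], t[k:k + length]].sum())
            i += length
            k += length
        elif op == "I":
            total -= scheme.gap_open + (length - 1) * ext
            i += length
        elif op == "D":
            total -= scheme.gap_open + (length - 1) * ext
            k += length
        else:
            raise ValueError(f"unknown CIGAR op {op!r}")
    return total


def locate_begin(query_codes, target_codes, query_end: int, ref_end: int,
                 scheme: ScoringScheme, best_score: int,
                 lanes: int = DEFAULT_LANES) -> tuple[int, int]:
    """Find the alignment begin by a reversed striped fill.

    Aligns ``reverse(query[:query_end+1])`` against
    ``reverse(target[:ref_end+1])`` and stops at the first target column
    whose maximum attains ``best_score``; that column index and the smallest
    attaining query offset map back to ``(query_begin, ref_begin)``.
    Stopping at the first such column yields the largest possible
    ``ref_begin``, which together with the engine's leftmost-end rule pins a
    unique optimal rectangle.
    """
    q = np.asarray(query_codes, dtype=np.intp).ravel()
    t = np.asarray(target_codes, dtype=np.intp).ravel()
    rq = q[:query_end + 1][::-1]
    rt = t[:ref_end + 1][::-1]
    profile = build_profile(rq, scheme, lanes)
    summary = striped_fill(profile, rt, scheme.gap_open, scheme.gap_extend,
                           stop_at=best_score)
    if summary.best_score != best_score:
        raise InconsistencyError(
            f"reversed fill reached {summary.best_score}, engine reported "
            f"{best_score}")
    rev_q_end = locate_query_end(summary)
    rev_t_end = summary.best_target_index
    return query_end - rev_q_end, ref_end - rev_t_end


def _banded_pass(q, t, S, go, ge, w):
    """One global affine DP over the rectangle within band half-width w."""
    nq, nr = len(q), len(t)
    delta = nr - nq
    lo = min(0, delta) - w
    hi = max(0, delta) + w
    H = [[_NEG] * (nr + 1) for _ in range(nq + 1)]
    E = [[_NEG] * (nr + 1) for _ in range(nq + 1)]  # query-consuming gap
    F = [[_NEG] * (nr + 1) for _ in range(nq + 1)]  # target-consuming gap
    H[0][0] = 0
    for i in range(1, nq + 1):
        v = -(go + (i - 1) * ge)
        H[i][0] = v
        E[i][0] = v
    for j in range(1, nr + 1):
        v = -(go + (j - 1) * ge)
        H[0][j] = v
        F[0][j] = v
    for i in range(1, nq + 1):
        Si = S[q[i - 1]]
        Hi, Hu = H[i], H[i - 1]
        Ei, Eu = E[i], E[i - 1]
        Fi = F[i]
        for j in range(max(1, i + lo), min(nr, i + hi) + 1):
            e = Hu[j] - go
            alt = Eu[j] - ge
            if alt > e:
                e = alt
            f = Hi[j - 1] - go
            alt = Fi[j - 1] - ge
            if alt > f:
                f = alt
            h = Hu[j - 1] + Si[t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
    return H, E, F


def _traceback_global(q, t, S, go, H, E, F):
    """Corner-to-corner walk; prefers M over D over I and closing a gap over
    extending it at equal score."""
    i, j = len(q), len(t)
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
            else:  # pragma: no cover
                raise InconsistencyError("banded traceback lost its path")
        elif state == "F":
            ops.append("D")
            if F[i][j] == H[i][j - 1] - go:
                state = "H"
            j -= 1
        else:
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
    return Cigar(runs)


def banded_fill(query_codes, target_codes, begin: tuple[int, int],
                end: tuple[int, int], scheme: ScoringScheme, best_score: int,
                stats: dict | None = None) -> Cigar:
    """Detailed alignment of the located rectangle by banded global DP.

    The initial band half-width is ``|ref_span - query_span| + 1``; while the
    banded corner-to-corner optimum falls short of ``best_score`` the
    half-width doubles.  The located rectangle always suffices, so a band
    that outgrows the rectangle without attaining the score signals an
    engine/traceback inconsistency.
    """
    qb, rb = begin
    qe, re = end
    q = [int(c) for c in np.asarray(query_codes).ravel()[qb:qe + 1]]
    t = [int(c) for c in np.asarray(target_codes).ravel()[rb:re + 1]]
    S = scheme.scores.tolist()
    go, ge = int(scheme.gap_open), int(scheme.gap_extend)
    nq, nr = len(q), len(t)
    w = abs(nr - nq) + 1
    doublings = 0
    while True:
        H, E, F = _banded_pass(q, t, S, go, ge, w)
        score = H[nq][nr]
        if score >= best_score:
            if score > best_score:  # pragma: no cover
                raise InconsistencyError(
                    f"banded score {score} exceeds engine optimum {best_score}")
            if stats is not None:
                stats["doublings"] = doublings
                stats["half_width"] = w
            logger.debug("banded fill: half-width %d after %d doubling(s)",
                         w, doublings)
            return _traceback_global(q, t, S, go, H, E, F)
        covers = (min(0, nr - nq) - w <= -nq) and (max(0, nr - nq) + w >= nr)
        if covers:
            raise InconsistencyError(
                f"band covers the whole rectangle but the score {score} "
                f"never reached {best_score}")
        w *= 2
        doublings += 1


def _as_codes(seq, scheme: ScoringScheme) -> np.ndarray:
    if isinstance(seq, (str, SequenceRecord)):
        return encode(seq, scheme)
    return np.asarray(seq, dtype=np.intp).ravel()


def align(query, target, scheme: ScoringScheme, *,
          lanes: int = DEFAULT_LANES, report_cigar: bool = True,
          mask_margin: int = 0) -> AlignmentResult:
    """Full striped alignment of one query/target pair.

    Runs the forward striped fill, locates the end cell from the column
    maxima and the recorded best column, recovers the begin cell by the
    reversed fill, produces the CIGAR by the banded DP (unless
    ``report_cigar`` is off), and reports the second-best column maximum
    outside the primary target interval widened by ``mask_margin``.  When
    the CIGAR (and hence the begin) is skipped, the mask falls back to the
    heuristic interval ``[ref_end - len(query), ref_end]``.

    ``query`` and ``target`` may be residue strings,
    :class:`~stripedsw.seqio.SequenceRecord` objects, or pre-encoded code
    arrays.
    """
    if mask_margin < 0:
        raise ValueError("mask_margin must be non-negative")
    qc = _as_codes(query, scheme)
    tc = _as_codes(target, scheme)
    profile = build_profile(qc, scheme, lanes)
    summary = striped_fill(profile, tc, scheme.gap_open, scheme.gap_extend)
    if summary.best_score <= 0:
        return AlignmentResult(score1=0, score2=0)
    best = summary.best_score
    ref_end = summary.best_target_index
    query_end = locate_query_end(summary)
    m = tc.size
    if report_cigar:
        query_begin, ref_begin = locate_begin(qc, tc, query_end, ref_end,
                                              scheme, best, lanes=lanes)
        cigar = banded_fill(qc, tc, (query_begin, ref_begin),
                            (query_end, ref_end), scheme, best)
        lo = max(0, ref_begin - mask_margin)
    else:
        query_begin = ref_begin = None
        cigar = None
        lo = max(0, ref_end - int(qc.size) - mask_margin)
    hi = min(m - 1, ref_end + mask_margin)
    score2, ref_end2 = second_best(summary.column_maxima, lo, hi)
    return AlignmentResult(score1=best, score2=score2,
                           ref_begin=ref_begin, ref_end=ref_end,
                           query_begin=query_begin, query_end=query_end,
                           ref_end2=ref_end2, cigar=cigar)
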