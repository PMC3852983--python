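"""Striped Smith-Waterman-Gotoh forward pass.

The query is laid out in Farrar's striped order: with ``p`` lanes and segment
length ``L = ceil(n/p)``, the lane-vector at segment position ``i`` holds
query positions ``j*L + i`` for lanes ``j = 0..p-1``.  One pass over the
``L`` segment positions advances a whole target column; the only dependency
that crosses lanes — the query-consuming gap state F — is repaired afterwards
by the lazy-F correction loop, which re-sweeps the column only while some
lane's propagated F can still raise H (or, through H, the saved E vectors),
and exits early.

Alongside the fill, the engine records the maximum H of every target column
(the "max" array), the column holding the global optimum, and that column's
full score vector; these drive end-position location and the masked
second-best (suboptimal) score without storing the matrix.

Scores are unbounded int64 throughout; the 8-bit/16-bit saturating registers
of SIMD implementations are a hardware device this package does not emulate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .seqio import ScoringScheme

__all__ = [
    "StripedProfile",
    "FillSummary",
    "build_profile",
    "striped_fill",
    "locate_query_end",
    "second_best",
    "DEFAULT_LANES",
]

logger = logging.getLogger(__name__)

DEFAULT_LANES = 8

#: padding / "minus infinity" sentinel.  Far below any reachable score but
#: with enough int64 headroom that per-column gap subtractions never wrap.
NEG = np.int64(-(1 << 40))


@dataclass(eq=False)
class StripedProfile:
    """Per-residue query profile in striped segment order.

    ``profile[s, i, j]`` is the substitution score of alphabet symbol ``s``
    against query position ``j*seg_len + i``; positions past the query end
    hold the :data:`NEG` sentinel so no positive path can cross them.
    """

    query_codes: np.ndarray
    lanes: int
    seg_len: int
    profile: np.ndarray          # (|alphabet|, seg_len, lanes)
    pad_mask: np.ndarray | None  # (seg_len, lanes) bool, True at padding

    def __len__(self) -> int:
        return len(self.query_codes)


@dataclass(eq=False)
class FillSummary:
    """What one forward pass records: the optimum and the column maxima."""

    best_score: int
    best_target_index: int
    column_maxima: np.ndarray      # length = number of target columns filled
    best_column_scores: np.ndarray  # length n, H of the best column, query order

    def __post_init__(self) -> None:
        assert self.column_maxima[self.best_target_index] == self.best_score


def build_profile(query_codes, scheme: ScoringScheme,
                  lanes: int = DEFAULT_LANES) -> StripedProfile:
    """Precompute the striped query profile for every alphabet symbol."""
    qc = np.asarray(query_codes, dtype=np.intp).ravel()
    n = qc.size
    if n == 0:
        raise ValueError("query must be non-empty")
    if lanes < 1:
        raise ValueError("lane count must be >= 1")
    seg_len = math.ceil(n / lanes)
    padded = np.full(seg_len * lanes, -1, dtype=np.intp)
    padded[:n] = qc
    grid = padded.reshape(lanes, seg_len).T          # grid[i, j] = pos j*L+i
    pad = grid < 0
    safe = np.where(pad, 0, grid)
    prof = scheme.scores[:, safe].astype(np.int64)   # (A, L, p)
    if pad.any():
        prof[:, pad] = NEG
        pad_mask = pad
    else:
        pad_mask = None
    return StripedProfile(qc, lanes, seg_len, prof, pad_mask)


def _shift(v: np.ndarray, fill: np.int64) -> np.ndarray:
    """Move lane j to lane j+1 (crossing a segment boundary in query order)."""
    out = np.empty_like(v)
    out[0] = fill
    out[1:] = v[:-1]
    return out


def striped_fill(profile: StripedProfile, target_codes, gap_open: int,
                 gap_extend: int, stop_at: int | None = None) -> FillSummary:
    """Run the striped fill over all target columns.

    Implements the Gotoh recurrences
    ``H(i,k) = max(0, H(i-1,k-1) + s(q_i, t_k), E(i,k), F(i,k))`` with
    affine gap states, scheduled in striped order: per column one vectorized
    pass over segment positions using the E vectors saved from the previous
    column, then the lazy-F correction loop.  ``stop_at`` truncates the fill
    at the first column whose maximum reaches that score (used by the
    reversed pass that locates alignment begins).
    """
    tc = np.asarray(target_codes, dtype=np.intp).ravel()
    if tc.size == 0:
        raise ValueError("target must be non-empty")
    go = np.int64(int(gap_open))
    ge = np.int64(int(gap_extend))
    L, p = profile.seg_len, profile.lanes
    n = len(profile)
    prof = profile.profile
    pad = profile.pad_mask

    h_load = np.zeros((L, p), dtype=np.int64)   # previous column's H
    e_store = np.full((L, p), NEG, dtype=np.int64)  # target-gap state, saved
    column_maxima = np.zeros(tc.size, dtype=np.int64)
    best = np.int64(-1)
    best_idx = 0
    best_col = np.zeros((L, p), dtype=np.int64)
    filled = tc.size

    for k, t in enumerate(tc):
        prof_t = prof[t]
        h_store = np.empty((L, p), dtype=np.int64)
        f_in = np.empty((L, p), dtype=np.int64)  # F entering each cell
        v_h = _shift(h_load[L - 1], np.int64(0))  # diagonal feed for row 0
        v_f = np.full(p, NEG, dtype=np.int64)
        for i in range(L):
            v_h = v_h + prof_t[i]
            np.maximum(v_h, e_store[i], out=v_h)
            np.maximum(v_h, v_f, out=v_h)
            np.maximum(v_h, 0, out=v_h)
            f_in[i] = v_f
            h_store[i] = v_h
            h_go = v_h - go
            np.maximum(e_store[i] - ge, h_go, out=e_store[i])
            v_f = np.maximum(v_f - ge, h_go)
            v_h = h_load[i]
        # Lazy-F: propagate F across segment boundaries until the incoming F
        # is dominated by one already applied at that cell (exact fixpoint;
        # integer scores make this terminate).
        v_f = _shift(v_f, NEG)
        sweeping = True
        while sweeping:
            sweeping = False
            for i in range(L):
                if not (v_f > f_in[i]).any():
                    break
                np.maximum(f_in[i], v_f, out=f_in[i])
                np.maximum(h_store[i], v_f, out=h_store[i])
                v_f = np.maximum(v_f - ge, h_store[i] - go)
            else:
                v_f = _shift(v_f, NEG)
                sweeping = True
        if pad is not None:
            h_store[pad] = 0
        # lazy raises of H feed the next column's target-gap state
        np.maximum(e_store, h_store - go, out=e_store)
        cm = h_store.max()
        column_maxima[k] = cm
        if cm > best:
            best = cm
            best_idx = k
            best_col = h_store.copy()
        h_load = h_store
        if stop_at is not None and cm >= stop_at:
            filled = k + 1
            break

    best_scores = best_col.T.ravel()[:n]  # un-stripe to query order
    return FillSummary(int(max(best, 0)), best_idx,
                       column_maxima[:filled], best_scores)


def locate_query_end(summary: FillSummary) -> int | None:
    """Smallest query index attaining the optimum within the best column.

    Returns ``None`` when the best score is 0 (empty alignment).
    """
    if summary.best_score <= 0:
        return None
    hits = np.flatnonzero(summary.best_column_scores == summary.best_score)
    return int(hits[0])


def second_best(column_maxima, mask_lo: int,
                mask_hi: int) -> tuple[int, int | None]:
    """Largest column maximum outside the closed interval [mask_lo, mask_hi].

    Returns ``(score2, ref_end2)`` with ``ref_end2`` the leftmost column
    attaining it, or ``(0, None)`` when every column is masked or nothing
    positive remains.
    """
    cm = np.asarray(column_maxima, dtype=np.int64).ravel()
    m = cm.size
    if not (0 <= mask_lo <= mask_hi < m):
        raise ValueError(f"invalid mask interval [{mask_lo}, {mask_hi}] "
                         f"for {m} columns")
    keep = np.ones(m, dtype=bool)
    keep[mask_lo:mask_hi + 1] = False
    if not keep.any():
        return 0, None
    outside = np.where(keep, cm, np.int64(-1))
    score2 = int(outside.max())
    if score2 <= 0:
        return 0, None
    return score2, int(np.flatnonzero(outside == score2)[0])
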