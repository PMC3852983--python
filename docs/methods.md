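# Methods

## Model

The aligner computes optimal local pairwise alignment under the
Smith-Waterman-Gotoh model: three coupled dynamic programs `H` (alignment
ends in a substitution column), `E` (ends in a query-consuming gap) and `F`
(ends in a target-consuming gap), with affine gap costs.  Penalties are
stored as non-negative magnitudes; a gap of length *k* costs
`gap_open + (k-1)·gap_extend`.  The type deliberately permits
`gap_open < gap_extend`; in that regime the recurrences let a gap close and
re-open at every step, so the effective cost of extending is
`min(gap_open, gap_extend)`.  `score_cigar` and the planted-alignment
scorer charge gaps accordingly, which keeps "re-score the CIGAR" an exact
identity for every admissible parameter pair rather than only the usual
`gap_open ≥ gap_extend` case.

## Striped fill

The engine follows the striped schedule: per target column, one pass over
segment positions operating on whole lane-vectors (numpy int64 arrays of
width `lanes`), with the target-gap vectors `E` saved between columns, then
the lazy-F loop.  Two details differ from the classic SIMD C lineage, both
in the direction of exactness:

* **Lazy-loop exit test.**  The loop keeps, per cell, the largest
  query-consuming gap score that has ever entered it (`f_in`).  A re-sweep
  stops as soon as the propagated `F` is dominated by `f_in` everywhere in
  the current segment row.  Because the propagation map is monotone and all
  scores are integers, this reaches the exact Gotoh fixpoint and
  terminates; it does not rely on `gap_open ≥ gap_extend` the way the
  traditional `F > H - gap_open` test does.
* **E repair.**  If the lazy loop raises `H` in a column, the saved `E`
  vectors are re-maxed against `H - gap_open` afterwards (one vector
  operation per column).  Classic implementations skip this, thereby
  forbidding an insertion directly after a deletion; here the recurrences
  hold exactly, which is also what the shipped naive reference computes.

Scores are unbounded int64; the padding sentinel (−2⁴⁰) is far enough from
the int64 limits that per-column subtractions can never wrap.  Padding
cells are forced to `H = 0` after each column so they cannot contaminate
the column maxima.  The default lane count is 8 and is purely a layout
choice: the fill is bit-identical for lanes ∈ {1, 2, 4, 8, 16} (tested).

## End, begin, CIGAR

The optimal end is the leftmost target column attaining the best score,
then the smallest query index inside that column's recorded score vector —
deterministic, order-independent tie rules.  The begin comes from a second
striped fill over the reversed prefixes, stopped at the first column to
attain the known optimum; that choice yields the largest admissible
`ref_begin` and `query_begin`, and together with the leftmost-end rule pins
a unique rectangle.  A consequence worth noting: the reported alignment
never starts or ends with a gap, for any non-negative penalty pair, because
a boundary gap could be dropped without lowering the score and would
contradict the extremal begin/end choice.

The CIGAR is produced by a global affine DP from rectangle corner to
corner, restricted to a diagonal band of initial half-width
`|ref_span - query_span| + 1`, doubled until the corner score equals the
known optimum (it always does before the band outgrows the rectangle; a
violation raises `InconsistencyError` rather than returning a wrong
alignment).  Traceback prefers a diagonal step over a target-consuming gap
over a query-consuming gap, and closing a gap over extending it, at equal
score — the same rules the naive reference uses, so CIGARs are comparable
string-for-string.  CIGARs use M/I/D with SAM semantics (I consumes query).

## Suboptimal score

The second-best score is the largest column maximum outside the primary
alignment's target interval `[ref_begin, ref_end]`, optionally widened by
`mask_margin` (default 0: exactly the primary interval is masked).  When
the caller skips begin/CIGAR recovery the interval is unknown, and the mask
falls back to the heuristic `[ref_end - n, ref_end]` with `n` the query
length (an upper bound on the primary's target span whenever the alignment
has no deletions longer than the soft-clipped query ends; documented as a
heuristic).  Only the suboptimal's target end column is reported; a query
coordinate would require a second traceback the model does not need.

## Naive reference

`stripedsw.oracle` re-derives every quantity with full O(nm) matrices and
plain loops: the local fill for score/end and column maxima, a reversed
full fill for the begin, and an unbanded global DP over the rectangle for
the CIGAR.  It shares only the tie-rule *definitions* with the fast path,
not code, so engine/traceback bugs cannot cancel.  The oracle itself is
ground-truthed in the tests against exhaustive path enumeration on tiny
instances (exponential, lengths ≤ 6).

## Synthetic data

No external dataset is required.  The fixture generator draws a uniform
random parent sequence and plants, per position, an insertion with
probability `ins_rate` and a substitution/deletion with probabilities
`sub_rate`/`del_rate`, returning the ground truth so tests can score the
planted path directly.  The recovery suite uses reads of length 200 with
2% substitutions and 0.5% insertion and deletion rates — typical short-read
error magnitudes — and asserts the aligner's score is at least the planted
path's (equality is not asserted: the optimum may legitimately exceed the
planted alignment).  The generator emulates independent point errors only:
no homopolymer-biased indels, no quality-correlated errors, no structural
variants.  Passing tests therefore show algorithmic correctness of the
alignment machinery, not robustness to every real sequencing artifact.

The randomized verification suite sizes — 500 instances (query 10–100,
target 20–500) for oracle equivalence, 50 for lane invariance, 100 for
symmetry, 100 fixtures for recovery — keep a full run around a minute on
one core while covering DNA and protein alphabets and adversarial gap
parameterizations (zero penalties, open < extend).

## Degenerate inputs and numerics

Empty sequences are rejected with `ValueError`; a fill whose best score is
0 yields the empty alignment (`score1 = 0`, no coordinates, no CIGAR,
`score2 = 0`).  Ambiguity residues: N scores 0 against everything in the
DNA scheme; parsed BLOSUM/PAM tables keep their published X/B/Z rows, and
only symbols absent from the matrix header encode to the wildcard.  All
integer arithmetic is exact; there are no floating-point tolerances
anywhere in the method.

## Known limitations

* Pure Python/numpy: the striping here buys vectorized inner loops, not
  SIMD-register speed; throughput is far below the C implementations this
  design descends from, and quadratic-time behaviour makes whole-genome
  targets impractical.
* The target is held in memory; no streaming for very large references.
* One suboptimal score only; no enumeration of further sub-alignments, and
  no mapping-quality computation from (score1, score2).
* BAM output, multi-threading and quality-aware scoring are out of scope.
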