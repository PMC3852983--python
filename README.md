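# stripedsw

Striped Smith-Waterman-Gotoh local alignment, in Python, that returns more
than a score: the optimal alignment's begin/end coordinates on both
sequences, the detailed alignment (CIGAR), and a heuristic suboptimal
(second-best) score — the pieces a read mapper, split-read aligner or
alignment validator actually needs from a local aligner.

## The problem and the method

Local pairwise alignment with affine gap penalties finds, for a query `q`
(length *n*) and target `t` (length *m*), the highest-scoring pair of
substrings under the Gotoh recurrences

```
H(i,k) = max( 0, H(i-1,k-1) + s(q_i, t_k), E(i,k), F(i,k) )
E(i,k) = max( H(i-1,k) - g_open, E(i-1,k) - g_ext )     # gap in the target
F(i,k) = max( H(i,k-1) - g_open, F(i,k-1) - g_ext )     # gap in the query
```

so a gap of length *k* costs `g_open + (k-1)·g_ext`.  The fast fill here
uses Farrar's *striped* layout: the query is split into `p` interleaved
segments so one vector operation advances `p` distant query positions at
once, and the only dependency that crosses segments is repaired afterwards
by the *lazy-F* correction loop, which re-sweeps a column only while a
propagated gap score can still change it.

The fill alone yields only the score.  Three cheap additions recover the
full result in linear space:

1. the maximum of every target column is recorded in a **"max" array**,
   together with the full score vector of the best column — locating the
   alignment **end** on target and query;
2. a second striped fill over the **reversed** prefixes, stopped at the
   first column that attains the known optimum, locates the alignment
   **begin**;
3. a **banded** global DP confined to the small begin/end rectangle (band
   half-width doubling until the optimum is reached) produces the CIGAR.

Masking the primary alignment's target interval in the max array and taking
the largest remaining entry gives the **suboptimal score** — the signal
mappers use to judge whether the best hit is trustworthy — at no extra fill
cost.

A deliberately naive full-matrix implementation (`stripedsw.oracle`) ships
with the package and re-derives every result independently; the test suite
holds the two implementations to exact, element-wise agreement.

## Worked example

Library use:

```python
>>> import stripedsw as ssw
>>> scheme = ssw.make_dna_scheme(2, 1, 2, 1)   # match 2, mismatch -1, gaps -2/-1
>>> res = ssw.align("ACGT", "ACGTAAAAAAACGT", scheme)
>>> res.score1, (res.ref_begin, res.ref_end), str(res.cigar)
(8, (0, 3), '4M')
>>> res.score2, res.ref_end2
(8, 13)
```

The query matches the target twice; the primary hit (columns 0–3, score 8)
is masked, so the second copy ending at column 13 is reported as an equally
good suboptimal hit — exactly the situation in which a mapper should not
trust the primary location.

Command line (`stripedsw TARGET QUERY`; queries may be FASTA or FASTQ):

```text
$ stripedsw ref.fa reads.fa --match 2 --mismatch 1 --gap-open 2 --gap-extend 1 --cigar
target_name: ref
query_name: read1
optimal_alignment_score: 26	suboptimal_alignment_score: 24	strand: +	target_begin: 3	target_end: 15	query_begin: 1	query_end: 13
cigar: 13M
Target:         3 ACGTAGGTTACCG 15
                  |||||||||||||
Query:          1 ACGTAGGTTACCG 13
```

Coordinates in reports and SAM are 1-based inclusive; the Python API is
0-based inclusive throughout.  `--sam` emits SAM with soft clips for
unaligned query ends and `AS`/`XS` score tags:

```text
$ stripedsw ref.fa reads.fa --sam
@HD	VN:1.6	SO:unsorted
@SQ	SN:ref	LN:37
@PG	ID:stripedsw	PN:stripedsw	VN:0.1.0
read1	0	ref	3	255	13M	*	0	0	ACGTAGGTTACCG	*	AS:i:26	XS:i:23
read2	0	ref	19	255	8M	*	0	0	ACGTAAGG	*	AS:i:16	XS:i:13
```

Protein alignment: `--protein --matrix BLOSUM50 --gap-open 12 --gap-extend 2`
(builtin BLOSUM/PAM names or an NCBI-format matrix file).  DNA defaults are
match/mismatch/open/extend = 2/2/3/1; `--best-of-strands` also aligns the
reverse complement and reports the better strand.

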