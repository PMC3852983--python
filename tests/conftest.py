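"""Shared fixtures: canonical scoring schemes and random instance sampling."""

import numpy as np
import pytest

import stripedsw as ssw

AA_LETTERS = "ARNDCQEGHILKMFPSTWYV"
DNA_LETTERS = "ACGT"


@pytest.fixture(scope="session")
def dna_setting1():
    """match/mismatch/gap-open/gap-extend = 2/1/2/1."""
    return ssw.make_dna_scheme(2, 1, 2, 1)


@pytest.fixture(scope="session")
def dna_setting2():
    """match/mismatch/gap-open/gap-extend = 1/3/5/2."""
    return ssw.make_dna_scheme(1, 3, 5, 2)


@pytest.fixture(scope="session")
def blosum50():
    """BLOSUM50 with gap open 12, extend 2."""
    return ssw.parse_score_matrix("BLOSUM50").with_gaps(12, 2)


def random_dna_scheme(rng):
    """A small random scheme, including open < extend and zero penalties."""
    return ssw.make_dna_scheme(int(rng.integers(1, 5)),
                               int(rng.integers(0, 5)),
                               int(rng.integers(0, 7)),
                               int(rng.integers(0, 4)))


def random_seq(rng, length, letters=DNA_LETTERS):
    return "".join(rng.choice(list(letters), size=length))


def sample_instance(rng, schemes, qlen=(10, 100), tlen=(20, 500)):
    """Draw (scheme, query, target) over DNA and protein alphabets.

    ``schemes`` maps the fixed configurations; a quarter of the draws use a
    fresh random DNA scheme so zero/inverted gap penalties are exercised.
    """
    dna1, dna2, b50 = schemes
    kind = int(rng.integers(4))
    if kind == 3:
        scheme, letters = b50, AA_LETTERS
    elif kind == 2:
        scheme, letters = random_dna_scheme(rng), DNA_LETTERS
    else:
        scheme, letters = (dna1, dna2)[kind], DNA_LETTERS
    n = int(rng.integers(qlen[0], qlen[1] + 1))
    m = int(rng.integers(tlen[0], tlen[1] + 1))
    return scheme, random_seq(rng, n, letters), random_seq(rng, m, letters)


@pytest.fixture(scope="session")
def instance_sampler(dna_setting1, dna_setting2, blosum50):
    schemes = (dna_setting1, dna_setting2, blosum50)

    def sampler(rng, **kw):
        return sample_instance(rng, schemes, **kw)

    return sampler


def assert_cigar_invariants(result):
    """Structural CIGAR contract: run sums match spans, no leading/trailing
    gaps, adjacent runs have distinct ops."""
    runs = result.cigar.runs
    assert runs[0][1] == "M" and runs[-1][1] == "M"
    assert all(length > 0 for length, _ in runs)
    assert all(a[1] != b[1] for a, b in zip(runs, runs[1:]))
    assert result.cigar.query_span == result.query_end - result.query_begin + 1
    assert result.cigar.ref_span == result.ref_end - result.ref_begin + 1


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
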