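"""Unit and property tests for the word-combinatorics core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hacf import (
    DNASequence,
    abelian_complexity,
    abelian_complexity_batch,
    abelian_head_cut,
    abelian_upper_bound,
    complexity_profile,
    koslicki_n0,
    min_length_full_abelian,
    parikh_vector,
    subword_complexity,
    topological_entropy,
)
from hacf.complexity import write_profiles
from oracles import naive_abelian_complexity

words = st.text(alphabet="ACGT", min_size=1, max_size=120)


@pytest.mark.parametrize(
    "word, expected",
    [
        ("AAGC", (2, 1, 1, 0)),
        ("AAGCAGTCGG", (3, 2, 4, 1)),
        ("T", (0, 0, 0, 1)),
    ],
)
def test_parikh_vector_counts_letters(word, expected):
    assert parikh_vector(word) == expected


def test_parikh_vector_rejects_non_acgt():
    with pytest.raises(ValueError):
        parikh_vector("ACGN")


@pytest.mark.parametrize(
    "word, n, expected",
    [
        ("AAGCAGTCGG", 1, 4),
        ("AAGCAGTCGG", 2, 8),
        ("AAAA", 2, 1),  # a complete repeat uses a single subword
        ("AAGCAGTCGG", 11, 0),
    ],
)
def test_subword_complexity_examples(word, n, expected):
    assert subword_complexity(word, n) == expected


@pytest.mark.parametrize(
    "word, n, expected",
    [
        ("AAGCAGTCGG", 2, 7),
        ("AAGCAGTCGG", 3, 5),
        ("AAGCAGTCGG", 10, 1),
        ("AAGCAGTCGG", 11, 0),
    ],
)
def test_abelian_complexity_examples(word, n, expected):
    assert abelian_complexity(word, n) == expected


@pytest.mark.parametrize("func", [subword_complexity, abelian_complexity])
@pytest.mark.parametrize("n", [0, -3])
def test_nonpositive_n_rejected(func, n):
    with pytest.raises(ValueError):
        func("ACGT", n)


def test_abelian_complexity_rejects_non_acgt():
    with pytest.raises(ValueError):
        abelian_complexity("ACNG", 2)


def test_profile_abelian_worked_example(example_word):
    prof = complexity_profile(example_word, "abelian", 3)
    assert prof.values == {1: 4, 2: 7, 3: 5}


def test_profile_homopolymer_all_ones():
    prof = complexity_profile("AAAA", "abelian", 3)
    assert prof.values == {1: 1, 2: 1, 3: 1}


def test_profile_subword_worked_example(example_word):
    assert complexity_profile(example_word, "subword", 2).values == {1: 4, 2: 8}


def test_profile_out_of_range_nmax_is_an_error(example_word):
    with pytest.raises(ValueError):
        complexity_profile(example_word, "abelian", 11)


def test_profile_tsv_export(tmp_path, example_word):
    prof = complexity_profile(DNASequence("w1", example_word), "abelian", 3)
    out = tmp_path / "prof.tsv"
    write_profiles([prof], out)
    lines = out.read_text().strip().split("\n")
    assert lines[0] == "seq_id\tn\tvalue"
    assert lines[2] == "w1\t2\t7"


@pytest.mark.parametrize("n, expected", [(1, 4), (2, 10), (16, 969)])
def test_abelian_upper_bound_values(n, expected):
    assert abelian_upper_bound(n) == expected


@pytest.mark.parametrize("m, expected", [(1, 4), (2, 11), (16, 984)])
def test_min_length_full_abelian_values(m, expected):
    assert min_length_full_abelian(m) == expected


@pytest.mark.parametrize("L, expected", [(1000, 16), (984, 16), (4, 1)])
def test_abelian_head_cut_values(L, expected):
    assert abelian_head_cut(L) == expected


@pytest.mark.parametrize("L, expected", [(1000, 4), (259, 3), (5, 1)])
def test_koslicki_n0_values(L, expected):
    assert koslicki_n0(L) == expected


@pytest.mark.parametrize("func, bad", [(abelian_head_cut, 3), (koslicki_n0, 4),
                                       (abelian_upper_bound, 0), (min_length_full_abelian, 0)])
def test_bound_functions_reject_small_arguments(func, bad):
    with pytest.raises(ValueError):
        func(bad)


def test_topological_entropy_examples(example_word):
    assert topological_entropy("A" * 1000) == 0.0
    assert topological_entropy(example_word) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        topological_entropy("ACGT")


def test_topological_entropy_full_complexity_is_one():
    # a word of length 259 containing all 256 3-mers (p(3) = 4^3) has TE 1 at n0 = 3
    rng = np.random.default_rng(3)
    for _ in range(200):
        w = "".join("ACGT"[i] for i in rng.integers(0, 4, size=259))
        if subword_complexity(w, 3) == 64:
            assert topological_entropy(w) == pytest.approx(1.0)
            return
    pytest.skip("no full-complexity draw found (astronomically unlikely)")


@settings(deadline=None, max_examples=150, derandomize=True)
@given(word=words, n=st.integers(1, 130))
def test_acf_matches_naive_oracle(word, n):
    expected = naive_abelian_complexity(word, n)
    assert abelian_complexity(word, n) == expected
    assert abelian_complexity_batch(word, [n])[0] == expected


@settings(deadline=None, max_examples=150, derandomize=True)
@given(word=words)
def test_complexity_chain_bounds(word):
    """1 <= rho(n) <= p(n) <= min(4^n, L-n+1) and rho(n) <= C(n+3,3)."""
    L = len(word)
    for n in range(1, L + 1):
        rho = abelian_complexity(word, n)
        p = subword_complexity(word, n)
        assert 1 <= rho <= p <= min(4**n, L - n + 1)
        assert rho <= abelian_upper_bound(n)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(word=words)
def test_acf_symmetries(word):
    """ACF is invariant under reversal, reverse complement, and any uniform
    alphabet permutation; SCF is invariant under reversal."""
    L = len(word)
    ns = list(range(1, L + 1))
    base = list(abelian_complexity_batch(word, ns))
    rev = word[::-1]
    rc = word.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    perm = word.translate(str.maketrans("ACGT", "GTAC"))
    assert list(abelian_complexity_batch(rev, ns)) == base
    assert list(abelian_complexity_batch(rc, ns)) == base
    assert list(abelian_complexity_batch(perm, ns)) == base
    for n in (1, max(1, L // 2), L):
        assert subword_complexity(rev, n) == subword_complexity(word, n)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(L=st.integers(5, 4000))
def test_entropy_range_and_zero_iff_single_subword(L):
    rng = np.random.default_rng(L)
    w = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
    h = topological_entropy(w)
    assert 0.0 <= h <= 1.0
    n0 = koslicki_n0(L)
    assert (h == 0.0) == (subword_complexity(w, n0) == 1)
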