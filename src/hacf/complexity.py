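"""Word-combinatorics core: subword and abelian complexity of DNA words.

For a finite word omega over the alphabet {A, C, G, T}:

* the subword complexity function (SCF) p(n) counts the distinct length-n
  factors of omega;
* the Parikh vector of a word is its 4-tuple of letter counts
  (|w|_A, |w|_C, |w|_G, |w|_T), i.e. the order-insensitive abelianization;
* the abelian complexity function (ACF) rho(n) counts the distinct Parikh
  vectors among the length-n factors, so 1 <= rho(n) <= p(n) for n <= |omega|.

The ACF admits the alphabet-size-specific absolute bound
rho(n) <= C(n+3, 3): a Parikh vector of weight n is a weak composition of n
into 4 parts.  A word exhibiting full abelian complexity up to index m must
have length at least C(m+3, 3) + m - 1, which yields a principled "head cut"
for feature selection: at a fixed analysis length L, indices up to the
largest m0 with C(m0+3,3) + m0 - 1 <= L can saturate their bound and carry
little discriminative signal (m0 = 16 at L = 1000).

Topological entropy is estimated at Koslicki's position n0 — the unique n0
with 4^n0 + n0 - 1 < L <= 4^(n0+1) + (n0+1) - 1 — as log4(p(n0)) / n0,
a value in [0, 1] (0 for a pure repeat, 1 at full subword complexity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .sequence_io import ALPHABET, DNASequence

Word = Union[str, DNASequence]

# byte -> letter index lookup for vectorized encoding (A=0, C=1, G=2, T=3)
_BYTE_TO_IDX = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _BYTE_TO_IDX[ord(_c)] = _i

_IDX = {c: i for i, c in enumerate(ALPHABET)}


def _as_word(seq: Word) -> str:
    word = seq.bases if isinstance(seq, DNASequence) else seq
    if not word:
        raise ValueError("empty word")
    return word


def _encode(word: str) -> np.ndarray:
    """Map a word to an int array of letter indices; reject non-ACGT."""
    arr = _BYTE_TO_IDX[np.frombuffer(word.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) == 255:
        bad = sorted(set(word) - set(ALPHABET))
        raise ValueError(f"word contains non-ACGT characters {bad}")
    return arr


def parikh_vector(seq: Word) -> tuple[int, int, int, int]:
    """Letter-count 4-tuple (|w|_A, |w|_C, |w|_G, |w|_T) of a word."""
    word = _as_word(seq)
    counts = tuple(word.count(c) for c in ALPHABET)
    if sum(counts) != len(word):
        bad = sorted(set(word) - set(ALPHABET))
        raise ValueError(f"word contains non-ACGT characters {bad}")
    return counts  # type: ignore[return-value]


def subword_complexity(seq: Word, n: int) -> int:
    """Number of distinct length-``n`` factors; 0 when ``n`` exceeds |word|."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    word = _as_word(seq)
    _encode(word)  # validation only
    if n > len(word):
        return 0
    return len({word[i : i + n] for i in range(len(word) - n + 1)})


def abelian_complexity(seq: Word, n: int) -> int:
    """Number of distinct Parikh vectors among length-``n`` factors.

    Returns 0 when ``n`` exceeds the word length (the stated convention).
    Implemented as a single incremental slide: the window's letter counts
    are updated in O(1) per step and inserted into a set of exact tuples.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    word = _as_word(seq)
    L = len(word)
    if n > L:
        _encode(word)
        return 0
    counts = [0, 0, 0, 0]
    try:
        for ch in word[:n]:
            counts[_IDX[ch]] += 1
    except KeyError as e:
        raise ValueError(f"word contains non-ACGT character {e.args[0]!r}") from None
    seen = {tuple(counts)}
    for i in range(L - n):
        out_ch = word[i]
        in_ch = word[i + n]
        if in_ch not in _IDX:
            raise ValueError(f"word contains non-ACGT character {in_ch!r}")
        counts[_IDX[out_ch]] -= 1
        counts[_IDX[in_ch]] += 1
        seen.add(tuple(counts))
    return len(seen)


def abelian_complexity_batch(seq: Word, ns: Sequence[int]) -> np.ndarray:
    """ACF at several window lengths at once (vectorized).

    Uses cumulative letter counts: the Parikh vector of the window starting
    at i is ``cum[i+n] - cum[i]``; each vector is packed into one integer
    (T count is implied by the fixed window weight) and distinct values are
    counted with ``np.unique``.  Equivalent to :func:`abelian_complexity`
    per n, with far smaller constants for profile/feature extraction.
    """
    word = _as_word(seq)
    idx = _encode(word)
    L = len(word)
    cum = np.zeros((L + 1, 3), dtype=np.int64)
    np.cumsum(idx == 0, out=cum[1:, 0])
    np.cumsum(idx == 1, out=cum[1:, 1])
    np.cumsum(idx == 2, out=cum[1:, 2])
    K = L + 1  # counts are < K, so base-K packing is collision-free
    out = np.zeros(len(ns), dtype=np.int64)
    for j, n in enumerate(ns):
        if n <= 0:
            raise ValueError(f"n must be positive, got {n}")
        if n > L:
            out[j] = 0
            continue
        d = cum[n:] - cum[:-n]
        codes = (d[:, 0] * K + d[:, 1]) * K + d[:, 2]
        out[j] = np.unique(codes).size
    return out


@dataclass
class ComplexityProfile:
    """Per-n complexity values for one sequence plus derived scalars."""

    seq_id: str
    length: int
    kind: str  # "subword" | "abelian"
    values: dict[int, int]
    n0: Optional[int] = None
    m0: Optional[int] = None
    h_top: Optional[float] = field(default=None)

    def as_array(self) -> np.ndarray:
        ns = sorted(self.values)
        return np.array([self.values[n] for n in ns], dtype=np.int64)


def complexity_profile(seq: Word, kind: str, n_max: int) -> ComplexityProfile:
    """Profile of p(n) or rho(n) for 1 <= n <= ``n_max``.

    ``n_max`` beyond the sequence length is a caller bug and raises, unlike
    single-n queries which return 0 there.  Abelian profiles are typically
    non-monotone; no monotonicity is enforced or implied.
    """
    if kind not in ("subword", "abelian"):
        raise ValueError(f"kind must be 'subword' or 'abelian', got {kind!r}")
    word = _as_word(seq)
    L = len(word)
    if not 1 <= n_max <= L:
        raise ValueError(f"n_max must be in [1, {L}], got {n_max}")
    ns = range(1, n_max + 1)
    if kind == "abelian":
        vals = abelian_complexity_batch(word, list(ns))
        values = {n: int(v) for n, v in zip(ns, vals)}
    else:
        values = {n: subword_complexity(word, n) for n in ns}
    seq_id = seq.id if isinstance(seq, DNASequence) else ""
    prof = ComplexityProfile(seq_id=seq_id, length=L, kind=kind, values=values)
    if L >= 5:
        prof.n0 = koslicki_n0(L)
        prof.h_top = topological_entropy(word)
    if L >= 4:
        prof.m0 = abelian_head_cut(L)
    return prof


def write_profiles(profiles: Iterable[ComplexityProfile], path: str | Path) -> None:
    """Export profiles as TSV with columns seq_id, n, value."""
    with open(path, "w") as fh:
        fh.write("seq_id\tn\tvalue\n")
        for p in profiles:
            for n in sorted(p.values):
                fh.write(f"{p.seq_id}\t{n}\t{p.values[n]}\n")


def abelian_upper_bound(n: int) -> int:
    """Absolute ACF bound C(n+3, 3) = (n+3)(n+2)(n+1)/6, exact integers."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    return (n + 3) * (n + 2) * (n + 1) // 6


def min_length_full_abelian(m: int) -> int:
    """Minimal word length admitting full abelian complexity up to index m.

    A word with rho(i) = C(i+3,3) for i = 1..m must contain C(m+3,3)
    distinct length-m factors, hence have length >= C(m+3,3) + m - 1.
    """
    if m <= 0:
        raise ValueError(f"m must be positive, got {m}")
    return abelian_upper_bound(m) + m - 1


def abelian_head_cut(seq_len: int) -> int:
    """Largest m0 with ``min_length_full_abelian(m0) <= seq_len``.

    ACF indices <= m0 may saturate their absolute bound at this sequence
    length and are discarded as head features (m0 = 16 at 1 kb).
    """
    if seq_len < 4:
        raise ValueError(f"seq_len must be >= 4, got {seq_len} (no m0 >= 1 exists)")
    m = 1
    while min_length_full_abelian(m + 1) <= seq_len:
        m += 1
    return m


def koslicki_n0(seq_len: int) -> int:
    """The unique n0 with 4^n0 + n0 - 1 < seq_len <= 4^(n0+1) + n0."""
    if seq_len < 5:
        raise ValueError(f"seq_len must be >= 5, got {seq_len}")
    n0 = 1
    while 4 ** (n0 + 1) + (n0 + 1) - 1 < seq_len:
        n0 += 1
    return n0


def topological_entropy(seq: Word) -> float:
    """Finite-word topological entropy estimate log4(p(n0)) / n0 in [0, 1]."""
    word = _as_word(seq)
    if len(word) < 5:
        raise ValueError(f"sequence must have length >= 5, got {len(word)}")
    n0 = koslicki_n0(len(word))
    p = subword_complexity(word, n0)
    return math.log(p, 4) / n0
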