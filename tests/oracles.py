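"""Independent brute-force oracles used to cross-check the implementation.

These deliberately materialize every window and recount letters from
scratch; they share no code with the package's incremental/vectorized
paths.
"""

from __future__ import annotations


def naive_parikh(word: str) -> tuple[int, int, int, int]:
    return (word.count("A"), word.count("C"), word.count("G"), word.count("T"))


def naive_subword_complexity(word: str, n: int) -> int:
    if n > len(word):
        return 0
    return len({word[i : i + n] for i in range(len(word) - n + 1)})


def naive_abelian_complexity(word: str, n: int) -> int:
    if n > len(word):
        return 0
    vecs = set()
    for i in range(len(word) - n + 1):
        vecs.add(naive_parikh(word[i : i + n]))
    return len(vecs)


def brute_force_koslicki_n0(L: int) -> int:
    """Scan n until the defining double inequality holds."""
    n = 1
    while True:
        if 4**n + n - 1 < L <= 4 ** (n + 1) + (n + 1) - 1:
            return n
        n += 1


def brute_force_head_cut(L: int) -> int:
    """Largest m with C(m+3,3) + m - 1 <= L, by direct scan."""
    m = 0
    while True:
        c = (m + 4) * (m + 3) * (m + 2) // 6  # C((m+1)+3, 3)
        if c + (m + 1) - 1 > L:
            return m
        m += 1
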