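"""Complexity functions on a small DNA word.

Computes the subword complexity, abelian complexity, topological entropy
and the bound-derived feature-window constants for the 10-base word
AAGCAGTCGG.
"""

from hacf import (
    abelian_complexity,
    abelian_head_cut,
    abelian_upper_bound,
    complexity_profile,
    koslicki_n0,
    parikh_vector,
    subword_complexity,
    topological_entropy,
)

word = "AAGCAGTCGG"

print(f"word: {word}")
print(f"Parikh vector (A,C,G,T counts): {parikh_vector(word)}")
print(f"subword complexity p(2): {subword_complexity(word, 2)}")
print(f"abelian complexity rho(2): {abelian_complexity(word, 2)}")
print(f"abelian complexity rho(3): {abelian_complexity(word, 3)}")
print(f"rho(11) with window > word: {abelian_complexity(word, 11)}")
print(f"abelian profile n=1..3: {complexity_profile(word, 'abelian', 3).values}")
print(f"topological entropy: {topological_entropy(word):.3f}")
print()
print("constants at the 1 kb analysis length:")
print(f"  Koslicki position n0:    {koslicki_n0(1000)}")
print(f"  abelian head cut m0:     {abelian_head_cut(1000)}")
print(f"  ACF absolute bound at 16: {abelian_upper_bound(16)}")
# rho(2)=7 > rho(3)=5 shows the ACF fluctuates where the SCF would only grow;
# m0=16 means ACF indices 1..16 can saturate their bound inside 1 kb, so the
# informative feature window starts at 17.
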