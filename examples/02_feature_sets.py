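"""Building SACF, TNF and HACF feature sets with rank-sum selection.

Generates a small synthetic training set (1 kb sequences, dinucleotide
repeat motifs planted in the positives), extracts the ACF feature block,
filters it with the Wilcoxon rank-sum test and assembles the hybrid set.
"""

from hacf import (
    FeatureRecipe,
    GeneratorConfig,
    build_labeled_dataset,
    feature_matrix,
    wilcoxon_select,
)

cfg = GeneratorConfig(seed=1, n_pos=25, neg_pos_ratio=4, insertion_rate=40.0)
seqs, y = build_labeled_dataset(cfg)
print(f"{len(seqs)} sequences of {cfg.seq_len} bp ({y.sum()} positives)")

X_sacf = feature_matrix(seqs, FeatureRecipe(kind="sacf"))
print(f"SACF block: {X_sacf.shape[1]} features ({X_sacf.columns[0]}..{X_sacf.columns[-1]})")

# relaxed threshold: this demo set is far smaller than a real training set,
# so the extreme production cutoff (1e-20) would keep nothing
sel = wilcoxon_select(X_sacf[y == 1], X_sacf[y == 0], threshold=1e-6)
print(f"rank-sum filter at p<1e-6 keeps {len(sel.kept_names)} ACF features")

recipe = FeatureRecipe(kind="hacf", kept_acf_names=sel.kept_names or None)
X = feature_matrix(seqs, recipe)
print(f"HACF matrix: {X.shape[0]} x {X.shape[1]} "
      f"({len(sel.kept_names)} ACF + 256 TNF features)")
# each row is one sequence; ACF columns are integer complexities, TNF columns
# are 4-mer frequencies summing to 1
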