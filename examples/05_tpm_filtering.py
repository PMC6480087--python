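"""Dataset filtering by minimal nonzero expression.

Generates a toy TPM-style matrix (elements x conditions) and keeps the
elements whose smallest nonzero expression value is at least alpha —
the rule used to select ubiquitously active elements for training.
"""

from hacf import filter_by_tpm, generate_tpm_matrix

matrix = generate_tpm_matrix(n_elements=200, n_conditions=30, sparsity=0.6, seed=2)
for alpha in (0.02, 0.08, 0.32):
    kept = filter_by_tpm(matrix, alpha=alpha)
    print(f"alpha = {alpha:>5}: {len(kept):>3} of {len(matrix.element_ids)} elements kept")
# larger alpha demands higher minimum activity across every condition in
# which the element is expressed at all; all-zero rows are always dropped
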