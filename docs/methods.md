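# Methods

## The complexity model

All quantities are defined for finite words over the four-letter DNA
alphabet; anything off that alphabet (including N) is outside the model,
which is why sequences or scan windows containing N are excluded from
featurization rather than coerced.

**Subword complexity and entropy.** p_ω(n) is the number of distinct
length-n factors. Topological entropy is a finite-word estimate of the
asymptotic growth rate of p_ω: it is evaluated at the single Koslicki
position n₀, the largest window length at which a word of this length
could still exhibit full complexity 4^n₀ (a length of 4^n₀ + n₀ − 1
suffices to place all 4^n₀ factors). Multi-point refinements that average
neighbouring positions exist but are not implemented; the single-point
estimate is the quantity used downstream.

**Abelian complexity.** ρ_ω(n) counts distinct Parikh vectors (window
compositions) among length-n factors. It is coarser than p_ω
(1 ≤ ρ ≤ p) and bounded by the number of weak compositions of n into 4
parts, C(n+3, 3). Unlike p_ω it is typically non-monotone in n, which is
the property that makes it informative in the mid-range of window lengths.
Single-n queries with n > |ω| return 0 (the standard convention, applied
to both ACF and SCF); profile construction over a range that exceeds the
word length raises instead, because a profile over out-of-range n is
always a caller bug.

**Bound-derived feature window.** Reaching full abelian complexity up to
index m needs length ≥ C(m+3, 3) + m − 1 (a factor set of size C(m+3,3)
must fit in some subword). The head cut m₀(L) is the largest m whose bound
fits in the analysis length L; indices ≤ m₀ can saturate and are dropped.
The back cut retains indices up to L/2. The underlying back-end rule is
data-dependent (drop the tail whose complexity falls below the value at
the first kept index), but this featurizer hard-codes the half-length
outcome so that the feature space is a deterministic function of L alone;
at L = 1000 both rules give the published window 17–500.

## Implementation notes

* The public single-n ACF is an incremental slide (O(1) count update per
  step, exact tuple set membership — no hash-collision tolerance). Batch
  paths (profiles, SACF extraction) use an equivalent vectorized
  formulation: cumulative letter counts, base-(L+1) integer packing of
  each window's composition (collision-free since every count < L+1), and
  `np.unique`. Both routes are property-tested against a naive
  window-enumeration oracle, exhaustively for all 87,380 words of length
  ≤ 8 and on random words up to 200 bp.
* All combinatorial bounds use exact integer arithmetic.
* Wilcoxon selection uses the two-sided Mann–Whitney U with normal
  approximation and tie correction. No multiple-testing correction is
  applied: the production cutoff 10⁻²⁰ is far beyond any Bonferroni
  adjustment at 484 tests. A feature constant across both groups is
  assigned p = 1 and never kept.
* TNF values are frequencies (counts over the |ω| − 3 windows), not raw
  counts, tying them to [0, 1] independent of length.
* The SVM uses standardized features and sigmoid (Platt) calibration so
  scores live in [0, 1]; defaults are RBF kernel, C = 1, gamma = "scale".
  These hyperparameters are deliberately unremarkable and exposed in
  `SVMConfig`. Class weighting is off by default to preserve the
  intentionally imbalanced 1:10 training design; "balanced" weighting is
  available via config.
* Hard labels everywhere use score > 0.5 — the same strict rule as the
  genome scanner's candidate call, so evaluation and scanning agree.
* Cross-validation is stratified; held-out scores are pooled across folds
  for the AUC, and count metrics are computed on the pooled hard labels.
  AUC is the rank-based area (ties contribute 1/2), asserted in tests to
  equal the normalized Mann–Whitney U statistic.
* Feature importance is permutation importance (mean AUC drop over
  shuffles), deterministic given its seed.
* The scanner scores only full windows: floor((L − W)/step) + 1 of them.
  Conventions that also score partial terminal windows yield slightly
  higher counts on real chromosomes; the full-window rule is used because
  a partial window cannot be featurized at the fixed analysis length.
  External peak calling (e.g. MACS2) is supported through scored-BED
  export; `merge_candidates` (merge overlapping/near-adjacent candidate
  windows, peak score = max member) is the built-in, documented substitute.
* Windows are scored on the given strand; ACF features are
  reverse-complement invariant by construction, TNF is not, and an
  optional symmetrized mode averages the score of each window with its
  reverse complement (off by default).

## Length standardization

Training sequences are truncated or expanded to the fixed analysis length
(default 1 kb), centered on the midpoint; with an odd trim the extra base
comes off the 3′ end (a deterministic tie-break). Expansion requires
genomic coordinates and a reference accessor for flanks and clamps at
contig starts, taking the deficit from the other side; without a
reference it is refused rather than padded. Elements shorter than 100 bp
are excluded upstream (featurization of very short sequences is
unreliable), mirrored by the generator's minimum-length floor.

## The synthetic-data generator

The generator emulates the study design, not enhancer biology:

* **Background** (negatives): Markov sequences, default order 0 with
  ~41% GC (human-like composition); arbitrary order-k transition tables
  are accepted.
* **Positives**: background plus Poisson-distributed insertions of
  dinucleotide repeat motifs (defaults GCGCGC and GAGAGA, the repeat class
  reported as required for active enhancers). The insertion rate is the
  effect-size dial; rate 0 degenerates exactly to background. The default
  rate of 8 insertions per 1 kb gives a clearly learnable but imperfect
  signal.
* **Design ratio**: 1 positive : 10 negatives by default, matching the
  genomic prior that enhancers cover a minority of the genome.
* **TPM matrices**: log-normal entries with independent dropout; the
  filter keeps elements whose minimal *nonzero* value across conditions is
  ≥ α (default 0.08), dropping all-zero rows as inactive.

What passing tests on this generator do show: the full pipeline recovers a
planted compositional-repeat signal, is calibrated at null (no signal →
chance-level AUC), and responds monotonically to effect size. What they do
not show: performance on real enhancers, whose signal involves TF-motif
grammar, chromatin context and cell-type specificity that the generator
does not attempt to model. Redundancy removal (CD-HIT-style clustering) is
not simulated — the generator avoids duplicates by construction — and
remains a documented external preprocessing step for real data.

## Test problem sizes

Heavy checks are sized to run comfortably on one CPU: the pipeline
recovery suite uses 5-fold CV at 1 kb with 75 positives/750 negatives per
null replicate (three replicates, mean AUC asserted within [0.45, 0.55] —
at ~825 pooled samples the null AUC standard error is ≈ 0.03, so the band
is a ≈ 2.7σ check on the mean) and 60/600 at insertion rates 2, 8 and 32
for the monotonicity check. Brute-force inequality scans for n₀ and m₀
cover lengths up to 10,000.

## Known limitations

* Entropy uses the single-point estimate only; words much shorter than
  ~5 bp have no admissible n₀ and are rejected.
* The ACF bound C(n+3, 3) and everything derived from it is specific to a
  4-letter alphabet.
* The exact membership of a rank-sum-selected feature subset depends on
  the training data; the published 209-of-484 selection arises from a
  specific enhancer training corpus and is re-derived, not hard-coded —
  pipelines built here carry their own kept-name list in the model
  archive.
* `overlap_fraction` counts a reference interval as recovered on ≥ 1 bp
  overlap with any prediction; no reciprocal-overlap option.
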