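# Methods

## Grantham distance

The Grantham distance between amino acids *a* and *b* is

D(a,b) = ρ · [ α (c_a − c_b)² + β (p_a − p_b)² + γ (v_a − v_b)² ]^½

with composition *c*, polarity *p*, and molecular volume *v* per residue, and
constants α = 1.833, β = 0.1018, γ = 0.000399. ρ = 50.723 scales the mean over
all 190 unordered residue pairs to approximately 100.

The package ships two views of this quantity:

- `canonical_matrix()` — the published integer matrix (Grantham 1974, Science
  185:862–864, Table 2), stored as versioned package data. This is the
  **authoritative default** used by the conservation screen and the CLI.
- `grantham_distance()` / `build_matrix()` — the distance recomputed from the
  property table at full floating precision, for parameterized work (custom
  α, β, γ, ρ via `GranthamParams`).

These two views are deliberately kept distinct because they do not agree
exactly: recomputing from the published property table and constants and
rounding to integers reproduces 145 of the 190 published entries; 45 entries
differ by ±1 unit and one (D–W) differs by ≈ 9.6 units (published 181 vs
computed 190.55), a hand-computation erratum in the original table. No choice
of (α, β, γ, ρ) removes the discrepancies. Because forty years of literature
cite the published integers (e.g. L–I = 5, C–W = 215 as the maximum), the
published table is treated as canonical, and the formula is exposed separately
rather than silently substituting near-miss values. A characterization test
freezes the exact deviation set so any change to either view is detected.

## Conservation screen

For an alignment column, conservation within a sequence set is the mean of the
Grantham distances over all unordered residue pairs (gaps and ambiguous
residues excluded; a site needs at least `min_ungapped = 2` usable foreground
residues, otherwise it is reported with a note rather than dropped). Site
coordinates are 1-based positions of an ungapped reference sequence, mapped to
alignment columns via `build_position_map`.

A site is called conserved when (a) its p-value (q-value if
Benjamini–Hochberg correction is enabled) is ≤ alpha (default 0.05) and (b)
the foreground mean is strictly below the background mean.

Three tests are offered:

- `mann_whitney` (default): one-sided rank test of foreground pairwise
  distances vs background pairwise distances.
- `t_test`: one-sided Welch t-test on the same two samples.
- `permutation` (recommended): draws random foreground-sized subsets of the
  family, recomputes the subset mean pairwise distance, and reports
  p = (1 + #{null ≤ observed}) / (1 + n_perm) with n_perm ≥ 100 (default 999).

The permutation test is recommended because the C(n,2) pairwise distances
within a group share sequences and are therefore positively dependent; tests
that treat them as independent samples (Mann–Whitney, t) are anti-conservative.
Measured on null families (no planted signal), the permutation screen's
per-site flag rate is ≈ 0.05–0.06 at alpha 0.05 and its p-values pass a
Kolmogorov–Smirnov uniformity check, while the Mann–Whitney screen's per-site
false-positive rate is ≈ 0.10–0.12. A consequence worth stating explicitly:
with 20 null sites in a panel, even a perfectly calibrated per-site test at
alpha 0.05 flags at least one decoy with probability 1 − 0.95²⁰ ≈ 0.64, so
"all planted sites recovered AND zero decoys flagged" cannot be a
high-probability event without family-wise error control (e.g. permutation
p-values plus Bonferroni), which is not the default here. The corresponding
acceptance test is left failing by design.

## Candidate selection

`filter_degs` applies the stated boundary conventions exactly: |log2 fold
change| ≥ cutoff (inclusive, default 1, i.e. 2-fold) and p < cutoff (strict,
default 0.05). Rows with NaN p-values never enter a DEG set; non-finite fold
changes or p-values outside [0, 1] are rejected naming the offending gene.
`intersect_candidates` partitions a down-regulated set by annotation class
(OR / OR-like / other); genes missing from the annotation are classed "other"
with a warning. `simple_de_test` is a deliberately simple stand-in for a full
DE package: counts-per-million with pseudocount 0.5, log2 ratio of group mean
CPMs, and a two-sided Welch t-test on log2 CPM. It is used for end-to-end
pipeline validation, not as a replacement for edgeR/DESeq2-class methods.

## Reporter assay

Dual-luciferase wells are normalized as response = firefly / renilla; wells
with non-positive renilla are excluded with a warning. `response_test`
compares a construct's responses at a stimulus concentration against its own
0 µM wells (Welch t by default, Mann–Whitney optional). `relative_response`
expresses mutant and wild-type responses relative to the mean response of a
receptor-free control group on the same plate (the control's own relative
response is 1 by construction) and tests mutant vs wild type. Significance
tiers: `**` p < 0.01, `*` p < 0.05, `ns` otherwise, `na` when no test is
possible (fewer than 2 replicates).

## Synthetic data generators

- `gen_family` (FamilySpec): defaults 200 background + 5 foreground sequences,
  length 310 (a typical OR length), gap rate 0.02, planted sites (40, 150,
  250). Background columns are i.i.d. draws from per-column residue
  distributions (uniform, or Dirichlet-sampled when `dirichlet_alpha` is set),
  so sequences are exchangeable — the property the null-calibration test
  relies on. At planted sites, foreground residues are drawn from the set of
  residues within Grantham radius *r* of a site anchor; r = 0 means perfect
  identity, r = 50 (default) is strong physicochemical conservation (e.g. the
  I/L/M/V neighborhood of L), r = 120 is weak. The reference row "REF" is kept
  gap-free so reference positions equal alignment columns.
- `gen_counts` (CountSpec): negative-binomial counts for 2000 genes × 4+4
  samples, baseline mean 100, dispersion 0.05 (biological coefficient of
  variation ≈ 22%, a typical cell-line value; dispersion 0 degenerates to
  Poisson), fold change 4 for planted genes. Planted structure mirrors a
  realistic screen: 15 down-regulated OR genes, 49 down-regulated OR-like
  genes, 76 other down-regulated genes, 60 up-regulated genes, out of 120 OR
  and 150 OR-like genes total.
- `gen_plate` (PlateSpec): firefly/renilla wells at concentrations 0/100/200 µM
  with n = 6 replicates and multiplicative lognormal noise with CV 10% (the
  noise factor has mean 1, σ² = log(1 + CV²)); responders multiply the firefly
  baseline by a per-concentration activation fold.

Defaults (n = 4 RNA-seq samples per group, n = 6 assay replicates, CV 10%,
4-fold planted expression changes, 2-fold reporter activation) are sized so
the intended effects are detectable but not trivial: measured over 200 seeded
replicates, the DE pipeline recovers all planted OR candidates in 99.5% of
runs, and the assay statistics detect 2-fold responders and
30%-of-wild-type mutants in ≥ 99% of plates.

## Numerical and implementation notes

- The canonical matrix and its array form are cached (`functools.lru_cache`);
  a 23-site screen of a 205-sequence family runs in < 0.1 s.
- Permutation subsets are drawn via vectorized argsort of uniform variates,
  seeded with `numpy.random.default_rng`; all generators and tests accept
  explicit seeds and are reproducible bit-for-bit for a fixed seed.
- Mean pairwise distance at a site is computed from residue counts
  (multiset), so runtime per site is O(k²) in the number of distinct residues,
  not the number of sequences.

## Limitations

- The screen treats alignment columns independently and sequences as
  exchangeable; phylogenetic correlation between family members is not
  modeled, and on real repertoires the effective number of independent
  sequences is smaller than the count.
- `simple_de_test` does not shrink dispersions or model library size beyond
  total-count normalization.
- The synthetic family generator draws i.i.d. columns, which understates the
  background conservation structure of real transmembrane helices; planted
  recovery rates on synthetic data are therefore optimistic upper bounds.
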