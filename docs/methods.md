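# Methods

## Contact model and distance normalization

A `ContactMatrix` stores one chromosome's binned intra-chromosomal contacts
as a sparse upper triangle (`0 ≤ i ≤ j < n_bins`); genomic positions are
1-based inclusive and position `pos` maps to bin `(pos − 1) // resolution`.
Inter-chromosomal contacts are ignored throughout: every statistic in this
package lives within a few kilobases of the diagonal.

Raw matrices are balanced by iterative correction — alternating row/column
scaling until all unmasked marginals agree within `tol` (default 1e-6,
`max_iter` 200). Matrix balancing only fixes multiplicative per-bin biases,
so any converged balancing serves the downstream rank statistics equally;
matrices normalized upstream (e.g. cooler weights) are accepted verbatim as
`normalization="external"`. Bins with zero marginal are masked and their
entries dropped; non-convergence yields a warning and `converged=False`
rather than an error.

The expected profile `E(d)` is the plain per-separation mean over all valid
(unmasked) bin pairs, counting unstored pairs as zero, floored at 1e-9 so OE
division is always defined. No smoothing: at the depths this tool targets
the per-diagonal means are stable out to the separations used, and a raw
mean keeps the OE-conservation property (mean OE per separation = 1)
exactly. Zero-count pairs inside a tested region enter the rank tests as
OE = 0 samples; dropping them would inflate target OE precisely in the
sparse high-resolution regime the tool is built for.

## Region geometry

Bin membership is decided by bin midpoint (`i·res + (res+1)/2`), which gives
symmetric, deterministic rounding at gene borders. Controls are always
*translations of the target along the genomic axis*: both anchors shift by
the same number of bins, so the multiset of separations — and therefore the
OE null distribution — is preserved exactly. This is the one construction
that simultaneously (i) keeps target and control equidistant from the
diagonal and (ii) places one control anchor outside and one inside the gene
body. Single-gene controls shift by `⌈L/2⌉` bp (rounded to whole bins);
multigene controls shift by the bin-width of the adjacent boundary gene.
Controls clipped by a chromosome edge are used as-is when they retain at
least `min_pairs` pairs (default 3, the smallest sample a one-sided U test
accepts); otherwise the gene or cluster is *untestable* — reported, never
silently passed. Genes spanning fewer than 2 bins are untestable by
construction (no intragenic pairs).

The differential gene-body region uses strict `i < j` pairs (the diagonal
carries self-ligation artifacts, not folding signal); the surrounding
region takes pairs with exactly one midpoint inside the gene and the other
within the 2-kb flank, i.e. the border-crossing contacts whose depletion
defines insulation. The multigene interior span deliberately includes the
far boundary gene, so boundary stripes measure contacts from a boundary
into the *rest of the domain* including the opposite boundary.

## Statistics

* One-sided Mann–Whitney U ("target stochastically greater"), tie-corrected
  normal approximation with continuity correction. For tie-free samples of
  ≤ 8 per group this approximation is uniformly within 0.019 of the exact
  permutation p (exhaustive scan over all attainable U), so no exact switch
  is needed. Completely tied samples return p = 0.5 (no evidence).
* The per-gene p combines the two controls as the maximum (an
  intersection–union test): enrichment must be significant against *both*
  sides. This is the conservative canonical choice for "higher than all
  controls"; the multigene cluster p is likewise the max over all
  comparisons and controls.
* Two-sided Wilcoxon signed-rank on paired OE differences, zeros dropped,
  ≥ 5 nonzero differences required. Tie-free samples of ≤ 12 use the exact
  signed-rank distribution — at these sizes the normal approximation can
  deviate from the exact p by up to 0.035, too coarse for a calibrated
  Q-value — and larger or tied samples use the tie- and continuity-
  corrected normal approximation. Both paths are deterministic.
* Benjamini–Hochberg step-up Q values (statsmodels `fdr_bh`), one family
  per run: all testable genes (single/diff) or all candidate windows
  (multi). Untestable entries are excluded from the family size. Nested or
  overlapping multigene windows passing FDR are all reported; no
  deduplication is attempted.
* Differential direction: `r_body = body_control/body_treat` and
  `r_surr = surr_treat/surr_control` must both fall below `1 − 0.1`
  (treat-enhanced) or both reciprocals below it (control-enhanced). Fold
  changes are ratios of region means, not means of pairwise ratios, so
  sparse zero-count pairs cannot produce divisions by zero.

## Analytics

Pile-up windows cover `[start − f·L, end + f·L]` (`f` = 0.5). Native-
resolution OE is replicated onto a 10-bp grid — native bins carry no
sub-resolution information, so replication is the faithful expansion — then
bicubic-interpolated (cubic-spline `map_coordinates`) to 80 × 80 and
averaged element-wise; minus-strand domains are flipped along both axes
first. Masked bins inside a window are imputed with the window's finite
mean before interpolation; fully masked windows and windows leaving the
chromosome are skipped with a warning.

The directionality index per bin uses `A`/`B` = summed contacts to the `w`
upstream/downstream bins (`w` = window/resolution, default 5 kb),
`E = (A + B)/2`, `di = sign(B − A)·((A−E)²/E + (B−E)²/E)`; bins with
truncated windows or `E = 0` are omitted. The compartment eigenvector is
the largest-|eigenvalue| eigenvector of the Pearson correlation of the
dense OE matrix over unmasked bins, unit-normalized, sign-oriented so bins
containing gene starts average positive (A compartment at active 5' ends)
when an annotation is supplied — otherwise left as computed with a warning.
A 750-bp matrix is the intended input for fine-scale compartments.

Jaccard reproducibility matches calls one-to-one (greedy by total boundary
distance) when both boundaries agree within `tol_bins` (default 1) bins,
and returns `|matches| / (|A| + |B| − |matches|)`. Two empty sets are
defined as J = 1 with a warning: an edge case that matters when comparing
null runs, where "nothing vs nothing" is perfect agreement by convention.

## Simulator

Counts are independent Poisson draws around
`λ(i,j) = depth_c · (1 + j − i)^(−α) · f(i,j)`; `f` multiplies planted
single-gene target triangles (the same predicate the caller tests, so the
caller is evaluated against its stated signal model) and multigene
corner/stripe blocks by `enrichment`, and divides border-crossing pairs
within 2 kb of planted borders by `insulation`. Differential effects apply
per-condition factors to a gene's body and surrounding pairs. Enrichment is
realized by adding independent Poisson((f−1)λ) counts and depletion by
binomial thinning — both exact for Poisson, so emitted maps are genuine
samples from the modified intensity. A negative-binomial option
(gamma-mixed λ) provides overdispersion when desired. One seeded numpy
generator drives everything; a fixed seed is byte-reproducible.

Defaults emulate a gene-dense compact plant genome at high resolution:
2-Mb chromosome, 250-bp bins, genes 1–5 kb with 0.2–2 kb gaps, decay α = 1,
`depth_c` = 50 (≈ deep plant Hi-C at this bin size), enrichment 2.
What the simulator does *not* emulate: restriction-fragment granularity,
ligation/coverage biases (maps are bias-free before balancing),
condition-correlated noise, or real plant contact statistics. Passing
recovery tests therefore demonstrates the statistical machinery under its
stated signal model, not performance on real tissue Hi-C.

## Problem sizes and numerical choices

The validation suite runs on 0.4–2 Mb simulated chromosomes with ~40–285
genes — sizes chosen so the full pipeline (simulate → balance → normalize →
call) stays in seconds per run while every separation used by the
statistics is covered by hundreds of bin pairs. The null-calibration run
uses the largest gene count (285) that the capacity check
(`n_genes · max(gene + gap) ≤ chrom_length`) admits for 1–5 kb genes in
2 Mb. Balancing tolerance 1e-6; expected-profile floor 1e-9; BED scores
`min(1000, −10·log10(Q))`.

## Known limitations

* Recovery of planted domains is bounded by gene size: a ~1-kb gene at
  250 bp has only 3 intragenic target pairs, and the smallest one-sided
  rank-test p attainable with 3-vs-3 samples (~0.04) cannot clear a BH
  threshold in a family of hundreds of genes. Such genes are testable but
  effectively undetectable; calling them requires finer bins or pooling.
* The Mann–Whitney approximation's oracle agreement (±0.02) is guaranteed
  only for tie-free data; heavily tied low-count regions give valid but
  conservative p-values.
* Single-gene control offsets (±⌈L/2⌉) and the multigene interior
  convention are this package's normative geometry; other tools may place
  controls differently, which matters when comparing raw p-values across
  tools (call sets should be compared via the Jaccard utility instead).
* The `.hic` reader requires the optional `hic-straw` dependency and is
  otherwise disabled with an explanatory error; convert to cooler or
  triplet text when it is unavailable.
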