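# Methods

## The problem

Dense SNP chips genotype tens of thousands of markers, but assigning an
individual to its breed of origin only needs the small minority of markers
whose allele frequencies actually differ between breeds. `snptrace`
implements one route to finding that minority: train feed-forward neural
networks to predict breed from raw allele dosages, read per-marker
importance out of the fitted connection weights, and validate the reduced
panels with frequency-based assignment tests, PCA and Neighbor-Joining
trees.

## Genotype model and QC

Genotypes are biallelic dosages — 0, 1 or 2 copies of the counted allele —
with a missing sentinel. The only QC applied is a per-SNP call-rate filter
(default: keep SNPs with ≥ 99% of genotypes called); a per-sample variant
is available but off by default, since the per-SNP reading matches "the
proportion of SNP genotypes" being filtered. MAF is `min(p, 1−p)` with
`p = Σdosage / (2·n_called)`; observed heterozygosity is the called
fraction equal to 1. Statistics at SNPs with zero called genotypes are
reported as NaN, never silently as 0.

## Synthetic multi-breed panels

The simulator draws, per SNP, an ancestral frequency uniform on
[0.05, 0.95], then per-breed frequencies from the Balding–Nichols Beta
distribution `Beta(p(1−F)/F, (1−p)(1−F)/F)` (mean `p`, variance
`p(1−p)F`). A chosen subset of "planted" SNPs uses a large divergence
(default F = 0.35) against a weak background (F = 0.02), emulating a chip
on which a minority of markers is strongly breed-discriminant. Genotypes
are Binomial(2, breed frequency) — Hardy–Weinberg within breed — with
missingness injected at 0.2% by default. F1 hybrids draw one allele from
each parent breed. The default design is 5 breeds × 30 individuals ×
2,000 SNPs with 100 planted markers: large enough that chance overlap
with a top-100 ranking is 5%, small enough that the whole workflow runs in
seconds.

What the simulator deliberately omits: linkage disequilibrium (markers are
independent), pedigree structure beyond F1 crosses, ascertainment bias of
chip design, and genotyping error beyond missingness. Passing tests
therefore demonstrate that the selection and assignment machinery recovers
truly divergent, independent markers — not that it handles LD-clustered
panels or related reference individuals, where leave-one-out frequencies
are only a partial guard.

## Networks and training

Networks are plain multilayer perceptrons with logistic activations
everywhere, squared-error loss, and full-batch gradient descent at a fixed
learning rate (default 1.0, 600 epochs, convergence when the loss change
stays below 1e-6 for 5 epochs). Inputs are the raw dosages, unscaled.
Two architectures are used:

* two hidden layers of 40 and 38 units with one-hot (one logistic unit per
  breed) outputs — the deep network whose first-layer weights feed the
  max-|W| criterion;
* one hidden layer of 40 units with a single output unit, the breed index
  mapped onto [0, 1] — the form the classic Garson and Olden algorithms
  require (single hidden layer, single output).

Weights initialize uniformly on ±1/√(fan-in). With raw 0/1/2 inputs and
input layers 500–1,000 wide, a fixed-width init saturates every logistic
hidden unit and back-propagation cannot move the weights; fan-in scaling
keeps pre-activations O(1) regardless of chunk width. Returned weights are
the best iterate seen, so the reported loss never exceeds the loss at
initialization. Back-propagation gradients are verified against central
finite differences in the test suite (relative error < 1e-5).

Panels wider than the chunk size (default 1,000 SNPs) are partitioned into
consecutive column blocks, one network per block; raw weight magnitudes are
only comparable within a single fit, so the selection threshold is applied
per block. Missing dosages are mean-imputed per SNP before training only
(assignment instead skips missing loci, keeping likelihoods proper).

## Importance readouts and selection

* **First-layer (deep) criterion** — score of input j is `max_h |W_jh|`
  over the input-to-first-hidden matrix. Deeper layers are ignored: every
  downstream connection is a function of the first layer's load, so the
  first-layer magnitudes carry the per-variable signal. Selection keeps
  input j when its score *strictly* exceeds
  `mean(|W|) + sd(|W|)` (population sd) pooled over all first-layer
  magnitudes of the same network; pooling over per-input maxima is
  available as `statistic="per_input_max"`. Note the selected-set *size*
  this rule yields depends on the trained weight distribution, hence on
  initialization and optimizer; it is not a stable property of the data.
* **Garson** — per input, hidden-unit shares `|w_ih|·|v_ho| / Σ_i'|w_i'h|`
  summed over hidden units and normalized to 1 over inputs; outputs with
  zero total contribution are excluded from the per-output average so
  scores always sum to 1 (a fully degenerate network scores all-zero).
  Hidden units with all-zero incoming weights contribute 0, not NaN.
* **Olden** — signed `Σ_h w_ih·v_ho`, averaged over outputs; ranked by
  absolute value.

Garson and Olden selections are top-k (k is a parameter; the field
literature fixes such counts by eye, which is not reproducible). Rankings
are dense by decreasing score (|score| for Olden) with ties broken stably
by panel order. Averaging scores over n_iterations retrainings with fresh
seeds stabilizes the single-hidden-layer readouts markedly; single-fit
Garson/Olden rankings are noisy on overparameterized blocks.

## Assignment

Per breed, counted-allele frequencies are `Σdosage / (2·n_called)`.
Frequencies outside (0, 1) are clamped to `[1/(2n+2), 1 − 1/(2n+2)]`
(n = breed sample count) so unseen alleles have small positive likelihood
instead of −∞. The per-breed log-likelihood of a genotype is the sum over
non-missing loci of `log10` of the Hardy–Weinberg probability (p², 2p(1−p),
(1−p)²). The individual is assigned to the argmax breed; the LLR is the
log10 gap to the best alternative, so stringency level L (pass requires
LLR > L, strict) demands a 10^L-fold likelihood advantage. A diagnostic
true-breed-vs-best-other LLR is reported alongside (negative on
misassignment). When individuals are scored against the panel they belong
to, leave-one-out frequencies (own alleles removed from the labeled
breed's counts) are the default — resubstitution inflates success.
Success curves evaluate nested top-k panels on an explicit grid of marker
counts, and the minimal-k table reads the smallest evaluated k reaching
each target rate (no interpolation).

## Structure diagnostics

PCA runs on the mean-imputed, column-centered dosage matrix (optional
unit-variance scaling; default off, matching the raw-dosage convention
elsewhere), full SVD, with each component's sign fixed by making its
largest-magnitude loading positive — scores are fully deterministic.
The allele-sharing distance between two individuals is
`1 − mean_j (2 − |d_x − d_y|)/2` over loci called in both (pairwise
deletion); identical genotypes share 2 alleles, het vs hom 1, opposite
homozygotes 0. Neighbor-Joining is the Saitou–Nei algorithm with the
Q-criterion, deterministic index-order tie-breaking, and negative branch
lengths clamped to 0 with the deficit moved to the sister branch (logged);
the final three lineages join at an unresolved root, giving an unrooted
Newick. On additive matrices the tree reproduces the input distances
exactly (checked to 1e-9 and cross-checked against scikit-bio's NJ).

## Numerical and design notes

* Missing-data policy differs by stage on purpose: mean-imputation for
  network training (complete inputs required; QC caps missingness at 1%),
  locus-skipping for likelihoods, pairwise deletion for distances,
  mean-imputation for PCA.
* All randomness flows from integer seeds through `numpy` generators with
  spawned child streams per stage; identical config + seed reproduces
  byte-identical text outputs, which the pipeline manifest (SHA-256 per
  output) makes checkable.
* The LLR tie between two equally likely breeds is broken by breed order
  and flagged; it fails every stringency level since LLR = 0.
* Known limitations: no LD pruning or awareness; no Bayesian
  (Rannala–Mountain) assignment variant; Garson/Olden are undefined for
  multi-hidden-layer networks by construction and are rejected rather than
  approximated; the mean+sd selection rule's selected-set size is
  init-dependent (see above) — the *ranking* is the stable artifact.
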