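# Methods

## Model and estimation

The observation model is independent Poisson counts over a low-rank mean:
A_ij ~ Poisson((WH)_ij) with W (genes × k) and H (k × samples) nonnegative.
Minimizing the generalized KL divergence L(A, WH) = Σ A log(A/WH) − A + WH
is maximum-likelihood estimation under this model, and remains justified for
scaled-Poisson data (cA_ij Poisson with mean c(WH)_ij). The solver is the
classical pair of coupled multiplicative updates, H first, then W with the
already-updated H. Multiplicative updates preserve nonnegativity and never
increase L.

Numerical choices:

- Initialization: W and H i.i.d. uniform on (1e-4, 1], strictly positive so
  no entry is absorbed at zero. The whole trajectory is a deterministic
  function of the integer seed.
- Floors: 1e-12 added inside every division and applied entrywise to W and H
  after each update — standard practice to avoid 0/0 in the update ratios.
  0·log(0/x) is taken as 0 (limit convention).
- Stopping: the argmax-derived sample connectivity matrix of H is checked
  every 10 iterations; when unchanged for 4 consecutive checks the fit stops
  (cap 2000 iterations). This is the consensus-clustering convention: the
  quantity of interest is the assignment, which stabilizes long before the
  loss bottoms out. Loss-convergence studies (e.g. exact-rank recovery in
  the tests) disable the stall rule via the public `stall_checks` /
  `max_iter` parameters.
- Degenerate input (all-zero gene row, zero column) is rejected with an
  error naming the offender rather than silently repaired: a zero row makes
  the Poisson likelihood degenerate, and the caller should drop it
  deliberately.
- A Euclidean-loss variant (`fit_nmf_eu`, Gaussian noise model) is provided
  for comparison with the same interface.

## Normalization

Any positive diagonal D gives an equivalent factorization (WD⁻¹)(DH); the
post-processing step canonicalizes by a per-column statistic of W:
max, 1/2/3-norm, sample SD (n−1 denominator), or the 0.95/0.75/0.5 sample
quantile (linear interpolation — the quantile convention is not canonical,
and other conventions would shift quantile-scheme results slightly). All
eight statistics are positively homogeneous of degree 1, which is exactly
what makes the normalized pair — and every downstream assignment — invariant
under the rescaling ambiguity. W′H′ = WH holds to exact algebraic
cancellation. Columns on which the statistic is zero or undefined (all-zero
column; constant column under SD) raise an error naming the metagene: a dead
metagene means k is too large, and the user should know rather than receive
a silently rescaled result.

Only the max scheme bounds W′ in [0, 1], supporting the membership reading
of W′ (a gene fully in its metagene has membership 1); it is the default
everywhere, including rank selection.

## Embedded filter

After a first fit and normalization, each gene gets a spread u_i = max_j
W′_ij − min_j W′_ij; genes with u at or below the T-quantile of u (default
T = 0.5, inclusive comparison, so ties at the threshold are discarded and at
least half the genes go) are removed, and NMF is refit on the reduced matrix
— the second pass seeds as seed+1 so the pipeline reproduces from one
integer. The spread vector is computed from the first pass only; the second
pass contributes the final H. With a single metagene (k = 1) all spreads are
zero and the filter degenerates to discarding everything; this surfaces as a
warning and an error on refit. The variance filter (keep the top fraction of
genes by row variance, n−1 denominator, ties broken by original index) needs
no first fit and therefore runs NMF once.

## Consensus rank selection

For each candidate k, `nloop` fits with consecutive seeds are normalized
(max), argmax-assigned (ties to the smallest row index), and their binary
connectivity matrices averaged into the consensus matrix. The cophenetic
coefficient is the Pearson correlation, over each unordered sample pair
once, between 1 − C̄ and the cophenetic distances of an average-linkage
dendrogram built on 1 − C̄. Average linkage is the convention of the
consensus-clustering literature this workflow descends from. A perfectly
block-binary consensus makes 1 − C̄ ultrametric and r exactly 1; the
recommended k is the argmax of r with ties to the smaller k. `nloop`
defaults to 50 (stability/runtime balance at desk scale; the tests and the
acceptance script use 20, which is already stable on the synthetic designs).
Rank selection runs without the embedded filter by default (a `use_filter`
flag enables the filtered pipeline inside the consensus loop).

## Evaluation protocol

Predicted clusters are matched to true classes by rectangular Hungarian
assignment on the contingency table — the optimal injective matching, the
most charitable standard convention; unmatched predicted clusters contribute
no correct samples. (The tests verify equality with brute-force permutation
maximization over all contingency tables with up to 8 samples and 3
classes.) Experiments repeat the pipeline over consecutive seeds (100 runs
by default), report mean accuracy and SEM = SD/√n, and compare two method
configurations run on identical seeds with a paired two-sided t-test.
Zero-variance differences are degenerate for the t-test and are reported as
p = 1 (identical runs) or p = 0 (exact constant shift), with a warning.
Helpers reproduce the standard robustness probes: restriction to the most
variable genes, and additive uniform noise A′ = A + μ·r with r ~
U[0, max(A)].

## Synthetic data

The generator plants the exact structure the model assumes. Signal genes
get membership 1 in a round-robin home metagene and U(0, 0.2) elsewhere, so
every metagene contains at least one fully-on gene — the assumption that
justifies max normalization. Irrelevant genes get near-constant membership
rows (spread ≤ `flatness`, default 0.05) at a high baseline, U(0.85, 0.95):
they emulate housekeeping genes, strongly expressed regardless of class,
which is the variant of class-irrelevant signal that measurably perturbs the
fit (low-expressed flat rows are almost harmless: their noise projects onto
the common expression direction). Samples are assigned round-robin (or by a
`cluster_weights` vector for unbalanced cohorts); each sample expresses its
home metagene `dominance` times the others, scaled by `expression_scale`.
Entries are Poisson draws from the planted mean (or X/c with X ~
Poisson(c·mean) in the scaled variant); all-zero rows are redrawn a bounded
number of times.

Default design (1000 genes of which 10% irrelevant, 60 samples, k = 3,
scale 50, dominance 5) is deliberately well separated: the pipeline should
recover the planted classes essentially perfectly, and rank selection
should peak at k = 3. The stress design used for method comparison (200
genes of which 50% irrelevant, 36 samples, scale 3, dominance 2) was chosen
to put the unfiltered baseline below ceiling while keeping the first-pass
fit good enough for the filter to stay precise (recall of planted
irrelevant genes above 90%).

What passing these tests does not show: real expression data have
gene-specific magnitudes spanning orders of magnitude, correlated gene
modules beyond the planted factors, batch structure, and (for counts)
overdispersion — none of which the generator emulates. Results on synthetic
data bound what the implementation does under its own model assumptions,
not its field performance.

## Known limitations

- On data generated exactly from the Poisson/membership model, max
  normalization does not measurably improve argmax assignment over the raw
  H: raw multiplicative-update solutions already land on nearly comparable
  row scales, so the normalization mostly adds the sampling noise of the
  column-maximum estimator. The observed benefit of normalization on real
  cohorts presumably rides on asymmetries (gene-magnitude heterogeneity,
  module correlation) this model cannot express. The embedded filter's
  benefit is real but small in this model and is detected only with many
  paired runs.
- KL multiplicative updates converge sublinearly near flat minima;
  exact-loss targets require disabling the stall rule and generous
  iteration budgets, and ill-conditioned factor matrices (highly correlated
  columns) may not reach tight loss tolerances in reasonable time.
- The default filter threshold T = 0.5 is a convention, not an adaptive
  choice; with gene panels much cleaner or dirtier than 50% irrelevant it
  will over- or under-filter.
- The cophenetic coefficient compares candidate ranks only through
  assignment stability; a smaller-than-true k with a consistently merged
  pair of classes can also look stable.
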