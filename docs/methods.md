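# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `fragilome`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The degradation model

A genome is a string over {A,C,G,T}; ambiguity codes are tolerated on
input and excluded window-wise from counting (below). One degradation
iteration visits every base of the current sequence independently:

- with probability `snp_rate` the base is substituted, uniformly over the
  three other bases (a substitution never reproduces the original base;
  a non-ACGT base hit by a SNP becomes a uniform random base);
- with probability `del_rate` the base is deleted (deletion pre-empts a
  substitution at the same position);
- with probability `ins_rate` an insertion of `indel_length` uniform
  random bases is placed immediately before it;
- optionally, with probability `inversion_rate`, a segment of
  `inversion_length` bases starting there is reverse-complemented
  (off by default; translocations and duplications are out of scope).

All events of one iteration are decided in one left-to-right pass over
the input coordinates, and one RNG stream (seeded from
`MutationConfig.seed`) drives an entire degradation run, which makes
degradation compositional: running k₁ iterations and then k₂ more on the
same stream is identical to running k₁+k₂. Equal seeds give bit-identical
output.

Under a SNP-only configuration each site is an independent 4-state
uniform-replacement Markov chain, so sequence length is preserved exactly
(Hamming distance stays defined), the expected fraction of sites differing
from the origin after t iterations is (3/4)(1 − e^(−4rt/3)) — concave and
increasing — and the tuple distribution converges to uniform, i.e. the
n-tuple entropy converges to its maximum log₂ 4ⁿ. These closed-form limits
are what the concavity and entropy-limit tests check against.

### Mutation-rate presets

The per-iteration rates are free parameters of the paradigm; the package
fixes three SNP-only presets and uses them consistently:

- `MutationConfig.probe()` — `snp_rate = 1e-4` (also the library default,
  with `ins_rate = del_rate = 1e-6` when indels are wanted). This is the
  *measurement* rate: over the standard 0–2000 checkpoint window it keeps
  entropy trajectories in the smoothly concave, far-from-saturation regime
  where the quadratic compression is faithful (bulk R² ≈ 0.99 in the
  synthetic studies; at 7e-4 the same curves saturate by iteration 2000
  and quadratic R² collapses to ≈ 0.88, which would defeat the feature
  construction).
- `MutationConfig.heavy()` — `snp_rate = 3e-4`, the *damage* rate used to
  plant low-quality database members: 2000 iterations hit ≈ 45% of sites
  at least once, enough that planted genomes separate decisively in
  triplet-distribution space while their residual entropy headroom still
  supports a well-fitting quadratic when re-measured. Rates between
  2.5e-4 and 4e-4 behave equivalently in the planted-recovery studies;
  3e-4 is the middle of that robust region.
- `MutationConfig.calibrated()` — `snp_rate = 7e-4`, which matches the
  decay speed of long-repeat counts reported for a degraded E. coli
  genome (all repeats of length ≥ 20 obliterated within a few hundred
  iterations); used for repeat/palindrome decay work.

## Tuple distributions and the Markov null

`tuple_distribution` counts every contiguous length-n window (n = 1..4)
consisting solely of A/C/G/T and divides by the number of such windows;
windows containing any other character are excluded from numerator and
denominator alike, so an N-run shrinks the sample rather than biasing it.
Indexing is lexicographic (A<C<G<T), single-strand only, no
reverse-complement symmetrization.

The triplet counts also yield the 16×4 transition matrix T(b₁b₂→b₃)
(a second-order Markov model) plus the prefix-pair distribution Q, with
the exact identity P₃(b₁b₂b₃) = Q(b₁b₂)·T(b₁b₂→b₃). Contexts never
observed are flagged NaN, not zero-filled. `TransitionMatrix.sample_codes`
simulates from this model (vectorized across replicates); it is both the
synthetic-genome generator and the null model for significance
thresholds: `null_threshold` takes the (1−α) empirical quantile of
Hellinger distances between a genome's n-tuple distribution and those of
`reps` same-length Markov simulations (an iid-base alternative is
exposed). Which resampling scheme best mimics real null variation is an
open question; the Markov null is the most information-preserving of the
simple choices.

## Distances

- Hellinger distance is computed in the root-vector form
  (1/√2)‖√p − √q‖₂, which is exactly zero at p = q and bounded in [0,1].
- Hamming distance between unequal-length sequences is the distinguished
  value `inf` rather than an exception, so SNP-only trajectory code and
  indel-bearing configurations share one code path.
- Levenshtein distance delegates to `edlib` (unit-cost global alignment);
  an independent quadratic DP oracle verifies it in the tests.

## Trajectories and quadratic features

`entropy_trajectory` measures the n-tuple entropy of the degradation
snapshot at each checkpoint (default 0, 250, 500, 1000, 2000);
`distance_trajectory` measures Hamming/Levenshtein/Hellinger-n distance
from a fixed origin (the genome itself, its parent, or any third genome —
the three origin conventions differ, and the fixed-third-genome form is
the one that stays informative when no pristine parent exists).
`fit_quadratic` regresses the 5 values on (1, k, k²) by ordinary least
squares with the raw iteration counts as abscissa; R² uses the convention
R² = 1 when the total sum of squares is zero. Fitting raw entropy rather
than entropy increase changes only c₀, which the later standardization
absorbs.

## Outlier detection

Features are either the 3 quadratic coefficients or the 64 triplet
probabilities, column-standardized (z-scores, sample SD; constant columns
zeroed with a warning). Clustering is agglomerative on Euclidean
distances with three linkage options: `complete` (scipy), `ward`
(Lance–Williams Ward update applied to *raw* distances — replicating the
`ward.D` quirk of R's hclust, implemented here directly) and `ward2`
(the orthodox squared-distance Ward, scipy's `ward`). Cut labels are
renumbered by dendrogram leaf order so cluster 1 sits at the bottom of
the tree.

`choose_k` scans k = 2..k_max with the Calinski–Harabasz index and takes
the *first local maximum*: the global argmax degenerates when an
internally dispersed outlier cluster is present (splitting it inflates
the index monotonically), whereas the first local maximum prefers the
parsimonious solution and still recovers planted blob counts. All scores
and an elbow-style merge-height profile are available from
`choose_k_scores` for inspection.

`embed_centroids` is classical (Torgerson) MDS: double-center the squared
centroid distance matrix, take the top two eigenpairs, scale by
√eigenvalue; non-positive eigenvalues contribute zero coordinates.
`variance_explained` is per-column one-way ANOVA R² (between/total sum of
squares, in percent); `cross_tabulate` is a margin-summed contingency
table of two clusterings.

`flag_outliers` flags clusters that are simultaneously small
(size ≤ `max_size_fraction`·n) and separated (centroid at least
`min_centroid_separation` × the median inter-centroid distance from the
nearest non-candidate centroid). The function defaults (0.01, 2.0) suit
databases of tens of thousands of genomes, where the cut typically
produces many bulk clusters and the median inter-centroid distance is a
bulk-to-bulk scale. The pipeline layer passes (0.05, 1.0) instead: in a
few-hundred-genome database the planted fraction itself is ≈ 3.5%, and
with few clusters the median inter-centroid distance is already an
outlier-to-bulk distance, so a multiplier above 1 would reject genuine
outliers by construction.

## Repeats and palindromes

Both counts use ≥-threshold conventions, so columns of a decay table are
nested. A repeat count at length L is the number of L-windows whose exact
sequence occurs at least twice on the same strand (occurrence counting,
self-overlaps included). A palindrome count at half-length h is the
number of inter-base centers whose left flank reversed-complemented
equals the right flank; at h = 6 the iid-sequence expectation is
|G|·4⁻⁶, which the tests verify on a 1 Mb random genome. Occurrence
counting was chosen over distinct-string or maximal-repeat counting
because it makes the slow decline of counts across thresholds at
iteration 0 behave like published E. coli repeat tables; the convention
is frozen here and exercised against a naive hash-table oracle. Planted
repeats can gain shifted duplicate windows when flanking bases happen to
match across copies (probability 1/4 per pair per side) — the planted
fixtures account for this.

## The synthetic database

`build_database` emulates the structure of a spiked genome database:

- one 30 kb template genome drawn from a random Dirichlet(1)-row
  second-order Markov model (triplet entropy ≈ 5.4 bits, comfortably
  below the 6-bit maximum, as in structured viral genomes);
- 300 bulk members, each the template with iid SNPs at 5e-3 per base —
  large enough that members are distinct, small enough that they form a
  single cluster;
- 10 degraded outliers: randomly chosen bulk members run through 2000
  iterations of `MutationConfig.heavy()`;
- 1 foreign genome: iid uniform, length 34,125 (a nod to the classic
  adenovirus spike; the value is cosmetic).

A truth table logs each member's role, parent and seed, so every pipeline
stage is testable by parameter recovery. What the generator does *not*
emulate: real phylogenetic (clustered, non-star) diversity, recombination,
composition skew along the genome, assembly gaps and N-runs, and
sequencing-platform error profiles. Passing the planted-recovery studies
therefore shows the pipeline recovers quality outliers under the model's
own assumptions — star-shaped bulk divergence and mutation-style damage —
not that it is robust to every failure mode of real databases.

## Problem sizes and numerical choices

The validation studies use 311 genomes of 30 kb, 20-replicate averages for
curve-shape assertions, and 100+ replicates for null quantiles — sizes at
which every Monte-Carlo assertion has comfortable margin while a full run
of suite plus acceptance script stays in the minutes range on one CPU.
Tolerances: probability vectors must sum to 1 within 1e-12 (1e-8 on user
input), oracle equivalences are asserted at 1e-8–1e-10, entropy-limit
convergence at 0.02 bits (the finite-sample entropy bias of 30 kb windows
over 64 bins is ≈ 0.0015 bits, an order of magnitude below). Determinism:
every stochastic component takes either a seed or an explicit
`numpy.random.Generator`; nothing reads global RNG state.

## Known limitations

- The Hamming/Levenshtein trajectory layer decodes snapshots to strings
  per checkpoint; for genomes far beyond bacterial scale the Levenshtein
  option is the bottleneck (quadratic alignment), as is well known.
- `ward.D` linkage is implemented as a dense O(n³) greedy agglomeration;
  fine for thousands of genomes, not for hundreds of thousands.
- Degraded sequences render all ambiguity codes as N (the original
  letter is not preserved through the mutation engine).
- Amino-acid translation of triplet distributions and read-level error
  models are deliberately out of scope.
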