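# Methods

## Model and assumptions

The input is one chromosome's binned contact count matrix **X** ∈ ℝ₊ⁿˣⁿ,
assumed symmetric, finite and non-negative; all-zero rows (unmappable bins)
are retained. The model is graph-regularized NMF: minimize
‖X − UVᵀ‖²_F + λ·Tr(VᵀLV) + λ·Tr(UᵀLU) over U, V ≥ 0, with L the Laplacian
of the chain graph that links bins within r bins of each other. The graph
encodes the one assumption the method leans on: bins that are close along
the chromosome should have similar latent profiles. For symmetric X the two
factors agree up to a scaling constant; no symmetry is forced during the
updates, and quantities derived from the factors use U (clustering) or the
symmetrized product (smoothing) accordingly.

TADs are modeled as contiguous clusters: the chain-constrained k-medoids
step can only produce consecutive runs of bins, so nested or overlapping
domains are out of scope by construction, as are asymmetric (e.g.
inter-chromosomal) matrices.

## Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| k | rank = number of domains | chromosome length / 1 Mb (min 2) | 1 Mb is TAD scale; 500 kb / 2 Mb give sub/meta-TAD segmentations |
| r | neighbor-graph radius (bp) | 250 kb | regularization neighborhoods below ~100 kb behave like no regularization |
| λ | regularization strength | 1 | λ = 0 is plain NMF; large λ over-smooths |
| max_iter / tol / check_every | stopping rule | 300 / 1e-4 / 10 | objective logged every 10 iterations; stop on relative decrease < tol |
| ε | denominator guard in updates | 1e-10 | multiplicative updates are undefined at zero denominators |

## Numerical choices

* **Initialization.** NNDSVD on randomized-SVD triplets (oversampling 10,
  2 power iterations, seeded Gaussian test matrix), so fits are
  deterministic given a seed. The dense-fill variant replaces exact zeros in
  the initial factors with mean(X)/100: plain NNDSVD zeros are absorbing
  under multiplicative updates and would permanently disable entries.
* **Update order.** Full U update then full V update per iteration, each
  vectorized (simultaneous within a matrix).
* **k-medoids determinism.** Medoid t starts at bin ⌊(2t+1)n/2k⌋; split-point
  and medoid ties resolve toward the smaller bin index; distances are
  Euclidean on rows of U. The per-iteration within-cluster cost is
  non-increasing, and iteration stops when labels are stable (cap 50).
* **Filters.** Mean and Gaussian windows are truncated at matrix edges and
  renormalized by the in-bounds weight mass, so constants are preserved
  exactly everywhere. The Gaussian filter's analytic prefactor 1/(2πσ²) —
  under which edges are damped and constants only approximately preserved —
  is available behind `normalize=False`. Window half-width is 4σ.
* **Downsampler.** Strata are genomic distances in bins, diagonal included
  as d = 0. At each distance, z_d = max(0, target zeros − existing zeros)
  non-zero entries are zeroed uniformly at random (symmetrically), then the
  survivors are rescaled so their mean equals the target's non-zero mean
  exactly. Scaling entries before sparsification would match that mean only
  in expectation, and on skewed sparse strata the realized mean of a random
  surviving subset misses by more than the 10% fidelity the contract asks
  for; rescaling survivors matches both the sparsity level and the non-zero
  mean by construction. Scaled counts stay real-valued (no re-rounding;
  an integer-rounding flag is deliberately absent by default).
* **Empirical p-values** against shuffled-TAD nulls use the strict fraction
  of null values better than the observed one (ties count as not better);
  direction is explicit per statistic (lower is better for DBI, higher for
  DCC and signal means). Mutual information is the plug-in estimator with
  natural log and no bias correction. The Rand index is the standard
  both-agreements form. DCC excludes diagonal entries (pairs p < q);
  DBI uses Euclidean distance on raw matrix rows.
* **Background bins.** Callers that skip genome stretches are represented by
  the reserved label −1, which forms a single comparison cluster in
  agreement metrics and is excluded from per-TAD statistics; shuffling
  preserves the multiset of TAD lengths and of background gap lengths.

## Synthetic data

The simulator draws Poisson counts around
μᵢⱼ = A·(|i−j|+1)^(−α)·(1 + β·[same block]), i.e. power-law distance decay
with planted contiguous blocks; the +1 offset keeps the diagonal finite.
Defaults (n = 240 bins of 25 kb, six 40-bin blocks, α = 1, β = 6, A = 50)
emulate a well-covered 6 Mb region with 1 Mb domains of strong contrast.
What it does **not** emulate: A/B compartment checkerboards, loop peaks,
copy-number and mappability artifacts, nested domain hierarchies, or
overdispersion beyond Poisson. Passing the recovery tests therefore shows
the pipeline identifies clean block structure under realistic decay and
count noise — not that it resolves the harder ambiguities of real Hi-C.

## Experiment conditions used by tests and the acceptance script

Problem sizes are chosen so the whole suite runs in minutes on one CPU.

* **Planted-domain recovery:** 10 seeds at the simulator defaults, k = 6,
  r = 10 bins, λ = 1; success is Rand ≥ 0.9 against planted labels.
* **Objective monotonicity:** 20 matrices (n = 200, five 40-bin blocks),
  λ ∈ {0, 1, 10}, objective logged every 10 iterations.
* **λ = 0 reduction:** 50 iterations on a 60-bin matrix against an
  independently written plain-NMF update loop from the same NNDSVD start.
* **Smoothing benefit:** the deep matrix uses weaker contrast and coverage
  (β = 2, A = 10, n = 240) so that its 20%-depth, doubled-sparsity
  downsampled version sits in a regime where calling genuinely degrades —
  at the default β = 6, A = 50 the downsampled matrix is still trivially
  callable and every method ties. TADs are called by a fixed rule
  independent of the smoother under test (chain k-medoids on matrix rows,
  k = 6), on the deep matrix, the downsampled matrix, and its
  completion-smoothed reconstruction; the comparison counts seeds where
  smoothing strictly improves agreement with the deep-data TADs.
* **Null calibration:** 2000 five-bin TADs with i.i.d. Gaussian per-bin
  signal; the shuffled-TAD null (10 shuffles) should flag ≈ 5% of TADs at
  α = 0.05.

## Known limitations

* One chromosome per matrix; no genome-wide container, no .hic/.cool I/O,
  no KR/VC normalization (inputs are taken as provided).
* The factorization objective is non-convex; different seeds can give
  different local optima (the deterministic NNDSVD start makes any given
  seed reproducible).
* The relative scale of U vs V is not identified by the objective; smoothing
  symmetrizes the product and factor-smoothness comparisons should be made
  on unit-norm columns.
* k is a user choice (or derived from an expected domain size); the method
  does not infer the number of domains.
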