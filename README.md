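# tadnmf

Graph-regularized non-negative matrix factorization for **simultaneous
smoothing and TAD calling** on Hi-C contact matrices.

Chromosomes fold into topologically associating domains (TADs): contiguous
stretches of the genome whose binned regions contact one another more often
than they contact their surroundings. Calling TADs from a binned contact
count matrix is hard precisely when the data are most interesting — at fine
resolution or low sequencing depth the matrix is sparse and noisy, and most
callers degrade. `tadnmf` addresses both problems with one model: a low-rank
factorization whose latent features are forced to vary smoothly along the
chromosome. The factors segment the chromosome into contiguous domains, and
the low-rank reconstruction doubles as a smoothed, imputed contact matrix.

It is aimed at computational biologists analyzing chromosome-conformation
data (Hi-C and related protocols such as SPRITE or HiChIP) at the
per-chromosome, fixed-bin-size level.

## Model

Given a symmetric non-negative contact matrix **X** (n × n bins), find
non-negative factors **U**, **V** (n × k) minimizing

```
‖X − UVᵀ‖²_F + λ·Tr(VᵀLV) + λ·Tr(UᵀLU),   U, V ≥ 0
```

where **L** = **D** − **W** is the Laplacian of a chain graph connecting bins
within a radius *r* of one another (**W**ᵢⱼ = 1 iff 0 < |i−j| ≤ r bins,
**D** the degree matrix). The Laplacian terms penalize differences between
the latent features of linearly adjacent bins, encoding the strong distance
dependence of chromatin contacts. Optimization is by multiplicative updates

```
U ← U ⊙ (XV + λWU) ⊘ (UVᵀV + λDU)
V ← V ⊙ (XᵀU + λWV) ⊘ (VUᵀU + λDV)
```

from a deterministic NNDSVD initialization built on randomized SVD; with
λ = 0 this is classic unregularized NMF. Rows of **U** are then clustered by
**chain-constrained k-medoids** — medoids start evenly spaced, consecutive
medoids compete for the bins between them through a single optimal split
point, so every cluster is one consecutive run of bins. Those runs are the
TADs; **X**ˢ = (UVᵀ + VUᵀ)/2 is the smoothed matrix.

Defaults follow the TAD-scale setting: k = chromosome length / 1 Mb,
r = 250 kb, λ = 1.

The package also ships the classical mean and Gaussian window-filter
smoothers, a distance-stratified depth downsampler, a synthetic-matrix
simulator with planted domains, and a TAD evaluation suite (Davies-Bouldin
index, delta contact count, shuffled-TAD empirical nulls, Rand index, mutual
information, boundary fold enrichment, hypergeometric tests, Jaccard, AUPR).

## Worked example

```python
import tadnmf as t

# simulate a 240-bin chromosome (25 kb bins) with six planted 40-bin domains
m, truth = t.simulate(t.SimulationParams(seed=3))

est = t.TADCaller(n_clusters=6, radius=250_000, lam=1.0, random_state=3).fit(m)
print([(tad.start_bin, tad.end_bin) for tad in est.tads_])
print(t.evaluator.rand_index(est.labels_, truth.labels))
```

prints

```
[(0, 39), (40, 79), (80, 119), (120, 159), (160, 199), (200, 239)]
1.0
```

— the six called TADs coincide exactly with the planted blocks (Rand index 1
against the planted labels). The same pipeline is available from the shell:

```
tadnmf simulate --n-bins 240 --blocks 40x6 --seed 3 --out-prefix sim
tadnmf call-tads --matrix sim.matrix.txt --bin-size 25000 --k 6 \
    --radius 250000 --lam 1 --seed 3 --out-prefix run
```

which writes `run.tads.bed`, the smoothed matrix `run.smoothed.txt`, the
factor matrices and a parameter log. See `tadnmf --help` for the `smooth`,
`filter`, `downsample` and `evaluate` subcommands.

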