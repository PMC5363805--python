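# gomclust

Grade-of-membership (GoM) clustering of RNA-seq count matrices.

Classic clustering forces every sample into exactly one group. For bulk and
single-cell RNA-seq that is often too coarse: a tissue sample is a mixture of
cell populations, and a differentiating cell sits *between* stages rather
than in one of them. `gomclust` instead fits a mixed-membership model in
which each sample carries a fractional membership in each of `K` latent
expression programs — the same model family known as topic models / latent
Dirichlet allocation in text mining and as admixture models in population
genetics. The package is aimed at computational biologists who want
model-based soft clustering of a samples × genes count table, together with
interpretable per-cluster gene rankings and publication-style Structure
plots.

## The model

Given counts `c_ng` for sample `n` and gene `g` with library size
`c_n+ = Σ_g c_ng`, the model is

```
(c_n1, …, c_nG) ~ Multinomial(c_n+, p_n1, …, p_nG),
p_ng = Σ_k q_nk θ_kg ,
```

where `q_nk` (N×K, rows on the simplex) is the grade of membership of
sample `n` in cluster `k` and `θ_kg` (K×G, rows on the simplex) is the
relative expression of gene `g` in cluster `k`. Fitting is maximum a
posteriori via EM under symmetric Dirichlet priors on the rows of `q` and
`θ` (defaults: flat on `q`, concentration 1.1 on `θ` so profiles stay
strictly positive), with several random restarts; the restart with the
highest data log-likelihood is kept.

Clusters are annotated by the distinctiveness of each gene,

```
D_g[k] = min_{l≠k} KL( Poisson(θ_kg) ‖ Poisson(θ_lg) ),
```

the Kullback–Leibler divergence to the *closest* competing cluster: a gene
scores high only if it separates cluster `k` from every other cluster.

The package also provides binomial thinning (`t_ng ~ Bin(c_ng, p_thin)`) to
emulate shallower sequencing, a pairwise two-group separation benchmark
comparing the GoM fit (K=2, steepest-fall cut on sorted memberships) against
agglomerative hierarchical clustering on log-CPM (Euclidean distance,
complete or average linkage, dendrogram cut at 2), and a synthetic-data
generator that samples the generative model with known ground truth.

## Worked example

```python
import gomclust as gc

# simulate 60 samples, 120 genes, 3 expression programs, 2000 reads each;
# 70% of samples are pure, the rest admixed
cfg = gc.SimulationConfig(N=60, G=120, K=3, library_size=2000,
                          membership_regime="mixed",
                          profile_separation=1.5, seed=101)
counts, q_true, theta_true = gc.simulate_gom_counts(cfg)

fit = gc.fit_gom(counts, gc.FitConfig(K=3, seed=5))
print(f"log-likelihood {fit.log_likelihood:.1f}, "
      f"converged={fit.converged} in {fit.n_iter} iterations")
print("membership error", round(gc.aligned_membership_error(q_true, fit.q), 4))

table = gc.distinctiveness(fit.theta, fit.gene_ids)
print(gc.top_driving_genes(table, k=0, n=3))
```

prints

```
log-likelihood -150908.0, converged=True in 402 iterations
membership error 0.0246
[('gene_79', 1.6213716446162616), ('gene_24', 0.2641865776776977), ('gene_51', 0.21309642948696)]
```

The membership error of 0.025 says the fitted `q` matches the simulated
truth to about two percent per entry (after matching cluster labels); the
driving-gene scores are the `D_g[k]` values above — here `gene_79` is the
gene whose expression most distinguishes cluster 1 from its closest
competitor.

The same pipeline is available from the shell:

```bash
gomclust simulate --n 60 --g 120 --k 3 --seed 101 --out sim/
gomclust fit --counts sim/counts.tsv --k 3 --seed 5 --out fit/
gomclust annotate --fit fit/ --top-n 20 --out annot/
gomclust plot-structure --fit fit/ --labels sim/labels.tsv --out structure.svg
gomclust thin --counts sim/counts.tsv --p-thin 0.01 --seed 42 --out thinned.tsv
gomclust evaluate-pairs --counts sim/counts.tsv --labels sim/labels.tsv --out eval/
```

Every subcommand writes a `manifest.json` (resolved config, seed, version,
input checksums) so runs are reproducible bit-for-bit.

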