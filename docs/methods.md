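# Methods

## Model and estimation

`gomclust` fits a mixed-membership multinomial model to a samples × genes
count table. Sample `n` with library size `c_n+` is modelled as
`Multinomial(c_n+, p_n·)` with `p_ng = Σ_k q_nk θ_kg`, where `q` (N×K) holds
per-sample membership proportions and `θ` (K×G) per-cluster gene
frequencies; both have rows on the probability simplex. The model is
identical in form to latent Dirichlet allocation over gene counts and to
population-genetic admixture models; it assumes that, conditional on the
membership and profile parameters, reads are drawn independently — no
overdispersion beyond what mixing of clusters induces, no zero-inflation,
and no gene–gene covariance within a cluster.

Estimation is maximum a posteriori by plain EM under independent symmetric
Dirichlet priors on the rows of `q` and `θ`. With responsibilities
`r_ngk = q_nk θ_kg / p_ng` (needed only where `c_ng > 0`), the M-step is the
closed-form simplex update

```
q_nk ∝ Σ_g c_ng r_ngk + (α_q − 1)
θ_kg ∝ Σ_n c_ng r_ngk + (α_θ − 1)
```

which is implemented as two matrix products with the ratio matrix
`S = C / P` (entries with `c_ng = 0` contribute nothing). Concentrations are
constrained `≥ 1` so the update never leaves the simplex and the
log-posterior is non-decreasing at every iteration — a contract the test
suite checks at 1e-8 relative tolerance. A numerically degenerate row
(mass underflowing to zero) is reset to uniform with a warning rather than
propagating NaNs.

No quasi-Newton or squared-iterate acceleration is applied: plain EM keeps
the monotonicity guarantee exact and testable, at the price of more
iterations near the optimum. The defaults reflect that trade-off:
`tol = 1e-4` on the absolute log-posterior change, `max_iter = 1000`.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `K` | — | number of latent expression programs, set by the analyst |
| `alpha_theta` | 1.1 | Dirichlet concentration on `θ` rows; > 1 keeps every `θ_kg` strictly positive, which the Poisson-KL gene score requires |
| `alpha_q` | 1.0 | flat prior on memberships (maximum likelihood for `q`) |
| `tol` | 1e-4 | absolute log-posterior change declaring convergence |
| `max_iter` | 1000 | EM iteration cap per restart |
| `n_restarts` | 3 | independent seeded restarts; best data log-likelihood wins |

Restart selection deliberately uses the *likelihood*, not the posterior:
the multinomial coefficient and prior normalisers are constant across
restarts of the same configuration, and the likelihood is the quantity of
scientific interest. Whether to include the prior term is genuinely open;
using the likelihood is this package's recorded choice.

Initialisation draws `q` rows from a flat Dirichlet and starts each `θ` row
at the pooled gene-frequency vector mixed with 20% Dirichlet noise
(`0.8·base + 0.2·noise`). The data-informed start converges much faster
than a fully random one; the noise differs per restart so the restarts
explore different modes. Restart `r` is seeded with `seed + r`, making
every fit bit-reproducible.

`K = 1` has an analytic MAP solution,
`θ_g = (Σ_n c_ng + α_θ − 1) / (Σ c + G(α_θ − 1))`, which EM reaches in one
step; the suite uses it as an exact oracle. Automatic selection of `K` is
out of scope — users are expected to explore several values.

## Driving-gene annotation

Gene `g`'s distinctiveness for cluster `k` is
`D_g[k] = min_{l≠k} [θ_kg log(θ_kg/θ_lg) + θ_lg − θ_kg]`, the KL divergence
between Poisson rates taken against the *closest* other cluster, so a gene
scores high only if it discriminates `k` from every competitor. Scores are
computed on `θ` as fitted (frequencies over genes, not rescaled counts).
Ties in the per-cluster ranking are broken by ascending gene id so reports
are deterministic. `θ` entries of exactly zero — possible only if the user
forces `alpha_theta = 1` — are floored at 1e-12 with a warning, since the
KL score is undefined at zero rates. With a single cluster the score has no
competitor to minimise over and is an error by design.

## Thinning

`thin_counts` replaces each entry with a `Binomial(c_ng, p_thin)` draw,
emulating an experiment that sequenced each original read with probability
`p_thin` (100× thinning ≈ taking a bulk library to high-depth single-cell
scale). Draws are consumed from a single seeded stream in row-major order
over the **nonzero** entries only; zero entries never touch the stream.
This is a stated stability contract: the thinned result for a given seed is
invariant to how many structural zeros surround the data, which matters
when the same data move between sparse and dense representations.

## Pairwise separation benchmark

For a pair of labelled groups, 50 samples (or the whole pool if smaller)
are drawn from the pooled pair without enforcing balance — only a fully
degenerate draw with fewer than two samples from either label is redrawn,
up to 20 times. Each method then produces a hard two-block partition:

* **GoM** — K=2 fit on the raw counts; samples sorted by membership in
  cluster 1; cut at the steepest fall, i.e. after the position with the
  largest drop between consecutive sorted values (first such position on
  ties; an all-equal vector degenerates to a 1 vs n−1 split with a
  warning). The cut is invariant to shifting or positively rescaling the
  membership vector.
* **Hierarchical** — agglomerative clustering with Euclidean distance
  (complete linkage by default, average available) on log-CPM by default,
  with raw-count and per-gene standardised variants as options; the
  dendrogram is cut into two clusters via `scipy.cluster.hierarchy`.

A trial succeeds iff the blocks equal the label groups exactly, in either
orientation. `pairwise_separation_matrix` runs one trial per unordered
label pair with per-pair seeds derived from the global seed via
`SeedSequence`, and reports per-method success fractions; a pair whose
trial machinery errors is excluded from the denominator with a warning.

## Synthetic data

The generator samples the model forward, so ground truth is known exactly:

* **Profiles** — a shared base gene-frequency vector from a symmetric
  Dirichlet with concentration 0.05, giving the heavy-tailed expression
  spectrum of real libraries (a few genes dominate); clusters are the base
  perturbed multiplicatively by `exp(δ·z)`, `z ~ N(0,1)`. `δ = 0` gives
  identical clusters; `δ ≈ 2` gives nearly non-overlapping high-expression
  gene sets. δ = 1–2 is the "well separated" operating point used in the
  examples and checks.
* **Memberships** — regimes: `pure` (one-hot, round-robin), `dirichlet`
  (symmetric Dirichlet, concentration 0.5), `mixed` (a 70% pure fraction by
  default, rest admixed — the regime used for recovery checks), and
  `blockwise` (linear gradients between consecutive clusters, emulating
  developmental trajectories, mainly for plot tests).
* **Library sizes** — presets `bulk` = 1e7 reads (whole-tissue RNA-seq
  scale) and `sc` = 1e4 (single-cell scale); any integer or per-sample
  vector is accepted. Counts are exact multinomial draws, so row totals
  equal the configured library sizes.

What the generator does **not** emulate: batch effects, overdispersion
beyond the mixture, zero-inflation, gene–gene correlation within a
cluster, or ambient contamination. Passing tests therefore demonstrate
correctness of the algorithms under the model's own assumptions, not
robustness to the full messiness of real data.

## Problem sizes and numerical choices

The recovery check fits N=200 samples × G=500 genes at K=3 and 1e4 reads
per sample with three restarts, a size at which the fitted memberships
match truth to mean absolute error well under 0.05 while the whole run
stays in seconds; the benchmark sweeps use 50 drawn samples per trial at
the same depth, matching the benchmark's own protocol. Monte Carlo checks
on success-rate monotonicity allow two binomial standard errors of slack.
Membership recovery error is measured after optimal cluster matching
(brute-force over the K! column permutations, practical to K = 8), since
cluster labels are non-identifiable.

Structure plots sort each label block by the block's dominant cluster
(highest mean membership), descending with stable ties. The published
style of figure does not pin down the within-group rule; sorting by the
dominant cluster reproduces the characteristic within-group colour
gradient, and a `within_group="none"` escape hatch preserves input order.
The palette is a fixed 20-colour qualitative set; `K > 20` is an error
advising a custom palette rather than silently recycling colours. SVG
output uses a fixed hash salt and no timestamp, so identical inputs render
byte-identically — which makes plot reproducibility testable.

## Known limitations

* Plain EM converges slowly on large, weakly separated data; `max_iter`
  may bind before `tol` does (the `converged` flag reports which).
* MAP point estimates carry no uncertainty; no variational or collapsed
  Gibbs posterior is provided.
* The multinomial likelihood ignores overdispersion, so on real bulk data
  clusters may absorb technical variation.
* `aligned_membership_error` is factorial in K and refuses K > 8.
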