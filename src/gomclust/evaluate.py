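"""Pairwise two-group separation benchmark: GoM vs hierarchical clustering.

For a pair of labelled groups, a fixed number of samples is drawn from the
pooled pair and each method must split them into two blocks:

* GoM — fit the model with K = 2 on the raw counts, sort samples by their
  membership in cluster 1, and cut at the steepest fall in that membership;
* hierarchical — agglomerative clustering (Euclidean distance, complete or
  average linkage) on a transform of the counts (log-CPM by default), with
  the dendrogram cut into two clusters.

A trial succeeds iff the two blocks coincide exactly with the two label
groups (either orientation). Running all unordered label pairs gives a
per-method success fraction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch

from .counts import CountMatrix, log_cpm
from .fit import FitConfig, fit_gom

__all__ = [
    "SeparationResult",
    "steepest_fall_partition",
    "gom_pair_separation",
    "hclust_pair_separation",
    "pairwise_separation_matrix",
    "aligned_membership_error",
]

HCLUST_TRANSFORMS = ("logcpm", "raw", "standardized")


@dataclass
class SeparationResult:
    """Outcome of one two-group separation trial."""

    group_a: str
    group_b: str
    method: str
    n_sampled: int
    partition: tuple[list[str], list[str]]
    success: bool
    seed: int


def steepest_fall_partition(memberships: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices at the largest drop in sorted membership.

    Values are sorted descending; the cut goes after position i maximising
    value[i] - value[i+1] (first such position on ties). Returns the two
    index blocks in the original indexing. All-equal input degenerates to a
    1 vs n-1 split with a warning.
    """
    v = np.asarray(memberships, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D vector of at least 2 memberships")
    order = np.argsort(-v, kind="stable")
    sorted_v = v[order]
    gaps = sorted_v[:-1] - sorted_v[1:]
    if np.all(gaps == 0):
        warnings.warn(
            "all memberships equal; steepest-fall cut is degenerate "
            "(1 vs n-1 split)",
            RuntimeWarning,
            stacklevel=2,
        )
        cut = 0
    else:
        cut = int(np.argmax(gaps))
    return np.sort(order[: cut + 1]), np.sort(order[cut + 1 :])


def _blocks_match_labels(
    block_ids: tuple[list[str], list[str]], labels: dict[str, str]
) -> bool:
    a, b = ({labels[s] for s in block} for block in block_ids)
    return len(a) == 1 and len(b) == 1 and a != b


def _subsample_pair(
    m: CountMatrix,
    labels: dict[str, str],
    pair: tuple[str, str],
    n_sample: int,
    rng: np.random.Generator,
    max_redraws: int = 20,
) -> list[int]:
    la, lb = pair
    pool = [i for i, s in enumerate(m.sample_ids) if labels.get(s) in (la, lb)]
    for lab in pair:
        if sum(1 for i in pool if labels[m.sample_ids[i]] == lab) < 2:
            raise ValueError(f"fewer than 2 samples labelled {lab!r}")
    if len(pool) <= n_sample:
        return pool
    for _ in range(max_redraws):
        chosen = list(rng.choice(pool, size=n_sample, replace=False))
        got = {labels[m.sample_ids[i]] for i in chosen}
        counts = [
            sum(1 for i in chosen if labels[m.sample_ids[i]] == lab) for lab in pair
        ]
        if got == {la, lb} and min(counts) >= 2:
            return sorted(chosen)
    raise RuntimeError(
        f"could not draw a subsample with >= 2 samples per label for pair "
        f"({la}, {lb}) in {max_redraws} attempts"
    )


def _subset(m: CountMatrix, idx: list[int]) -> CountMatrix:
    return CountMatrix(
        m.counts[idx], [m.sample_ids[i] for i in idx], list(m.gene_ids)
    )


def gom_pair_separation(
    m: CountMatrix,
    labels: dict[str, str],
    pair: tuple[str, str],
    n_sample: int = 50,
    seed: int = 0,
    fit_cfg: FitConfig | None = None,
) -> SeparationResult:
    """One GoM separation trial: K = 2 fit on raw counts, steepest-fall cut."""
    rng = np.random.default_rng(seed)
    idx = _subsample_pair(m, labels, pair, n_sample, rng)
    sub = _subset(m, idx)
    cfg = fit_cfg or FitConfig(K=2, seed=seed)
    if cfg.K != 2:
        raise ValueError("the pairwise benchmark requires K = 2")
    if cfg.seed != seed:
        cfg = FitConfig(
            K=2,
            tol=cfg.tol,
            max_iter=cfg.max_iter,
            n_restarts=cfg.n_restarts,
            seed=seed,
            alpha_theta=cfg.alpha_theta,
            alpha_q=cfg.alpha_q,
        )
    fit = fit_gom(sub, cfg)
    block1, block2 = steepest_fall_partition(fit.q[:, 0])
    partition = (
        [sub.sample_ids[i] for i in block1],
        [sub.sample_ids[i] for i in block2],
    )
    return SeparationResult(
        group_a=pair[0],
        group_b=pair[1],
        method="gom",
        n_sampled=len(idx),
        partition=partition,
        success=_blocks_match_labels(partition, labels),
        seed=seed,
    )


def hclust_pair_separation(
    m: CountMatrix,
    labels: dict[str, str],
    pair: tuple[str, str],
    n_sample: int = 50,
    linkage: str = "complete",
    transform: str = "logcpm",
    seed: int = 0,
) -> SeparationResult:
    """One hierarchical-clustering trial: Euclidean distance, cut at 2.

    ``transform`` selects the input representation: ``logcpm`` (default),
    ``raw`` counts, or ``standardized`` (log-CPM with per-gene z-scores).
    """
    if linkage not in ("complete", "average"):
        raise ValueError(f"linkage must be complete or average, got {linkage!r}")
    if transform not in HCLUST_TRANSFORMS:
        raise ValueError(
            f"transform must be one of {HCLUST_TRANSFORMS}, got {transform!r}"
        )
    rng = np.random.default_rng(seed)
    idx = _subsample_pair(m, labels, pair, n_sample, rng)
    sub = _subset(m, idx)
    if transform == "raw":
        x = sub.counts.astype(float)
    else:
        x = log_cpm(sub)
        if transform == "standardized":
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            x = (x - x.mean(axis=0)) / sd
    z = sch.linkage(x, method=linkage, metric="euclidean")
    assignment = sch.fcluster(z, t=2, criterion="maxclust")
    partition = (
        [sub.sample_ids[i] for i in np.flatnonzero(assignment == 1)],
        [sub.sample_ids[i] for i in np.flatnonzero(assignment != 1)],
    )
    success = (
        len(partition[0]) > 0
        and len(partition[1]) > 0
        and _blocks_match_labels(partition, labels)
    )
    return SeparationResult(
        group_a=pair[0],
        group_b=pair[1],
        method="hclust",
        n_sampled=len(idx),
        partition=partition,
        success=success,
        seed=seed,
    )


def pairwise_separation_matrix(
    m: CountMatrix,
    labels: dict[str, str],
    methods: tuple[str, ...] = ("gom", "hclust"),
    n_sample: int = 50,
    seed: int = 0,
    fit_cfg: FitConfig | None = None,
    linkage: str = "complete",
    transform: str = "logcpm",
) -> tuple[list[SeparationResult], dict[str, float]]:
    """Run one trial per unordered label pair per method.

    Per-pair seeds are derived deterministically from the global seed.
    Returns all trial results and the per-method success fraction; pairs
    that error are recorded as failures of the trial machinery and excluded
    from the denominator with a warning.
    """
    groups = sorted(set(labels.values()))
    if len(groups) < 2:
        raise ValueError("need at least two distinct labels")
    for meth in methods:
        if meth not in ("gom", "hclust"):
            raise ValueError(f"unknown method {meth!r}")
    results: list[SeparationResult] = []
    tallies = {meth: [0, 0] for meth in methods}  # successes, trials
    for j, pair in enumerate(itertools.combinations(groups, 2)):
        pair_seed = int(
            np.random.SeedSequence([seed, j]).generate_state(1, np.uint32)[0] % (2**31)
        )
        for meth in methods:
            try:
                if meth == "gom":
                    res = gom_pair_separation(
                        m, labels, pair, n_sample, pair_seed, fit_cfg
                    )
                else:
                    res = hclust_pair_separation(
                        m, labels, pair, n_sample, linkage, transform, pair_seed
                    )
            except (ValueError, RuntimeError) as e:
                warnings.warn(
                    f"pair {pair} failed for method {meth}: {e}; excluded "
                    "from the success fraction",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            results.append(res)
            tallies[meth][1] += 1
            tallies[meth][0] += int(res.success)
    fractions = {
        meth: (s / t if t else float("nan")) for meth, (s, t) in tallies.items()
    }
    return results, fractions


def aligned_membership_error(q_true: np.ndarray, q_est: np.ndarray) -> float:
    """Mean absolute membership error after optimal cluster relabelling.

    Minimum over all K! column permutations of mean |q_true - q_est|; the
    standard label-switching-invariant recovery metric. Brute force over
    permutations, practical for K <= 8.
    """
    q_true = np.asarray(q_true, dtype=float)
    q_est = np.asarray(q_est, dtype=float)
    if q_true.shape != q_est.shape:
        raise ValueError(f"shape mismatch: {q_true.shape} vs {q_est.shape}")
    k = q_true.shape[1]
    if k > 8:
        raise ValueError("brute-force permutation scan limited to K <= 8")
    best = np.inf
    for perm in itertools.permutations(range(k)):
        err = float(np.abs(q_true - q_est[:, perm]).mean())
        best = min(best, err)
    return best
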