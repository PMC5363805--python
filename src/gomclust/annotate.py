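"""Driving-gene identification via Poisson Kullback-Leibler distinctiveness.

For each cluster k the distinctiveness of gene g against another cluster l is
the KL divergence between Poisson distributions with rates θ_kg and θ_lg,

    KL_g[k, l] = θ_kg log(θ_kg / θ_lg) + θ_lg - θ_kg ,

and the cluster-level score is the worst case over competitors,

    D_g[k] = min_{l != k} KL_g[k, l] .

A gene with high D_g[k] is expressed distinctively in cluster k relative to
even the most similar other cluster — the analogue of an ancestry-informative
marker in admixture analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DrivingGeneTable",
    "poisson_kl",
    "distinctiveness",
    "top_driving_genes",
    "write_driving_gene_table",
]

_THETA_FLOOR = 1e-12


def poisson_kl(theta_kg: float, theta_lg: float) -> float:
    """KL divergence from Poisson(theta_kg) to Poisson(theta_lg).

    Non-negative, zero iff the rates are equal, and asymmetric in its
    arguments. Both rates must be strictly positive.
    """
    if theta_kg <= 0 or theta_lg <= 0:
        raise ValueError(
            f"Poisson rates must be positive, got ({theta_kg}, {theta_lg})"
        )
    return theta_kg * math.log(theta_kg / theta_lg) + theta_lg - theta_kg


@dataclass
class DrivingGeneTable:
    """Per-cluster distinctiveness scores and gene rankings.

    ``scores`` is K x G; ``rankings[k]`` lists gene ids by descending
    D_g[k], ties broken by ascending gene id for determinism.
    """

    scores: np.ndarray
    rankings: list[list[str]]
    gene_ids: list[str]
    top_n: int = 100

    @property
    def K(self) -> int:
        return self.scores.shape[0]


def distinctiveness(
    theta: np.ndarray, gene_ids: list[str] | None = None, top_n: int = 100
) -> DrivingGeneTable:
    """Compute D_g[k] for every gene and cluster from a K x G profile matrix.

    Requires K >= 2 (with one cluster there is no competitor to compare
    against). θ entries of exactly zero — possible only when the fit was
    forced to a flat profile prior — are floored at 1e-12 with a warning,
    since the KL score is undefined at zero rates.
    """
    theta = np.asarray(theta, dtype=float)
    K, G = theta.shape
    if K < 2:
        raise ValueError("distinctiveness undefined for a single cluster")
    if gene_ids is None:
        gene_ids = [f"gene_{g + 1}" for g in range(G)]
    if np.any(theta <= 0):
        warnings.warn(
            f"{int((theta <= 0).sum())} non-positive profile entries floored "
            f"at {_THETA_FLOOR} before KL scoring",
            RuntimeWarning,
            stacklevel=2,
        )
        theta = np.maximum(theta, _THETA_FLOOR)
    # kl[k, l, g] = KL(Pois(θ_kg) || Pois(θ_lg)), vectorised over the tensor.
    log_theta = np.log(theta)
    kl = (
        theta[:, None, :] * (log_theta[:, None, :] - log_theta[None, :, :])
        + theta[None, :, :]
        - theta[:, None, :]
    )
    kl[np.arange(K), np.arange(K), :] = np.inf  # exclude l == k from the min
    scores = kl.min(axis=1)
    order_key = np.argsort(gene_ids, kind="stable")
    rankings = []
    for k in range(K):
        # sort by descending score; equal scores fall back to gene-id order
        by_id = scores[k][order_key]
        idx = order_key[np.argsort(-by_id, kind="stable")]
        rankings.append([gene_ids[i] for i in idx])
    return DrivingGeneTable(scores=scores, rankings=rankings, gene_ids=list(gene_ids), top_n=top_n)


def top_driving_genes(
    table: DrivingGeneTable, k: int, n: int
) -> list[tuple[str, float]]:
    """First ``n`` genes of cluster ``k``'s ranking with their scores."""
    if not 0 <= k < table.K:
        raise IndexError(f"cluster index {k} out of range [0, {table.K})")
    if not 1 <= n <= len(table.gene_ids):
        raise ValueError(f"n must be in [1, {len(table.gene_ids)}], got {n}")
    gene_pos = {g: i for i, g in enumerate(table.gene_ids)}
    return [(g, float(table.scores[k, gene_pos[g]])) for g in table.rankings[k][:n]]


def write_driving_gene_table(table: DrivingGeneTable, path: str, n: int | None = None) -> None:
    """Export ``cluster<TAB>rank<TAB>gene_id<TAB>score`` rows for all clusters."""
    n = n if n is not None else min(table.top_n, len(table.gene_ids))
    with open(path, "w") as fh:
        fh.write("cluster\trank\tgene_id\tscore\n")
        for k in range(table.K):
            for rank, (gene, score) in enumerate(top_driving_genes(table, k, n), 1):
                fh.write(f"{k + 1}\t{rank}\t{gene}\t{score:.10g}\n")
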