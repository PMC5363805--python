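"""Synthetic count data from the GoM generative model with known truth.

Every downstream module is testable without external data by sampling the
model forward: draw K cluster profiles θ over G genes, draw per-sample
memberships q under a chosen regime, and sample each library as
Multinomial(c_n+, q_n· θ).

Profiles are heavy-tailed — a small-concentration Dirichlet base frequency
vector, so a few genes carry most of the reads, as in real RNA-seq — and
clusters are separated by a multiplicative log-normal perturbation whose
strength δ interpolates from identical profiles (δ = 0) to essentially
disjoint high-expression gene sets (δ large).

Library-size presets: ``bulk`` ≈ 1e7 reads per sample (whole-tissue
RNA-seq scale) and ``sc`` ≈ 1e4 (single-cell scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts import CountMatrix

__all__ = [
    "SimulationConfig",
    "LIBRARY_PRESETS",
    "simulate_profiles",
    "simulate_memberships",
    "simulate_gom_counts",
    "make_pair_fixture",
]

LIBRARY_PRESETS = {"bulk": 10_000_000, "sc": 10_000}

MEMBERSHIP_REGIMES = ("pure", "dirichlet", "mixed", "blockwise")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic GoM dataset.

    Parameters
    ----------
    N, G, K
        Samples, genes, clusters.
    library_size
        Reads per sample: an integer (same for all samples), a length-N
        sequence, or a preset name (``bulk`` = 1e7, ``sc`` = 1e4).
    membership_regime
        ``pure`` — every sample one-hot on a cluster (round-robin);
        ``dirichlet`` — q rows drawn from a symmetric
        Dirichlet(``dirichlet_alpha``);
        ``mixed`` — a fraction ``pure_fraction`` of samples is one-hot,
        the rest Dirichlet-admixed;
        ``blockwise`` — samples interpolate linearly between consecutive
        cluster pairs, producing the membership gradients typical of
        developmental-stage data.
    profile_separation
        δ >= 0, the standard deviation of the per-cluster log-normal
        perturbation of the shared base profile. 0 means all clusters
        identical.
    profile_shape
        Concentration of the symmetric Dirichlet base gene-frequency
        draw; small values (default 0.05) give the heavy-tailed
        expression spectrum of real libraries.
    dirichlet_alpha
        Concentration of admixed membership draws.
    pure_fraction
        Fraction of one-hot samples under the ``mixed`` regime.
    seed
        Single seed driving every draw; identical configs give
        bit-identical output.
    """

    N: int
    G: int
    K: int
    library_size: int | str | tuple = 10_000
    membership_regime: str = "mixed"
    profile_separation: float = 1.0
    profile_shape: float = 0.05
    dirichlet_alpha: float = 0.5
    pure_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.N, self.G, self.K) < 1:
            raise ValueError("N, G, K must all be >= 1")
        if self.profile_separation < 0:
            raise ValueError("profile_separation must be >= 0")
        if self.membership_regime not in MEMBERSHIP_REGIMES:
            raise ValueError(
                f"unknown membership_regime {self.membership_regime!r}; "
                f"expected one of {MEMBERSHIP_REGIMES}"
            )
        if not 0.0 <= self.pure_fraction <= 1.0:
            raise ValueError("pure_fraction must be in [0, 1]")
        self.resolve_library_sizes()  # validate eagerly

    def resolve_library_sizes(self) -> np.ndarray:
        ls = self.library_size
        if isinstance(ls, str):
            if ls not in LIBRARY_PRESETS:
                raise ValueError(
                    f"unknown library preset {ls!r}; expected one of "
                    f"{sorted(LIBRARY_PRESETS)}"
                )
            ls = LIBRARY_PRESETS[ls]
        arr = np.broadcast_to(np.asarray(ls, dtype=np.int64), (self.N,)).copy()
        if np.any(arr < 1):
            raise ValueError("library sizes must be >= 1")
        return arr


def simulate_profiles(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the K x G cluster profile matrix θ.

    A shared heavy-tailed base frequency vector is perturbed per cluster by
    exp(δ · z_kg), z_kg ~ N(0, 1), then renormalised. δ = 0 returns K
    identical rows.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    base = rng.dirichlet(np.full(cfg.G, cfg.profile_shape))
    base = np.maximum(base, 1e-12)
    base /= base.sum()
    z = rng.standard_normal((cfg.K, cfg.G))
    theta = base[None, :] * np.exp(cfg.profile_separation * z)
    return theta / theta.sum(axis=1, keepdims=True)


def simulate_memberships(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the N x K membership matrix q under the configured regime."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, k = cfg.N, cfg.K
    if cfg.membership_regime == "pure":
        q = np.zeros((n, k))
        q[np.arange(n), np.arange(n) % k] = 1.0
        return q
    if cfg.membership_regime == "dirichlet":
        return rng.dirichlet(np.full(k, cfg.dirichlet_alpha), size=n)
    if cfg.membership_regime == "mixed":
        q = rng.dirichlet(np.full(k, cfg.dirichlet_alpha), size=n)
        n_pure = int(round(cfg.pure_fraction * n))
        q[:n_pure] = 0.0
        q[np.arange(n_pure), np.arange(n_pure) % k] = 1.0
        return q
    # blockwise: linear gradients between consecutive cluster pairs
    q = np.zeros((n, k))
    if k == 1:
        q[:] = 1.0
        return q
    t = np.linspace(0.0, 1.0, n)
    seg = np.minimum((t * (k - 1)).astype(int), k - 2)
    frac = t * (k - 1) - seg
    q[np.arange(n), seg] = 1.0 - frac
    q[np.arange(n), seg + 1] = frac
    return q


def simulate_gom_counts(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Sample a count matrix from the generative model.

    Returns ``(counts, q_true, theta_true)``; row totals equal the
    configured library sizes exactly (multinomial sampling).
    """
    rng = np.random.default_rng(cfg.seed)
    theta = simulate_profiles(cfg, rng)
    q = simulate_memberships(cfg, rng)
    p = q @ theta
    libs = cfg.resolve_library_sizes()
    counts = np.empty((cfg.N, cfg.G), dtype=np.int64)
    for i in range(cfg.N):
        counts[i] = rng.multinomial(libs[i], p[i] / p[i].sum())
    m = CountMatrix(
        counts,
        [f"sample_{i + 1}" for i in range(cfg.N)],
        [f"gene_{g + 1}" for g in range(cfg.G)],
    )
    return m, q, theta


def make_pair_fixture(
    delta: float,
    n_per_group: int = 25,
    n_genes: int = 300,
    library_size: int = 10_000,
    seed: int = 0,
) -> tuple[CountMatrix, dict[str, str]]:
    """Two groups of pure samples from two profiles at separation ``delta``.

    The workhorse fixture for the pairwise separation benchmark: at
    delta = 0 the groups are statistically identical; at large delta their
    high-expression gene sets barely overlap.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    cfg = SimulationConfig(
        N=2 * n_per_group,
        G=n_genes,
        K=2,
        library_size=library_size,
        membership_regime="pure",
        profile_separation=delta,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    theta = simulate_profiles(cfg, rng)
    q = np.zeros((cfg.N, 2))
    q[:n_per_group, 0] = 1.0
    q[n_per_group:, 1] = 1.0
    p = q @ theta
    counts = np.empty((cfg.N, cfg.G), dtype=np.int64)
    for i in range(cfg.N):
        counts[i] = rng.multinomial(library_size, p[i] / p[i].sum())
    m = CountMatrix(
        counts,
        [f"sample_{i + 1}" for i in range(cfg.N)],
        [f"gene_{g + 1}" for g in range(cfg.G)],
    )
    labels = {
        sid: ("groupA" if i < n_per_group else "groupB")
        for i, sid in enumerate(m.sample_ids)
    }
    return m, labels
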