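"""MAP fitting of the grade-of-membership (GoM) model by EM.

The model: each sample n has membership proportions q_n· over K clusters and
each cluster k has an expression profile θ_k· over G genes. The counts of
sample n are Multinomial(c_n+, p_n·) with

    p_ng = sum_k q_nk θ_kg .

This is the latent Dirichlet allocation / admixture likelihood on gene counts.
Fitting maximises the posterior under independent symmetric Dirichlet priors
on the rows of q (concentration ``alpha_q``) and θ (``alpha_theta``), both
constrained >= 1 so the M-step stays closed-form on the simplex:

    E-step:  r_ngk = q_nk θ_kg / p_ng          (only where c_ng > 0)
    M-step:  q_nk  ∝ sum_g c_ng r_ngk + (alpha_q - 1)
             θ_kg  ∝ sum_n c_ng r_ngk + (alpha_theta - 1)

Plain EM (no quasi-Newton acceleration) with a monotone log-posterior
guarantee; several random restarts are run and the fit with the highest data
log-likelihood is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, xlogy

from .counts import CountMatrix

__all__ = [
    "FitConfig",
    "GoMFit",
    "compute_p",
    "log_likelihood",
    "em_step",
    "fit_gom",
]


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters for MAP-EM fitting.

    Parameters
    ----------
    K
        Number of clusters (set by the analyst).
    tol
        Convergence threshold on the absolute change in log-posterior
        between EM iterations.
    max_iter
        Cap on EM iterations per restart.
    n_restarts
        Independent random restarts; the highest-likelihood run is kept.
    seed
        Base seed; restart r uses ``seed + r``.
    alpha_theta
        Symmetric Dirichlet concentration on each θ row. The default 1.1
        keeps every θ_kg strictly positive, which the Poisson-KL
        driving-gene score requires.
    alpha_q
        Symmetric Dirichlet concentration on each q row. The default 1 is
        a flat prior (maximum likelihood for the memberships).
    """

    K: int
    tol: float = 1e-4
    max_iter: int = 1000
    n_restarts: int = 3
    seed: int = 0
    alpha_theta: float = 1.1
    alpha_q: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("max_iter and n_restarts must be >= 1")
        if self.alpha_theta < 1 or self.alpha_q < 1:
            raise ValueError(
                "Dirichlet concentrations must be >= 1 to keep the M-step "
                "closed-form on the simplex"
            )


@dataclass
class GoMFit:
    """A fitted GoM model.

    ``q`` is N x K (rows sum to 1), ``theta`` is K x G (rows sum to 1).
    ``log_posterior_trace`` holds one value per EM iteration and is
    non-decreasing up to numerical tolerance.
    """

    q: np.ndarray
    theta: np.ndarray
    log_likelihood: float = np.nan
    log_posterior_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    restart_index: int = 0
    seed_used: int = 0
    sample_ids: list[str] | None = None
    gene_ids: list[str] | None = None

    @property
    def K(self) -> int:
        return self.q.shape[1]


def compute_p(fit: GoMFit) -> np.ndarray:
    """Per-sample multinomial probabilities p = q · θ (rows sum to 1)."""
    q, theta = np.asarray(fit.q), np.asarray(fit.theta)
    if q.shape[1] != theta.shape[0]:
        raise ValueError(
            f"q has {q.shape[1]} clusters but theta has {theta.shape[0]}"
        )
    return q @ theta


def log_likelihood(
    m: CountMatrix, fit: GoMFit, include_multinomial_coefficient: bool = False
) -> float:
    """Multinomial data log-likelihood of the counts under the fit.

    Returns sum_{n,g} c_ng log p_ng; with the flag set, adds the
    parameter-free multinomial coefficient
    sum_n [log c_n+! - sum_g log c_ng!]. A zero p_ng under a positive count
    yields -inf with a warning rather than an exception.
    """
    p = compute_p(fit)
    if p.shape != m.counts.shape:
        raise ValueError(
            f"fit predicts shape {p.shape} but counts have {m.counts.shape}"
        )
    c = m.counts
    if np.any((c > 0) & (p <= 0)):
        warnings.warn(
            "count observed where the fit assigns zero probability; "
            "log-likelihood is -inf",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("-inf")
    ll = float(xlogy(c, p).sum())
    if include_multinomial_coefficient:
        ll += float(gammaln(m.row_totals + 1).sum() - gammaln(c + 1).sum())
    return ll


def _log_prior(q: np.ndarray, theta: np.ndarray, cfg: FitConfig) -> float:
    # Unnormalised Dirichlet log-densities; constants drop out of the trace.
    lp = 0.0
    if cfg.alpha_q > 1:
        lp += (cfg.alpha_q - 1) * float(np.log(np.maximum(q, 1e-300)).sum())
    if cfg.alpha_theta > 1:
        lp += (cfg.alpha_theta - 1) * float(np.log(np.maximum(theta, 1e-300)).sum())
    return lp


def log_posterior(m: CountMatrix, fit: GoMFit, cfg: FitConfig) -> float:
    """Data log-likelihood plus Dirichlet log-prior terms (unnormalised)."""
    return log_likelihood(m, fit) + _log_prior(fit.q, fit.theta, cfg)


def _normalize_rows(x: np.ndarray, what: str) -> np.ndarray:
    s = x.sum(axis=1, keepdims=True)
    bad = (s <= 0) | ~np.isfinite(s)
    if np.any(bad):
        warnings.warn(
            f"numerical underflow produced {int(bad.sum())} zero-mass "
            f"{what} row(s); reset to uniform",
            RuntimeWarning,
            stacklevel=3,
        )
        x = x.copy()
        x[bad.ravel()] = 1.0
        s = x.sum(axis=1, keepdims=True)
    return x / s


def _em_update(
    c: np.ndarray, q: np.ndarray, theta: np.ndarray, cfg: FitConfig
) -> tuple[np.ndarray, np.ndarray]:
    """One full E+M sweep. Works on the dense count array.

    Using r_ngk = q_nk θ_kg / p_ng, the expected count sums collapse to
    matrix products with the ratio matrix S = C / P (taken as 0 where
    c_ng = 0, so zero counts contribute nothing):

        sum_g c_ng r_ngk = q_nk (S θᵀ)_nk
        sum_n c_ng r_ngk = θ_kg (qᵀ S)_kg
    """
    p = q @ theta
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(c > 0, c / p, 0.0)
    s = np.nan_to_num(s, nan=0.0, posinf=0.0)
    q_new = q * (s @ theta.T) + (cfg.alpha_q - 1.0)
    theta_new = theta * (q.T @ s) + (cfg.alpha_theta - 1.0)
    return (
        _normalize_rows(q_new, "membership"),
        _normalize_rows(theta_new, "profile"),
    )


def em_step(m: CountMatrix, fit: GoMFit, cfg: FitConfig) -> GoMFit:
    """Apply one EM iteration, returning a new fit.

    The log-posterior does not decrease beyond 1e-8 relative tolerance.
    """
    q, theta = _em_update(m.counts.astype(float), fit.q, fit.theta, cfg)
    new = GoMFit(
        q=q,
        theta=theta,
        log_posterior_trace=list(fit.log_posterior_trace),
        n_iter=fit.n_iter + 1,
        restart_index=fit.restart_index,
        seed_used=fit.seed_used,
        sample_ids=fit.sample_ids,
        gene_ids=fit.gene_ids,
    )
    new.log_likelihood = log_likelihood(m, new)
    new.log_posterior_trace.append(new.log_likelihood + _log_prior(q, theta, cfg))
    return new


def _init_params(
    m: CountMatrix, cfg: FitConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n, g = m.counts.shape
    q0 = rng.dirichlet(np.ones(cfg.K), size=n)
    # θ starts at the pooled gene frequencies, perturbed per cluster so
    # restarts explore different modes.
    base = m.counts.sum(axis=0).astype(float)
    base = (base + 1.0) / (base.sum() + g)
    noise = rng.dirichlet(np.ones(g), size=cfg.K)
    theta0 = 0.8 * base[None, :] + 0.2 * noise
    theta0 /= theta0.sum(axis=1, keepdims=True)
    return q0, theta0


def _run_em(m: CountMatrix, cfg: FitConfig, restart: int) -> GoMFit:
    seed = cfg.seed + restart
    rng = np.random.default_rng(seed)
    q, theta = _init_params(m, cfg, rng)
    c = m.counts.astype(float)
    fit = GoMFit(
        q=q,
        theta=theta,
        restart_index=restart,
        seed_used=seed,
        sample_ids=list(m.sample_ids),
        gene_ids=list(m.gene_ids),
    )
    fit.log_likelihood = log_likelihood(m, fit)
    prev = fit.log_likelihood + _log_prior(q, theta, cfg)
    fit.log_posterior_trace = [prev]
    for _ in range(cfg.max_iter):
        fit = em_step(m, fit, cfg)
        cur = fit.log_posterior_trace[-1]
        if abs(cur - prev) < cfg.tol:
            fit.converged = True
            break
        prev = cur
    return fit


def fit_gom(m: CountMatrix, cfg: FitConfig) -> GoMFit:
    """Fit the GoM model by multi-restart MAP-EM.

    Runs ``cfg.n_restarts`` independent EM runs from seeded random
    initialisations and returns the run with the highest data
    log-likelihood (the prior term is excluded from the selection — it is
    constant across restarts in expectation and the likelihood is the
    quantity of scientific interest).
    """
    if m.n_genes < cfg.K:
        warnings.warn(
            f"K={cfg.K} exceeds the number of genes ({m.n_genes}); the model "
            "is over-parameterised",
            UserWarning,
            stacklevel=2,
        )
    if np.any(m.row_totals == 0):
        raise ValueError("samples with zero total reads cannot be fit")
    best: GoMFit | None = None
    for r in range(cfg.n_restarts):
        fit = _run_em(m, cfg, r)
        if not np.isfinite(fit.log_likelihood):
            continue
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if best is None:
        raise RuntimeError("all restarts failed numerically")
    return best
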