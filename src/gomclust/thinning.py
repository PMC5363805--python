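"""Binomial thinning: simulate shallower sequencing from observed counts.

Each count c_ng is replaced by t_ng ~ Binomial(c_ng, p_thin) independently,
mimicking an experiment that sequenced each read with probability p_thin.
Thinning by 100x (p_thin = 0.01) takes a bulk library of ~1e7 reads down to
the ~1e5 scale, and 10000x to the depth of a typical single-cell library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counts import CountMatrix

__all__ = ["ThinningConfig", "thin_counts"]


@dataclass(frozen=True)
class ThinningConfig:
    """Retention probability and seed for a thinning run."""

    p_thin: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_thin <= 1.0:
            raise ValueError(f"p_thin must be in [0, 1], got {self.p_thin}")


def thin_counts(m: CountMatrix, cfg: ThinningConfig) -> CountMatrix:
    """Thin every entry of a count matrix binomially.

    Draws are consumed in fixed row-major order over the *nonzero* entries
    only; zero entries never touch the random stream. This is a stability
    contract: the thinned output for a given seed does not depend on how
    many structural zeros surround the data.
    """
    rng = np.random.default_rng(cfg.seed)
    flat = m.counts.ravel()  # row-major view
    nz = np.flatnonzero(flat)
    thinned = np.zeros_like(flat)
    if nz.size:
        thinned[nz] = rng.binomial(flat[nz], cfg.p_thin)
    return CountMatrix(
        thinned.reshape(m.counts.shape), list(m.sample_ids), list(m.gene_ids)
    )
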