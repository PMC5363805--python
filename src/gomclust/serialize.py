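"""On-disk representation of fitted models.

A fit is saved as a directory containing ``q.tsv`` and ``theta.tsv``
(labelled rows and columns, full double precision) plus ``fit.json`` with
the configuration, seeds, convergence trace and flags — everything needed
to reproduce or audit the run.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from .fit import FitConfig, GoMFit

__all__ = ["save_fit", "load_fit"]


def save_fit(fit: GoMFit, directory: str, cfg: FitConfig | None = None) -> None:
    os.makedirs(directory, exist_ok=True)
    sample_ids = fit.sample_ids or [f"sample_{i + 1}" for i in range(fit.q.shape[0])]
    gene_ids = fit.gene_ids or [f"gene_{g + 1}" for g in range(fit.theta.shape[1])]
    clusters = [f"cluster_{k + 1}" for k in range(fit.K)]
    pd.DataFrame(fit.q, index=pd.Index(sample_ids, name="sample_id"), columns=clusters).to_csv(
        os.path.join(directory, "q.tsv"), sep="\t", float_format="%.17g"
    )
    pd.DataFrame(fit.theta, index=pd.Index(clusters, name="cluster"), columns=gene_ids).to_csv(
        os.path.join(directory, "theta.tsv"), sep="\t", float_format="%.17g"
    )
    meta = {
        "log_likelihood": fit.log_likelihood,
        "log_posterior_trace": list(map(float, fit.log_posterior_trace)),
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "restart_index": fit.restart_index,
        "seed_used": fit.seed_used,
        "config": asdict(cfg) if cfg is not None else None,
    }
    with open(os.path.join(directory, "fit.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_fit(directory: str) -> GoMFit:
    q_df = pd.read_csv(os.path.join(directory, "q.tsv"), sep="\t", index_col=0)
    theta_df = pd.read_csv(os.path.join(directory, "theta.tsv"), sep="\t", index_col=0)
    with open(os.path.join(directory, "fit.json")) as fh:
        meta = json.load(fh)
    return GoMFit(
        q=q_df.to_numpy(dtype=float),
        theta=theta_df.to_numpy(dtype=float),
        log_likelihood=meta["log_likelihood"],
        log_posterior_trace=list(meta["log_posterior_trace"]),
        converged=meta["converged"],
        n_iter=meta["n_iter"],
        restart_index=meta["restart_index"],
        seed_used=meta["seed_used"],
        sample_ids=[str(s) for s in q_df.index],
        gene_ids=[str(g) for g in theta_df.columns],
    )
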