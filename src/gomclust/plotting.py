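"""Structure plots: stacked membership bar charts grouped by sample label.

Each sample is one horizontal bar of unit length, partitioned into K
coloured segments proportional to its membership in each cluster. Samples
sharing a label occupy a contiguous block; within each block samples are
sorted by their membership in the block's dominant cluster, descending, so
each group shows a smooth colour gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .fit import GoMFit

__all__ = [
    "PALETTE",
    "StructureOrdering",
    "structure_order",
    "structure_plot",
    "export_membership_coordinates",
    "read_membership_coordinates",
]

# Fixed 20-colour qualitative palette (matplotlib tab20 hex values).
PALETTE = [
    "#1f77b4", "#aec7e8", "#ff7f0e", "#ffbb78", "#2ca02c",
    "#98df8a", "#d62728", "#ff9896", "#9467bd", "#c5b0d5",
    "#8c564b", "#c49c94", "#e377c2", "#f7b6d2", "#7f7f7f",
    "#c7c7c7", "#bcbd22", "#dbdb8d", "#17becf", "#9edae5",
]


@dataclass
class StructureOrdering:
    """Display order for a Structure plot."""

    ordered_sample_ids: list[str]
    group_boundaries: list[int]
    group_names: list[str]
    palette: dict[int, str]


def structure_order(
    fit: GoMFit,
    labels: dict[str, str],
    group_order: list[str] | None = None,
    within_group: str = "dominant",
) -> StructureOrdering:
    """Order samples for plotting: contiguous label blocks, sorted within.

    ``within_group`` selects the in-block rule: ``dominant`` (default)
    sorts by descending membership in the cluster with the highest mean
    membership in that group; ``none`` keeps input order. Sorting is
    stable, so tied samples keep their input order.
    """
    if fit.sample_ids is None:
        raise ValueError("fit carries no sample ids")
    if fit.K > len(PALETTE):
        raise ValueError(
            f"built-in palette supports up to {len(PALETTE)} clusters "
            f"(K={fit.K}); supply a custom palette"
        )
    missing = [s for s in fit.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    present = sorted({labels[s] for s in fit.sample_ids})
    if group_order is None:
        group_order = present
    else:
        unknown = [g for g in group_order if g not in present]
        if unknown:
            raise ValueError(f"unknown label(s) in group_order: {unknown}")
    pos = {s: i for i, s in enumerate(fit.sample_ids)}
    ordered: list[str] = []
    boundaries: list[int] = []
    names: list[str] = []
    for grp in group_order:
        members = [s for s in fit.sample_ids if labels[s] == grp]
        if not members:
            continue
        if within_group == "dominant":
            sub_q = fit.q[[pos[s] for s in members]]
            dom = int(np.argmax(sub_q.mean(axis=0)))
            key = -sub_q[:, dom]
            order = np.argsort(key, kind="stable")
            members = [members[i] for i in order]
        elif within_group != "none":
            raise ValueError(f"unknown within_group rule {within_group!r}")
        boundaries.append(len(ordered))
        names.append(grp)
        ordered.extend(members)
    return StructureOrdering(
        ordered_sample_ids=ordered,
        group_boundaries=boundaries,
        group_names=names,
        palette={k: PALETTE[k] for k in range(fit.K)},
    )


def structure_plot(
    fit: GoMFit,
    ordering: StructureOrdering,
    output: str,
    format: str = "svg",
    title: str | None = None,
) -> None:
    """Render the stacked-bar Structure plot to ``output``.

    SVG output is byte-deterministic for identical inputs (fixed hash salt,
    no embedded timestamp).
    """
    if format not in ("svg", "png", "pdf"):
        raise ValueError(f"format must be svg, png or pdf, got {format!r}")
    if fit.sample_ids is None:
        raise ValueError("fit carries no sample ids")
    if set(ordering.ordered_sample_ids) != set(fit.sample_ids):
        raise ValueError("ordering is not a permutation of the fit's samples")
    pos = {s: i for i, s in enumerate(fit.sample_ids)}
    q = fit.q[[pos[s] for s in ordering.ordered_sample_ids]]
    n, k = q.shape
    with plt.rc_context({"svg.hashsalt": "gomclust"}):
        fig, ax = plt.subplots(figsize=(6, max(2.0, 0.035 * n + 1.0)))
        left = np.zeros(n)
        y = np.arange(n)[::-1]  # first sample on top
        for j in range(k):
            ax.barh(
                y,
                q[:, j],
                left=left,
                height=1.0,
                color=ordering.palette[j],
                linewidth=0,
                label=f"cluster {j + 1}",
            )
            left += q[:, j]
        bounds = ordering.group_boundaries + [n]
        for name, start, end in zip(ordering.group_names, bounds[:-1], bounds[1:]):
            ax.axhline(n - start - 0.5, color="black", linewidth=0.6)
            ax.text(
                1.01,
                n - (start + end) / 2 - 0.5,
                name,
                va="center",
                fontsize=8,
                transform=ax.get_yaxis_transform(),
            )
        ax.set_xlim(0, 1)
        ax.set_ylim(-0.5, n - 0.5)
        ax.set_yticks([])
        ax.set_xlabel("membership proportion")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        metadata = {"Date": None} if format == "svg" else None
        fig.savefig(output, format=format, metadata=metadata)
        plt.close(fig)


def export_membership_coordinates(fit: GoMFit, path: str) -> None:
    """Write q as TSV (``sample_id`` + ``cluster_1..cluster_K`` columns).

    Intended as input to external 2-D embedding tools (t-SNE and friends),
    which visualise samples with similar membership profiles near each
    other.
    """
    ids = fit.sample_ids or [f"sample_{i + 1}" for i in range(fit.q.shape[0])]
    df = pd.DataFrame(
        fit.q, index=pd.Index(ids, name="sample_id"),
        columns=[f"cluster_{k + 1}" for k in range(fit.K)],
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_membership_coordinates(path: str) -> pd.DataFrame:
    """Read back a membership table written by :func:`export_membership_coordinates`."""
    return pd.read_csv(path, sep="\t", index_col=0)
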