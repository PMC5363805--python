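"""Count-matrix container, I/O, filtering, and log-CPM transform.

The central object is :class:`CountMatrix`, an N samples x G genes table of
non-negative integer read counts with unique sample and gene identifiers.
Counts are stored as integers and validated on construction: the multinomial
model downstream is defined on integer counts, so non-integer input is
rejected rather than truncated.

Supported on-disk formats:

* dense TSV/CSV — first row gene ids, first column sample ids,
  samples x genes orientation;
* sparse Matrix Market coordinate integer format (1-based indices,
  header required) with ``genes.tsv`` / ``samples.tsv`` sidecars
  (one identifier per line).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

_INT_TOL = 1e-9


class CountValidationError(ValueError):
    """Raised when a count matrix violates the model's requirements."""


@dataclass
class CountMatrix:
    """N x G table of read counts with sample/gene labels.

    Attributes
    ----------
    counts
        Dense ``(N, G)`` integer array, every entry >= 0.
    sample_ids
        N unique sample identifiers (rows).
    gene_ids
        G unique gene identifiers (columns).
    row_totals
        Per-sample total read counts (library sizes), recomputed on
        construction.
    """

    counts: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    row_totals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise CountValidationError(f"counts must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.all(np.abs(arr - rounded) <= _INT_TOL):
                bad = np.argwhere(np.abs(arr - rounded) > _INT_TOL)[0]
                raise CountValidationError(
                    f"non-integer count at sample {bad[0]}, gene {bad[1]}: "
                    f"{arr[bad[0], bad[1]]!r}"
                )
            arr = rounded.astype(np.int64)
        else:
            arr = arr.astype(np.int64, copy=False)
        if np.any(arr < 0):
            bad = np.argwhere(arr < 0)[0]
            raise CountValidationError(
                f"negative count at sample {bad[0]}, gene {bad[1]}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, g = arr.shape
        if len(self.sample_ids) != n:
            raise CountValidationError(
                f"{len(self.sample_ids)} sample ids for {n} rows"
            )
        if len(self.gene_ids) != g:
            raise CountValidationError(f"{len(self.gene_ids)} gene ids for {g} columns")
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise CountValidationError(f"duplicate {name} id: {dup!r}")
        self.counts = arr
        self.row_totals = arr.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.gene_ids == other.gene_ids
            and np.array_equal(self.counts, other.counts)
        )


def _check_positive_totals(m: CountMatrix) -> None:
    zero = np.flatnonzero(m.row_totals == 0)
    if zero.size:
        names = ", ".join(m.sample_ids[i] for i in zero[:5])
        raise CountValidationError(
            f"sample(s) with zero total reads: {names}; the multinomial model "
            "is undefined for empty samples — remove them before analysis"
        )


FORMATS = ("dense-tsv", "dense-csv", "mtx-triplet")


def read_counts(path: str, format: str = "dense-tsv") -> CountMatrix:
    """Read a count matrix from disk.

    Parameters
    ----------
    path
        File to read. For ``mtx-triplet`` this is the ``.mtx`` file and
        ``genes.tsv`` / ``samples.tsv`` sidecars must sit alongside it.
    format
        One of ``dense-tsv``, ``dense-csv``, ``mtx-triplet``.

    Samples with zero total reads are rejected with an error naming them.
    """
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format in ("dense-tsv", "dense-csv"):
        sep = "\t" if format == "dense-tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as e:
            raise CountValidationError(f"malformed file {path}: {e}") from e
        m = CountMatrix(
            df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns]
        )
    else:
        d = os.path.dirname(os.path.abspath(path))
        genes_path = os.path.join(d, "genes.tsv")
        samples_path = os.path.join(d, "samples.tsv")
        for side in (genes_path, samples_path):
            if not os.path.exists(side):
                raise FileNotFoundError(
                    f"mtx-triplet sidecar missing: {side} (expected next to {path})"
                )
        try:
            mat = scipy.io.mmread(path)
        except ValueError as e:
            raise CountValidationError(f"malformed Matrix Market file {path}: {e}") from e
        gene_ids = _read_id_list(genes_path)
        sample_ids = _read_id_list(samples_path)
        dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        m = CountMatrix(dense, sample_ids, gene_ids)
    _check_positive_totals(m)
    return m


def _read_id_list(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def write_counts(m: CountMatrix, path: str, format: str = "dense-tsv") -> None:
    """Write a count matrix in any of the supported formats (round-trip safe)."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if format in ("dense-tsv", "dense-csv"):
        sep = "\t" if format == "dense-tsv" else ","
        df = pd.DataFrame(m.counts, index=m.sample_ids, columns=m.gene_ids)
        df.to_csv(path, sep=sep)
    else:
        d = os.path.dirname(os.path.abspath(path))
        os.makedirs(d, exist_ok=True)
        sp = scipy.sparse.coo_matrix(m.counts)
        scipy.io.mmwrite(path, sp, field="integer")
        with open(os.path.join(d, "genes.tsv"), "w") as fh:
            fh.write("\n".join(m.gene_ids) + "\n")
        with open(os.path.join(d, "samples.tsv"), "w") as fh:
            fh.write("\n".join(m.sample_ids) + "\n")


def read_labels(path: str, m: CountMatrix | None = None) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>label`` file (header optional).

    If ``m`` is given, every sample id in the file must exist in ``m``.
    """
    labels: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CountValidationError(
                    f"malformed label file {path} at line {i + 1}: expected 2 "
                    f"tab-separated columns, got {len(parts)}"
                )
            sid, lab = parts
            if i == 0 and sid.lower() in ("sample_id", "sample"):
                continue
            labels[sid] = lab
    if m is not None:
        known = set(m.sample_ids)
        unknown = [s for s in labels if s not in known]
        if unknown:
            raise CountValidationError(
                f"label file references unknown samples: {unknown[:5]}"
            )
    return labels


def write_labels(labels: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


def filter_genes(
    m: CountMatrix, min_total: int = 0, min_samples_expressed: int = 0
) -> CountMatrix:
    """Keep genes with column total >= ``min_total`` and a nonzero count in
    at least ``min_samples_expressed`` samples.

    A generic minimum-expression filter; idempotent for fixed thresholds.
    """
    if min_total < 0 or min_samples_expressed < 0:
        raise ValueError("thresholds must be non-negative")
    col_totals = m.counts.sum(axis=0)
    n_expressed = (m.counts > 0).sum(axis=0)
    keep = (col_totals >= min_total) & (n_expressed >= min_samples_expressed)
    n_removed = int((~keep).sum())
    if not keep.any():
        raise CountValidationError(
            "gene filter removed every gene; reduce min_total or "
            "min_samples_expressed"
        )
    if n_removed:
        logger.info("filter_genes removed %d of %d genes", n_removed, m.n_genes)
    return CountMatrix(
        m.counts[:, keep],
        list(m.sample_ids),
        [g for g, k in zip(m.gene_ids, keep) if k],
    )


def log_cpm(m: CountMatrix) -> np.ndarray:
    """log2(1 + counts-per-million) matrix, removing library-size effects.

    Used as input to hierarchical clustering and external embeddings; a zero
    count maps to exactly 0.
    """
    _check_positive_totals(m)
    cpm = 1e6 * m.counts / m.row_totals[:, None]
    return np.log2(1.0 + cpm)
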