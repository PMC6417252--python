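"""Expression-matrix ingestion, normalization, binarization and aggregation.

Microarray expression matrices (genes x samples) for the non-complex nodes
are normalized per dataset, thresholded per gene into binary
activation/inhibition calls, and row-concatenated into one composite binary
dataset.  Complex-node columns are created as missing; they are filled later
by rule-based synthesis (:mod:`wrkybn.synthesis`), never imputed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import COMPLEX_NODES, BinaryDataset

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "normalize",
    "binarize",
    "aggregate",
]

NON_COMPLEX_NODES = ("A", "B", "F", "H")


@dataclass
class ExpressionMatrix:
    """Continuous expression values, genes (rows) x samples (columns)."""

    frame: pd.DataFrame
    tag: str = ""
    normalization: str = "raw"

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        vals = self.frame.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            i, j = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.frame.index[i]!r}, "
                f"sample {self.frame.columns[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_samples(self) -> int:
        return self.frame.shape[1]


def read_expression(path, format: str | None = None, tag: str = "") -> ExpressionMatrix:
    """Read a genes x samples matrix from CSV/TSV.

    First column holds gene ids, header row sample ids.  Non-numeric cells
    (including "NA") raise a parse error naming the offending cell.
    """
    if format is None:
        format = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    sep = {"csv": ",", "tsv": "\t"}[format]
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    frame = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = raw.index[bad.argmax()]
            raise ValueError(
                f"non-numeric cell {raw[col][bad].iloc[0]!r} at gene {gene!r}, "
                f"sample {col!r} in {path}"
            )
        frame[col] = converted.to_numpy()
    m = ExpressionMatrix(frame, tag=tag or str(path))
    return m


def normalize(m: ExpressionMatrix, method: str = "zscore") -> ExpressionMatrix:
    """Per-gene normalization within one dataset.

    ``zscore`` centres and scales each gene; a zero-variance gene is centred
    only, with a warning.  ``minmax`` rescales each gene to [0, 1].
    ``none`` is the identity.
    """
    if m.frame.empty:
        raise ValueError("cannot normalize an empty expression matrix")
    f = m.frame
    if method == "none":
        out = f.copy()
    elif method == "zscore":
        mu = f.mean(axis=1)
        sd = f.std(axis=1, ddof=0)
        flat = sd == 0
        if flat.any():
            warnings.warn(
                f"zero-variance genes centred only: {list(f.index[flat])}",
                stacklevel=2,
            )
        sd = sd.where(~flat, 1.0)
        out = f.sub(mu, axis=0).div(sd, axis=0)
    elif method == "minmax":
        lo, hi = f.min(axis=1), f.max(axis=1)
        span = (hi - lo).where(hi > lo, 1.0)
        out = f.sub(lo, axis=0).div(span, axis=0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return ExpressionMatrix(out, tag=m.tag, normalization=method)


def binarize(
    m: ExpressionMatrix,
    threshold_stat: str = "mean",
    node_map: dict[str, str] | None = None,
) -> BinaryDataset:
    """Threshold each gene at its own mean or median: strictly above -> 1,
    at or below -> 0 (ties map to 0, deterministically).

    ``node_map`` renames gene/probe ids to network node ids; unmapped genes
    keep their own id.  Output rows are samples (observations), columns are
    nodes, tagged ``real``.
    """
    if threshold_stat == "mean":
        thr = m.frame.mean(axis=1)
    elif threshold_stat == "median":
        thr = m.frame.median(axis=1)
    else:
        raise ValueError(f"unknown threshold statistic {threshold_stat!r}")
    binary = m.frame.gt(thr, axis=0).astype(float)
    mat = binary.T  # observations x genes
    if node_map:
        missing = [g for g in node_map if g not in mat.columns]
        if missing:
            raise ValueError(f"node_map genes absent from matrix: {missing}")
        mat = mat.rename(columns=node_map)
    mat = mat[sorted(mat.columns)].reset_index(drop=True)
    return BinaryDataset(mat, {c: "real" for c in mat.columns})


def aggregate(
    datasets: list[BinaryDataset],
    required: tuple[str, ...] = NON_COMPLEX_NODES,
    add_complex: tuple[str, ...] = COMPLEX_NODES,
) -> BinaryDataset:
    """Row-concatenate binarized datasets into one composite.

    Every input must carry the required (non-complex) node columns; columns
    are aligned by name, so input column order is irrelevant.  Complex-node
    columns are created as missing for later synthesis.
    """
    if not datasets:
        raise ValueError("no datasets to aggregate")
    for i, d in enumerate(datasets):
        missing = [c for c in required if c not in d.frame.columns]
        if missing:
            raise ValueError(f"dataset {i} is missing node columns {missing}")
    frames = [d.frame[list(required)] for d in datasets]
    composite = pd.concat(frames, ignore_index=True)
    for c in add_complex:
        composite[c] = np.nan
    composite = composite[sorted(composite.columns)]
    prov = {c: "real" for c in required}
    prov.update({c: "missing" for c in add_complex})
    return BinaryDataset(composite, prov)
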