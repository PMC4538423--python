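"""Differential-coexpression thresholding: two correlation matrices in, one
binary graph out.

Three edge rules are supported, each comparing a gene pair's correlation
between a normal-condition matrix ``C_N`` and a disease-condition matrix
``C_D``:

* ``gain``    — edge iff ``C_N(i,j) >= T1`` and ``C_D(i,j) <= T2``
                (coexpressed in normal, lost in disease);
* ``loss``    — the mirror: edge iff ``C_N(i,j) <= T1`` and ``C_D(i,j) >= T2``;
* ``absdiff`` — edge iff ``|C_N(i,j) - C_D(i,j)| >= T3`` and
                ``|C_N(i,j)| >= |C_D(i,j)|``; the difference is taken on
                signed correlations, so a reversal such as +0.9 -> -0.7
                (difference 1.6) qualifies.

In gain/loss modes correlations are by default taken as absolute values.
Pre-filtering helpers remove isolated genes and prune the lowest-degree
fraction of the graph before module detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bicor import CorrelationMatrix, _check_ids

__all__ = [
    "ThresholdConfig",
    "BinaryAdjacency",
    "binarize",
    "binarize_gain",
    "binarize_loss",
    "binarize_absdiff",
    "remove_isolated",
    "filter_low_degree",
    "graph_density",
]

_MODES = ("gain", "loss", "absdiff")


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds for turning a pair of correlation matrices into a graph.

    ``t1``/``t2`` apply in gain and loss modes, ``t3`` only in absdiff mode.
    ``use_absolute_correlation`` (default True) makes gain/loss compare
    absolute correlations; absdiff always differences signed values and
    compares absolute magnitudes, as its two conditions require.
    """

    mode: str = "gain"
    t1: float = 0.8
    t2: float = 0.4
    t3: float = 1.3
    use_absolute_correlation: bool = True

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not (0.0 <= self.t1 <= 1.0):
            raise ValueError(f"t1 must be in [0, 1], got {self.t1}")
        if not (0.0 <= self.t2 <= 1.0):
            raise ValueError(f"t2 must be in [0, 1], got {self.t2}")
        if not (0.0 <= self.t3 <= 2.0):
            raise ValueError(f"t3 must be in [0, 2], got {self.t3}")


@dataclass
class BinaryAdjacency:
    """Symmetric 0/1 gene-by-gene adjacency matrix with zero diagonal."""

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("adjacency matrix must be square")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.gene_ids = list(self.gene_ids)
        _check_ids(self.gene_ids, "gene_ids", n)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.values.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.values.sum(axis=0).astype(int)

    def subset(self, keep: np.ndarray) -> "BinaryAdjacency":
        keep = np.asarray(keep)
        ids = [g for g, f in zip(self.gene_ids, keep) if f] if keep.dtype == bool else [
            self.gene_ids[i] for i in keep
        ]
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return BinaryAdjacency(values=self.values[np.ix_(idx, idx)], gene_ids=ids)


def _check_matching(c_normal: CorrelationMatrix, c_disease: CorrelationMatrix) -> None:
    if c_normal.gene_ids != c_disease.gene_ids:
        raise ValueError("normal and disease correlation matrices must share the same gene set and order")


def _finish(edge: np.ndarray, gene_ids: list[str]) -> BinaryAdjacency:
    edge = edge & edge.T
    np.fill_diagonal(edge, False)
    return BinaryAdjacency(values=edge.astype(np.uint8), gene_ids=list(gene_ids))


def binarize_gain(
    c_normal: CorrelationMatrix, c_disease: CorrelationMatrix, cfg: ThresholdConfig
) -> BinaryAdjacency:
    """Edges for pairs coexpressed in normal (>= T1) but not in disease (<= T2)."""
    _check_matching(c_normal, c_disease)
    if cfg.mode != "gain":
        raise ValueError(f"binarize_gain requires mode 'gain', got {cfg.mode!r}")
    cn, cd = c_normal.values, c_disease.values
    if cfg.use_absolute_correlation:
        cn, cd = np.abs(cn), np.abs(cd)
    return _finish((cn >= cfg.t1) & (cd <= cfg.t2), c_normal.gene_ids)


def binarize_loss(
    c_normal: CorrelationMatrix, c_disease: CorrelationMatrix, cfg: ThresholdConfig
) -> BinaryAdjacency:
    """Mirrored rule: low correlation in normal (<= T1), high in disease (>= T2)."""
    _check_matching(c_normal, c_disease)
    if cfg.mode != "loss":
        raise ValueError(f"binarize_loss requires mode 'loss', got {cfg.mode!r}")
    cn, cd = c_normal.values, c_disease.values
    if cfg.use_absolute_correlation:
        cn, cd = np.abs(cn), np.abs(cd)
    return _finish((cn <= cfg.t1) & (cd >= cfg.t2), c_normal.gene_ids)


def binarize_absdiff(
    c_normal: CorrelationMatrix, c_disease: CorrelationMatrix, cfg: ThresholdConfig
) -> BinaryAdjacency:
    """Edges where the signed correlation changes by at least T3 with
    non-increasing magnitude (captures coexpression reversals)."""
    _check_matching(c_normal, c_disease)
    if cfg.mode != "absdiff":
        raise ValueError(f"binarize_absdiff requires mode 'absdiff', got {cfg.mode!r}")
    cn, cd = c_normal.values, c_disease.values
    edge = (np.abs(cn - cd) >= cfg.t3) & (np.abs(cn) >= np.abs(cd))
    return _finish(edge, c_normal.gene_ids)


_BINARIZERS = {"gain": binarize_gain, "loss": binarize_loss, "absdiff": binarize_absdiff}


def binarize(
    c_normal: CorrelationMatrix, c_disease: CorrelationMatrix, cfg: ThresholdConfig
) -> BinaryAdjacency:
    """Dispatch to the edge rule selected by ``cfg.mode``."""
    return _BINARIZERS[cfg.mode](c_normal, c_disease, cfg)


def remove_isolated(a: BinaryAdjacency) -> BinaryAdjacency:
    """Drop genes of degree zero (outliers in the graph sense). Idempotent."""
    return a.subset(a.degrees() > 0)


def filter_low_degree(a: BinaryAdjacency, fraction: float) -> BinaryAdjacency:
    """Remove the lowest-degree ``floor(fraction * n)`` genes in one pass.

    Degrees are computed once, before any removal.  Ties are broken by
    gene-id order (stable sort on (degree, gene_id)), so the result is
    deterministic.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    n = a.n_genes
    n_drop = math.floor(fraction * n)
    if n_drop == 0:
        return a.subset(np.arange(n))
    deg = a.degrees()
    order = sorted(range(n), key=lambda i: (deg[i], a.gene_ids[i]))
    keep = np.ones(n, dtype=bool)
    keep[order[:n_drop]] = False
    return a.subset(keep)


def graph_density(a: BinaryAdjacency) -> float:
    """Edges over maximum possible edges, n(n-1)/2; 1 for a clique."""
    n = a.n_genes
    if n < 2:
        raise ValueError("density needs at least 2 genes")
    return a.n_edges / (n * (n - 1) / 2)
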