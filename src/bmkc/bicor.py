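"""Robust pairwise correlation via biweight midcorrelation (bicor).

Bicor replaces the sample means of Pearson's correlation with medians and
down-weights observations far from the median using Tukey's biweight, with
the weight scale set to nine times the (unscaled) median absolute deviation.
Points further than 9·MAD from the median receive weight zero and therefore
act as identified outliers; everything else contributes smoothly.

For a vector ``x`` with median ``med(x)`` and MAD ``mad(x)``::

    u_i = (x_i - med(x)) / (9 * mad(x))
    w_i = (1 - u_i**2)**2            if |u_i| < 1, else 0

and for two vectors ``x``, ``y`` of equal length::

    bicor(x, y) = sum_i (x_i - med(x)) w_i^x (y_i - med(y)) w_i^y
                  / sqrt( sum_j [(x_j - med(x)) w_j^x]^2 )
                  / sqrt( sum_k [(y_k - med(y)) w_k^y]^2 )

which always lies in [-1, 1].  The MAD here is the plain median of absolute
deviations, with no Gaussian consistency factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "BicorOptions",
    "CorrelationMatrix",
    "DegenerateVectorError",
    "median",
    "mad",
    "bicor_weights",
    "bicor",
    "bicor_matrix",
]

_FALLBACKS = ("zero", "pearson", "error")


class DegenerateVectorError(ValueError):
    """Raised when a vector has zero MAD (or zero weighted norm) and the
    fallback policy is ``error``."""


@dataclass(frozen=True)
class BicorOptions:
    """Options controlling bicor's outlier handling.

    Parameters
    ----------
    max_p_outliers:
        Maximum allowed proportion of outliers, counted separately on each
        side of the median.  The default 1.0 imposes no cap.  When below 1,
        the ``u`` values on a side with too many zero-weight points are
        rescaled so that at most this proportion of that side's points fall
        beyond the weight cutoff.
    fallback_on_zero_mad:
        What to do for a vector whose MAD (or weighted norm) is zero:
        ``"zero"`` reports correlation 0 with a warning, ``"pearson"``
        falls back to Pearson's correlation, ``"error"`` raises.
    """

    max_p_outliers: float = 1.0
    fallback_on_zero_mad: str = "zero"

    def __post_init__(self) -> None:
        if not (0.0 < self.max_p_outliers <= 1.0):
            raise ValueError(f"max_p_outliers must be in (0, 1], got {self.max_p_outliers}")
        if self.fallback_on_zero_mad not in _FALLBACKS:
            raise ValueError(
                f"fallback_on_zero_mad must be one of {_FALLBACKS}, got {self.fallback_on_zero_mad!r}"
            )


def _check_ids(ids: list[str], what: str, n: int) -> None:
    if len(ids) != n:
        raise ValueError(f"{what} length {len(ids)} does not match matrix dimension {n}")
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes-by-samples expression matrix with identifiers and a condition label."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D genes x samples matrix")
        if self.values.shape[1] < 1:
            raise ValueError("expression matrix needs at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains missing or non-finite values")
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        _check_ids(self.gene_ids, "gene_ids", self.values.shape[0])
        _check_ids(self.sample_ids, "sample_ids", self.values.shape[1])

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    """Symmetric gene-by-gene correlation matrix with values in [-1, 1]."""

    values: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("correlation matrix must be square")
        self.gene_ids = list(self.gene_ids)
        _check_ids(self.gene_ids, "gene_ids", n)
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=False):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.values) > 1.0 + 1e-12):
            raise ValueError("correlation values must lie in [-1, 1]")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


def median(v: np.ndarray) -> float:
    """Sample median; mean of the two central order statistics for even length."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("median of an empty vector is undefined")
    return float(np.median(v))


def mad(v: np.ndarray) -> float:
    """Unscaled median absolute deviation: median(|v - median(v)|)."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    return float(np.median(np.abs(v - np.median(v))))


def _side_capped_u(u: np.ndarray, max_p: float) -> np.ndarray:
    # Rescale each side of the median so at most max_p of that side's points
    # sit beyond |u| >= 1 (the zero-weight cutoff).
    u = u.copy()
    for mask in (u < 0, u > 0):
        side = np.abs(u[mask])
        if side.size == 0:
            continue
        frac_out = float(np.mean(side >= 1.0))
        if frac_out > max_p:
            q = float(np.quantile(side, 1.0 - max_p))
            if q > 1.0:
                u[mask] = u[mask] / q
    return u


def bicor_weights(v: np.ndarray, opts: BicorOptions | None = None) -> np.ndarray:
    """Tukey biweight weights on the 9*MAD scale.

    Raises :class:`DegenerateVectorError` when ``mad(v)`` is zero; callers
    apply the configured fallback policy.
    """
    opts = opts or BicorOptions()
    v = np.asarray(v, dtype=float)
    m = mad(v)
    if m == 0.0:
        raise DegenerateVectorError("vector has zero median absolute deviation")
    u = (v - np.median(v)) / (9.0 * m)
    if opts.max_p_outliers < 1.0:
        u = _side_capped_u(u, opts.max_p_outliers)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return w


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, y)[0, 1]
    return float(r) if np.isfinite(r) else 0.0


def _fallback(opts: BicorOptions, x: np.ndarray, y: np.ndarray, reason: str) -> float:
    if opts.fallback_on_zero_mad == "error":
        raise DegenerateVectorError(reason)
    if opts.fallback_on_zero_mad == "pearson":
        warnings.warn(f"{reason}; falling back to Pearson correlation", stacklevel=3)
        return _pearson(x, y)
    warnings.warn(f"{reason}; reporting correlation 0", stacklevel=3)
    return 0.0


def bicor(x: np.ndarray, y: np.ndarray, opts: BicorOptions | None = None) -> float:
    """Biweight midcorrelation of two equal-length vectors, in [-1, 1]."""
    opts = opts or BicorOptions()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vectors must be 1-D with equal length, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("bicor needs at least 2 observations")
    try:
        wx = bicor_weights(x, opts)
        wy = bicor_weights(y, opts)
    except DegenerateVectorError as exc:
        return _fallback(opts, x, y, str(exc))
    xc = (x - np.median(x)) * wx
    yc = (y - np.median(y)) * wy
    denom = np.sqrt(np.sum(xc**2)) * np.sqrt(np.sum(yc**2))
    if denom == 0.0:
        return _fallback(opts, x, y, "zero weighted norm")
    return float(np.clip(np.dot(xc, yc) / denom, -1.0, 1.0))


def _weighted_centered_rows(values: np.ndarray, opts: BicorOptions) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene median-centred, biweight-weighted, norm-scaled rows.

    Returns the scaled rows and a boolean mask of degenerate genes (zero MAD
    or zero weighted norm), whose rows are left at zero.
    """
    n_genes, _ = values.shape
    med = np.median(values, axis=1, keepdims=True)
    dev = values - med
    madv = np.median(np.abs(dev), axis=1)
    degenerate = madv == 0.0
    scaled = np.zeros_like(values)
    ok = ~degenerate
    if np.any(ok):
        u = dev[ok] / (9.0 * madv[ok, None])
        if opts.max_p_outliers < 1.0:
            u = np.apply_along_axis(_side_capped_u, 1, u, opts.max_p_outliers)
        w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
        centred = dev[ok] * w
        norms = np.sqrt(np.sum(centred**2, axis=1))
        zero_norm = norms == 0.0
        if np.any(zero_norm):
            idx = np.flatnonzero(ok)[zero_norm]
            degenerate[idx] = True
            norms[zero_norm] = 1.0
        scaled[ok] = centred / norms[:, None]
        scaled[degenerate] = 0.0
    return scaled, degenerate


def bicor_matrix(x: ExpressionMatrix, opts: BicorOptions | None = None) -> CorrelationMatrix:
    """All pairwise bicor values for the genes of an expression matrix.

    Degenerate genes (zero MAD, e.g. flat housekeeping probes) are handled
    per ``opts.fallback_on_zero_mad``: ``zero`` leaves their whole row and
    column at 0 (including the diagonal), ``pearson`` substitutes Pearson
    correlations for those rows, ``error`` raises.
    """
    opts = opts or BicorOptions()
    if x.n_genes < 2:
        raise ValueError("correlation matrix needs at least 2 genes")
    if x.n_samples < 2:
        raise ValueError("correlation needs at least 2 samples")
    scaled, degenerate = _weighted_centered_rows(x.values, opts)
    if np.any(degenerate):
        bad = [x.gene_ids[i] for i in np.flatnonzero(degenerate)[:5]]
        if opts.fallback_on_zero_mad == "error":
            raise DegenerateVectorError(f"degenerate genes (zero MAD/norm): {bad}")
        warnings.warn(
            f"{int(degenerate.sum())} degenerate gene(s) (zero MAD/norm), e.g. {bad}",
            stacklevel=2,
        )
    corr = np.clip(scaled @ scaled.T, -1.0, 1.0)
    ok = ~degenerate
    diag = np.where(ok, 1.0, 0.0)
    np.fill_diagonal(corr, diag)
    if np.any(degenerate) and opts.fallback_on_zero_mad == "pearson":
        std = x.values.std(axis=1)
        computable = std > 0.0
        with np.errstate(invalid="ignore", divide="ignore"):
            pear = np.corrcoef(x.values)
        pear = np.nan_to_num(pear, nan=0.0)
        fill = degenerate & computable
        for i in np.flatnonzero(fill):
            corr[i, :] = pear[i, :]
            corr[:, i] = pear[:, i]
            corr[i, i] = 1.0
        for i in np.flatnonzero(degenerate & ~computable):
            corr[i, :] = 0.0
            corr[:, i] = 0.0
        corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(values=corr, gene_ids=list(x.gene_ids))
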