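"""Permutation significance of detected differential-coexpression modules.

The module score is the global total differential coexpression change: the
sum, over every detected module and every unordered gene pair inside it, of
|c_N(i,j) - c_D(i,j)|.  The null hypothesis is that all genes are mutually
independent within each condition; it is sampled by shuffling each gene's
expression values independently within each condition (group-wise), which
destroys all covariance structure while preserving every per-gene marginal.
Each permutation replicate re-runs the entire detection pipeline and scores
whatever modules it finds (0 when none), so the null accounts for the
selection step, not just the scoring.

The empirical p-value is the upper-tail exceedance #(null >= observed) / n,
reported together with the add-one variant (#exceed + 1) / (n + 1), which
is never exactly zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .bicor import CorrelationMatrix, ExpressionMatrix
from .cpm import ModuleSet

__all__ = ["PermutationResult", "module_score", "empirical_p", "permute_expression", "permutation_test"]

logger = logging.getLogger("bmkc")


@dataclass
class PermutationResult:
    """Observed score, null scores and empirical p-values of one test."""

    observed_score: float
    null_scores: np.ndarray
    p_value: float
    p_value_add_one: float
    n_permutations: int
    seed: int
    n_observed_modules: int

    def __post_init__(self) -> None:
        self.null_scores = np.asarray(self.null_scores, dtype=float)
        if self.null_scores.shape != (self.n_permutations,):
            raise ValueError("null_scores length must equal n_permutations")


def module_score(
    c_normal: CorrelationMatrix, c_disease: CorrelationMatrix, modules: ModuleSet
) -> float:
    """Sum of |c_N - c_D| over all unordered gene pairs within each module.

    Pairs shared by overlapping modules are counted once per module; an
    empty ModuleSet scores 0.
    """
    if c_normal.gene_ids != c_disease.gene_ids:
        raise ValueError("correlation matrices must share the same gene set and order")
    index = {g: i for i, g in enumerate(c_normal.gene_ids)}
    diff = np.abs(c_normal.values - c_disease.values)
    total = 0.0
    for module in modules:
        try:
            idx = np.array([index[g] for g in module], dtype=int)
        except KeyError as exc:
            raise ValueError(f"module gene {exc.args[0]!r} missing from correlation matrices") from None
        sub = diff[np.ix_(idx, idx)]
        total += float(np.triu(sub, k=1).sum())
    return total


def empirical_p(observed: float, null_scores: np.ndarray, add_one: bool = False) -> float:
    """Upper-tail exceedance probability of the observed score under the null."""
    null_scores = np.asarray(null_scores, dtype=float)
    n = null_scores.size
    if n == 0:
        raise ValueError("need at least one null score")
    exceed = int(np.sum(null_scores >= observed))
    if add_one:
        return (exceed + 1) / (n + 1)
    return exceed / n


def permute_expression(
    x_normal: ExpressionMatrix,
    x_disease: ExpressionMatrix,
    seed: int | np.random.Generator,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Shuffle each gene's values independently, within each condition.

    Per-gene value multisets are untouched; only the sample assignment is
    randomised, so all between-gene covariance is destroyed.
    """
    if x_normal.gene_ids != x_disease.gene_ids:
        raise ValueError("normal and disease inputs must share the same gene set and order")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm_n = rng.permuted(x_normal.values, axis=1)
    perm_d = rng.permuted(x_disease.values, axis=1)
    return (
        ExpressionMatrix(perm_n, list(x_normal.gene_ids), list(x_normal.sample_ids), x_normal.condition),
        ExpressionMatrix(perm_d, list(x_disease.gene_ids), list(x_disease.sample_ids), x_disease.condition),
    )


def permutation_test(
    x_normal: ExpressionMatrix,
    x_disease: ExpressionMatrix,
    pipeline_config,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Group-wise permutation test of the pipeline's detected modules.

    The observed score comes from the modules detected on the real data;
    each null score re-runs the full pipeline (correlation, binarization,
    filtering, module detection, scoring) on one permuted dataset.  With a
    fixed seed the whole result is bit-for-bit reproducible.
    """
    from .pipeline import detect_modules

    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    modules, c_normal, c_disease, _ = detect_modules(x_normal, x_disease, pipeline_config)
    observed = module_score(c_normal, c_disease, modules)
    if len(modules) == 0:
        warnings.warn("observed pipeline found no modules; permutation p-value will be 1", stacklevel=2)
    rng = np.random.default_rng(seed)
    null_scores = np.empty(n_permutations, dtype=float)
    for i in range(n_permutations):
        perm_n, perm_d = permute_expression(x_normal, x_disease, rng)
        null_modules, null_cn, null_cd, _ = detect_modules(perm_n, perm_d, pipeline_config)
        null_scores[i] = module_score(null_cn, null_cd, null_modules) if len(null_modules) else 0.0
    return PermutationResult(
        observed_score=observed,
        null_scores=null_scores,
        p_value=empirical_p(observed, null_scores),
        p_value_add_one=empirical_p(observed, null_scores, add_one=True),
        n_permutations=n_permutations,
        seed=seed,
        n_observed_modules=len(modules),
    )
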