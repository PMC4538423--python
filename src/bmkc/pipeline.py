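"""End-to-end orchestration: expression -> bicor -> binary graph -> modules.

The stage order is fixed: biweight midcorrelation for each condition,
threshold binarization into one differential-coexpression graph, removal of
isolated genes, optional low-degree pruning, k-clique percolation, and an
optional group-wise permutation test of the detected modules.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .bicor import BicorOptions, CorrelationMatrix, ExpressionMatrix, bicor_matrix
from .cpm import ModuleSet, PercolationStats, kclique_communities, order_parameters
from .diffnet import BinaryAdjacency, ThresholdConfig, binarize, filter_low_degree, remove_isolated

__all__ = ["PipelineConfig", "PipelineResult", "detect_modules", "run_pipeline"]

logger = logging.getLogger("bmkc")


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the pipeline, echoed verbatim into outputs for provenance."""

    bicor: BicorOptions = field(default_factory=BicorOptions)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    k: int = 4
    filter_fraction: float = 0.5
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if not (0.0 <= self.filter_fraction < 1.0):
            raise ValueError(f"filter_fraction must be in [0, 1), got {self.filter_fraction}")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    modules: ModuleSet
    stats: PercolationStats | None
    permutation: "object | None"  # PermutationResult when requested
    c_normal: CorrelationMatrix
    c_disease: CorrelationMatrix
    adjacency: BinaryAdjacency
    config: PipelineConfig


def detect_modules(
    x_normal: ExpressionMatrix, x_disease: ExpressionMatrix, cfg: PipelineConfig
) -> tuple[ModuleSet, CorrelationMatrix, CorrelationMatrix, BinaryAdjacency]:
    """Deterministic detection stages shared by the observed run and every
    permutation replicate.  Returns the modules, both correlation matrices
    and the filtered adjacency."""
    if x_normal.gene_ids != x_disease.gene_ids:
        raise ValueError("normal and disease inputs must share the same gene set and order")
    c_normal = bicor_matrix(x_normal, cfg.bicor)
    c_disease = bicor_matrix(x_disease, cfg.bicor)
    adjacency = binarize(c_normal, c_disease, cfg.thresholds)
    adjacency = remove_isolated(adjacency)
    if cfg.filter_fraction > 0.0 and adjacency.n_genes > 0:
        adjacency = filter_low_degree(adjacency, cfg.filter_fraction)
    if adjacency.n_genes == 0:
        return ModuleSet(k=cfg.k), c_normal, c_disease, adjacency
    return kclique_communities(adjacency, cfg.k), c_normal, c_disease, adjacency


def run_pipeline(
    x_normal: ExpressionMatrix,
    x_disease: ExpressionMatrix,
    cfg: PipelineConfig,
    outdir: str | Path | None = None,
    permute: bool | None = None,
) -> PipelineResult:
    """Run the full pipeline; optionally write all artifacts to ``outdir``.

    ``permute`` defaults to ``cfg.n_permutations > 0``.  An empty graph after
    filtering yields an empty ModuleSet with a warning, not an error.
    """
    logger.info("input: %d genes, %d + %d samples", x_normal.n_genes, x_normal.n_samples, x_disease.n_samples)
    modules, c_normal, c_disease, adjacency = detect_modules(x_normal, x_disease, cfg)
    logger.info(
        "graph after filtering: %d genes, %d edges; %d module(s) at k=%d",
        adjacency.n_genes,
        adjacency.n_edges,
        len(modules),
        cfg.k,
    )
    if adjacency.n_genes == 0:
        logger.warning("graph is empty after thresholding/filtering; no modules detected")
        stats = None
    else:
        stats = order_parameters(adjacency, cfg.k)
    permutation = None
    if permute if permute is not None else cfg.n_permutations > 0:
        from .significance import permutation_test

        permutation = permutation_test(
            x_normal, x_disease, cfg, n_permutations=cfg.n_permutations, seed=cfg.seed
        )
        logger.info(
            "permutation test: observed score %.4f, p = %.4g (add-one %.4g)",
            permutation.observed_score,
            permutation.p_value,
            permutation.p_value_add_one,
        )
    result = PipelineResult(
        modules=modules,
        stats=stats,
        permutation=permutation,
        c_normal=c_normal,
        c_disease=c_disease,
        adjacency=adjacency,
        config=cfg,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    from . import io as bmkc_io

    outdir.mkdir(parents=True, exist_ok=True)
    echo = result.config.to_dict()
    bmkc_io.write_correlation(result.c_normal, outdir / "bicor_normal.tsv")
    bmkc_io.write_correlation(result.c_disease, outdir / "bicor_disease.tsv")
    bmkc_io.write_edge_list(result.adjacency, outdir / "edges.tsv")
    bmkc_io.write_modules(result.modules, outdir / "modules.tsv")
    bmkc_io.write_modules_json(result.modules, outdir / "modules.json", stats=result.stats, config=echo)
    if result.permutation is not None:
        bmkc_io.write_permutation(result.permutation, outdir / "permutation.json", config=echo)
    (outdir / "config.json").write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")
    logger.info("artifacts written to %s", outdir)
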