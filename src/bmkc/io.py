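"""Plain-text I/O for every pipeline artifact.

Expression and correlation matrices travel as tab-separated text: first
column gene identifier, one header row of sample (or gene) ids.  Binary
graphs are written as two-column edge lists with gene pairs sorted
lexicographically within and across rows, so repeated runs are
byte-identical.  Modules go out both as a clique table (one row per clique,
tab-separated gene symbols) and as JSON carrying modules, cliques, k and
the percolation statistics.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .bicor import CorrelationMatrix, ExpressionMatrix
from .cpm import ModuleSet, PercolationStats
from .diffnet import BinaryAdjacency
from .significance import PermutationResult
from .simulate import BenchmarkTruth

__all__ = [
    "DataFormatError",
    "read_expression",
    "write_expression",
    "read_correlation",
    "write_correlation",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
    "write_modules",
    "write_modules_json",
    "write_truth",
    "read_truth",
    "write_permutation",
    "load_config_file",
]


class DataFormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def _parse_table(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise DataFormatError(f"{path}: file is empty")
    header = lines[0].rstrip("\n").split("\t")
    col_ids = header[1:]
    if not col_ids:
        raise DataFormatError(f"{path}: line 1: header has no sample columns")
    n_cols = len(col_ids)
    row_ids: list[str] = []
    seen: set[str] = set()
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_cols + 1:
            raise DataFormatError(
                f"{path}: line {lineno}: expected {n_cols + 1} fields, got {len(fields)}"
            )
        gid = fields[0]
        if gid in seen:
            raise DataFormatError(f"{path}: line {lineno}: duplicate gene id {gid!r}")
        seen.add(gid)
        row_ids.append(gid)
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError:
            bad = next(v for v in fields[1:] if not _is_float(v))
            raise DataFormatError(
                f"{path}: line {lineno}: non-numeric value {bad!r} for gene {gid!r}"
            ) from None
    if not rows:
        raise DataFormatError(f"{path}: no data rows")
    return row_ids, col_ids, np.array(rows, dtype=float)


def _is_float(v: str) -> bool:
    try:
        float(v)
    except ValueError:
        return False
    return True


def read_expression(path: str | Path, condition: str = "") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (gene id column + sample header row)."""
    gene_ids, sample_ids, values = _parse_table(path)
    if not np.all(np.isfinite(values)):
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise DataFormatError(
            f"{path}: line {i + 2}: missing/non-finite value for gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids, condition=condition)


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(x.sample_ids) + "\n")
        for gid, row in zip(x.gene_ids, x.values):
            fh.write(gid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


def read_correlation(path: str | Path) -> CorrelationMatrix:
    """Read a square gene-x-gene TSV with matching header row and column."""
    row_ids, col_ids, values = _parse_table(path)
    if row_ids != col_ids:
        raise DataFormatError(f"{path}: row and column gene ids differ")
    values = (values + values.T) / 2.0  # absorb round-trip rounding
    return CorrelationMatrix(values=np.clip(values, -1.0, 1.0), gene_ids=row_ids)


def write_correlation(c: CorrelationMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(c.gene_ids) + "\n")
        for gid, row in zip(c.gene_ids, c.values):
            fh.write(gid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


def write_edge_list(a: BinaryAdjacency, path: str | Path) -> None:
    """Two-column TSV of edges, lexicographically sorted within and across rows."""
    ii, jj = a.values.nonzero()
    edges = sorted(
        tuple(sorted((a.gene_ids[i], a.gene_ids[j])))
        for i, j in zip(ii.tolist(), jj.tolist())
        if i < j
    )
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_edge_list(path: str | Path, gene_ids: list[str] | None = None) -> BinaryAdjacency:
    """Rebuild a BinaryAdjacency from a two-column edge list.

    Without an explicit ``gene_ids`` universe, the sorted set of gene ids
    appearing in the file is used (isolated genes are then unrepresentable).
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise DataFormatError(f"{path}: line {lineno}: expected 2 fields, got {len(fields)}")
        if fields[0] == fields[1]:
            raise DataFormatError(f"{path}: line {lineno}: self-loop {fields[0]!r}")
        edges.append((fields[0], fields[1]))
    if gene_ids is None:
        gene_ids = sorted({g for e in edges for g in e})
    index = {g: i for i, g in enumerate(gene_ids)}
    values = np.zeros((len(gene_ids), len(gene_ids)), dtype=np.uint8)
    for lineno, (u, v) in enumerate(edges, start=1):
        if u not in index or v not in index:
            raise DataFormatError(f"{path}: line {lineno}: unknown gene id")
        values[index[u], index[v]] = values[index[v], index[u]] = 1
    return BinaryAdjacency(values=values, gene_ids=list(gene_ids))


def write_graphml(a: BinaryAdjacency, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(a.gene_ids)
    ii, jj = a.values.nonzero()
    g.add_edges_from(
        (a.gene_ids[i], a.gene_ids[j]) for i, j in zip(ii.tolist(), jj.tolist()) if i < j
    )
    nx.write_graphml(g, path)


def write_modules(modules: ModuleSet, path: str | Path) -> None:
    """Clique table: module number, clique number, then gene symbols."""
    with open(path, "w") as fh:
        fh.write("module\tclique\tgenes\n")
        for m, cliques in enumerate(modules.cliques_per_module, start=1):
            for c, clique in enumerate(cliques, start=1):
                fh.write(f"{m}\t{c}\t" + "\t".join(clique) + "\n")


def write_modules_json(
    modules: ModuleSet,
    path: str | Path,
    stats: PercolationStats | None = None,
    config: dict | None = None,
) -> None:
    payload = {
        "k": modules.k,
        "modules": [list(m) for m in modules.modules],
        "cliques_per_module": [[list(c) for c in cl] for cl in modules.cliques_per_module],
        "percolation_stats": dataclasses.asdict(stats) if stats is not None else None,
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_truth(truth: BenchmarkTruth, path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in sorted(truth.planted_gene_ids)))


def read_truth(path: str | Path) -> BenchmarkTruth:
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return BenchmarkTruth(planted_gene_ids=frozenset(ids))


def write_permutation(result: PermutationResult, path: str | Path, config: dict | None = None) -> None:
    payload = {
        "observed_score": result.observed_score,
        "p_value": result.p_value,
        "p_value_add_one": result.p_value_add_one,
        "n_permutations": result.n_permutations,
        "n_observed_modules": result.n_observed_modules,
        "seed": result.seed,
        "null_scores": [float(v) for v in result.null_scores],
        "config": config,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_config_file(path: str | Path) -> dict:
    """YAML key-value config mirroring the CLI flags; flat mapping."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise DataFormatError(f"{path}: config must be a mapping of option names to values")
    return data
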