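"""Spearman co-expression networks and the multi-query intersection screen.

A co-expression network connects genes whose expression profiles are rank
correlated across many cultivation conditions ("guilt by association"). The
screen implemented here interrogates the neighbourhoods of a handful of query
genes — e.g. three TCA-cycle genes (*citA*, *idh2*, *fumR*) and three Golgi
vesicle-coat genes (*copA*, *sec13*, *sec26*) — and intersects them to find
genes co-expressed with *all* queries.

Conventions (fixed for reproducibility):

* Spearman correlation uses average (fractional) ranks for ties.
* An edge requires rho strictly greater than the cutoff ("above" the cutoff);
  negative correlations never form edges.
* Matrices with missing values are rejected at construction time rather than
  pairwise-deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "CoexpressionNetwork",
    "ScreenResult",
    "spearman_rho",
    "build_network",
    "query_subnetwork",
    "intersect_subnetworks",
]

MIN_CONDITIONS = 5


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x conditions expression table.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (row labels).
    condition_ids
        Ordered, unique condition identifiers (column labels).
    values
        Real matrix of shape ``(len(gene_ids), len(condition_ids))`` with no
        missing entries.
    """

    gene_ids: tuple[str, ...]
    condition_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "condition_ids", tuple(self.condition_ids))
        object.__setattr__(self, "values", values)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.condition_ids)) != len(self.condition_ids):
            raise ValueError("duplicate condition identifiers")
        if values.shape != (len(self.gene_ids), len(self.condition_ids)):
            raise ValueError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.condition_ids)} conditions"
            )
        if len(self.condition_ids) < MIN_CONDITIONS:
            raise ValueError(
                f"at least {MIN_CONDITIONS} conditions required for a stable "
                f"Spearman network, got {len(self.condition_ids)}"
            )
        if not np.isfinite(values).all():
            raise ValueError(
                "expression matrix contains missing or non-finite values; "
                "filter or impute before loading"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_conditions(self) -> int:
        return len(self.condition_ids)

    def row(self, gene: str) -> np.ndarray:
        try:
            idx = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.condition_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            condition_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(dtype=float),
        )

    def to_tsv(self, path) -> None:
        """Write as TSV: first column gene ID, header row of condition IDs."""
        frame = self.to_frame()
        frame.index.name = "gene"
        frame.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls.from_frame(frame)


@dataclass(frozen=True)
class CoexpressionNetwork:
    """Undirected gene graph with edges above a Spearman cutoff.

    ``graph`` stores one edge per unordered gene pair with attribute ``rho``.
    When built in screen mode (``query_restriction``) only pairs touching the
    restriction set were evaluated; neighbourhoods of other genes are then
    incomplete by construction.
    """

    graph: nx.Graph
    cutoff: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "rho": d["rho"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho"])

    def to_tsv(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the multi-query subnetwork intersection."""

    query_genes: tuple[str, ...]
    per_query_neighbors: Mapping[str, frozenset[str]]
    intersection: frozenset[str]

    def __post_init__(self) -> None:
        for q, neigh in self.per_query_neighbors.items():
            if not self.intersection <= neigh:
                raise ValueError(
                    f"intersection not contained in neighbourhood of query {q!r}"
                )

    @property
    def intersection_size(self) -> int:
        return len(self.intersection)

    def membership_table(self) -> pd.DataFrame:
        """Per-gene support: how many query neighbourhoods contain it."""
        support: dict[str, int] = {}
        for neigh in self.per_query_neighbors.values():
            for g in neigh:
                support[g] = support.get(g, 0) + 1
        rows = [
            {
                "gene": g,
                "n_queries_supporting": n,
                "member_of_intersection": g in self.intersection,
            }
            for g, n in sorted(support.items())
        ]
        return pd.DataFrame(
            rows, columns=["gene", "n_queries_supporting", "member_of_intersection"]
        )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties.

    Raises on length mismatch, fewer than two observations, or a constant
    vector (the statistic is undefined there).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1:
        raise ValueError("inputs must be one-dimensional")
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rx = rankdata(xa)
    ry = rankdata(ya)
    return float(np.corrcoef(rx, ry)[0, 1])


def _ranked_zscores(values: np.ndarray) -> np.ndarray:
    """Row-wise ranks, centred and scaled so that R @ R.T / m gives Spearman."""
    ranks = rankdata(values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    if np.any(norms == 0):
        bad = [i for i, n in enumerate(norms.ravel()) if n == 0]
        raise ValueError(
            f"constant expression rows (undefined Spearman) at indices {bad[:5]}"
        )
    return ranks / norms


def build_network(
    matrix: ExpressionMatrix,
    cutoff: float = 0.5,
    query_restriction: Iterable[str] | None = None,
) -> CoexpressionNetwork:
    """Build the co-expression network with edges at rho strictly above ``cutoff``.

    With ``query_restriction`` only gene pairs having at least one member in
    the restriction set are evaluated (screen mode); this avoids the all-pairs
    cost when only query neighbourhoods are consumed downstream.
    """
    if not 0 <= cutoff < 1:
        raise ValueError(f"cutoff must lie in [0, 1), got {cutoff}")
    z = _ranked_zscores(matrix.values)
    graph = nx.Graph()
    graph.add_nodes_from(matrix.gene_ids)
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}

    if query_restriction is None:
        rho = z @ z.T
        iu, ju = np.nonzero(np.triu(rho > cutoff, k=1))
        for i, j in zip(iu.tolist(), ju.tolist()):
            graph.add_edge(
                matrix.gene_ids[i], matrix.gene_ids[j], rho=float(rho[i, j])
            )
    else:
        restriction = sorted(set(query_restriction))
        missing = [g for g in restriction if g not in gene_index]
        if missing:
            raise KeyError(f"restriction genes not in matrix: {missing}")
        rows = [gene_index[g] for g in restriction]
        rho = z[rows] @ z.T  # queries x all genes
        for qpos, q in enumerate(restriction):
            hits = np.nonzero(rho[qpos] > cutoff)[0]
            for j in hits.tolist():
                other = matrix.gene_ids[j]
                if other == q:
                    continue
                graph.add_edge(q, other, rho=float(rho[qpos, j]))
    return CoexpressionNetwork(graph=graph, cutoff=float(cutoff))


def query_subnetwork(network: CoexpressionNetwork, query: str) -> set[str]:
    """Neighbour set of ``query`` (the query itself excluded)."""
    if query not in network.graph:
        raise KeyError(f"query gene {query!r} not in network")
    return set(network.graph.neighbors(query))


def intersect_subnetworks(
    network: CoexpressionNetwork, queries: Sequence[str]
) -> ScreenResult:
    """Genes co-expressed with every query: the intersection of neighbourhoods.

    The query genes themselves are removed from the result, mirroring the
    screen's reporting of candidate (non-query) genes.
    """
    if not queries:
        raise ValueError("at least one query gene required")
    missing = [q for q in queries if q not in network.graph]
    if missing:
        raise KeyError(f"query genes not in network: {missing}")
    per_query = {q: frozenset(query_subnetwork(network, q)) for q in queries}
    inter: set[str] = set.intersection(*(set(s) for s in per_query.values()))
    inter -= set(queries)
    return ScreenResult(
        query_genes=tuple(queries),
        per_query_neighbors=per_query,
        intersection=frozenset(inter),
    )
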