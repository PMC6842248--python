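"""GO-term over-representation with Benjamini–Hochberg FDR control.

The test is the one-sided hypergeometric over-representation test (equivalent
to a one-sided Fisher exact test), the de facto standard behind GO enrichment
tools: given a candidate gene list of size ``n`` drawn from a universe of
``N`` annotated genes, of which ``K`` carry a term, the p-value is
``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

Annotations are flat gene -> term sets; no ontology propagation is applied.
The enrichment universe is the set of annotated genes in the annotation
table. Only terms with at least one candidate hit are tested, which fixes the
Benjamini–Hochberg family size deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "hypergeometric_upper_tail",
    "benjamini_hochberg",
    "enrich",
    "results_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSet:
    """Flat gene/term annotation maps with a defined universe."""

    gene_to_terms: Mapping[str, frozenset[str]]
    term_to_genes: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                if gene not in self.term_to_genes.get(t, frozenset()):
                    raise ValueError(f"inconsistent maps at gene {gene!r}, term {t!r}")
        for term, genes in self.term_to_genes.items():
            for g in genes:
                if term not in self.gene_to_terms.get(g, frozenset()):
                    raise ValueError(f"inconsistent maps at term {term!r}, gene {g!r}")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.gene_to_terms)

    @property
    def n_universe(self) -> int:
        return len(self.gene_to_terms)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationSet":
        g2t: dict[str, set[str]] = {}
        t2g: dict[str, set[str]] = {}
        for gene, term in pairs:
            g2t.setdefault(str(gene), set()).add(str(term))
            t2g.setdefault(str(term), set()).add(str(gene))
        return cls(
            gene_to_terms={g: frozenset(t) for g, t in g2t.items()},
            term_to_genes={t: frozenset(g) for t, g in t2g.items()},
        )

    @classmethod
    def from_tsv(cls, path) -> "AnnotationSet":
        """Read a two-column TSV (gene ID, term ID), one pair per line."""
        frame = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
        return cls.from_pairs(frame.itertuples(index=False))

    def to_tsv(self, path) -> None:
        rows = sorted(
            (g, t) for g, terms in self.gene_to_terms.items() for t in terms
        )
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-term 2x2 over-representation record.

    ``k`` of ``n`` candidates carry the term; ``K`` of ``N`` universe genes do.
    """

    term_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float
    reported: bool
    term_name: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.n, self.K):
            raise ValueError("inconsistent contingency counts")
        if not 0 < self.p_value <= 1:
            raise ValueError("p-value outside (0, 1]")
        if self.q_value < self.p_value - 1e-12 or self.q_value > 1:
            raise ValueError("q-value below p or above 1")


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    ``N`` universe size, ``K`` marked genes, ``n`` draws, ``k`` marked draws.
    Computed via the survival function, which works in log space and is stable
    for genome-scale ``N``.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v}")
    if K > N or n > N:
        raise ValueError("K and n must not exceed N")
    if k > min(n, K):
        raise ValueError("k must not exceed min(n, K)")
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0.0, 1.0)), 1.0)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted values, in input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values, clipped
    at 1. Order-preserving: ``p_a <= p_b`` implies ``q_a <= q_b``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a nonempty one-dimensional p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(
    candidates: Iterable[str],
    annotations: AnnotationSet,
    q_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term with >= 1 candidate hit for over-representation.

    Candidate genes outside the annotation universe are dropped with a logged
    warning. All tested terms are returned sorted by (q, p, term); results
    with ``q <= q_threshold`` carry ``reported=True``.
    """
    if not 0 < q_threshold <= 1:
        raise ValueError(f"q_threshold must lie in (0, 1], got {q_threshold}")
    cand = set(candidates)
    universe = annotations.universe
    dropped = cand - universe
    if dropped:
        logger.warning(
            "%d candidate gene(s) outside the annotation universe dropped: %s",
            len(dropped),
            sorted(dropped)[:10],
        )
    cand &= universe
    if not cand:
        raise ValueError("no candidate genes overlap the annotation universe")

    N = annotations.n_universe
    n = len(cand)
    tested: list[tuple[str, int, int, float]] = []
    for term, term_genes in annotations.term_to_genes.items():
        k = len(cand & term_genes)
        if k == 0:
            continue
        K = len(term_genes)
        tested.append((term, k, K, hypergeometric_upper_tail(k, K, n, N)))

    q_values = benjamini_hochberg([t[3] for t in tested])
    results = [
        EnrichmentResult(
            term_id=term,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            q_value=float(q),
            reported=bool(q <= q_threshold),
        )
        for (term, k, K, p), q in zip(tested, q_values)
    ]
    results.sort(key=lambda r: (r.q_value, r.p_value, r.term_id))
    return results


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results to the standard report columns."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_value": r.p_value,
                "q_value": r.q_value,
                "reported": r.reported,
            }
            for r in results
        ],
        columns=[
            "term_id",
            "term_name",
            "k",
            "n",
            "K",
            "N",
            "p_value",
            "q_value",
            "reported",
        ],
    )
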