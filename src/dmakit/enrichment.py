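"""Hypergeometric over-representation tests against a background set.

Given a query of n genes drawn from an M-gene background, a set with K
members in the background, and x members of the query inside the set, the
over-representation p-value is the upper tail P(X >= x) of the
hypergeometric distribution.  The pmf is evaluated in log space (gamma
functions) so large array backgrounds do not overflow; an exact
integer-arithmetic path is kept for cross-checking.  A pmf-only
compatibility mode reports the point mass P(X = x) instead of the tail.

For ontologies, annotations are first propagated to all ancestors (the
true-path rule: a gene annotated to a term counts for every ancestor)
before per-term testing; root terms are excluded from output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.special import gammaln

from .diffexp import bh_adjust
from .io import GeneSetCollection, OntologyGraph, normalize_gene

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "hypergeom_pmf",
    "hypergeom_tail",
    "enrich_gene_sets",
    "enrich_go",
    "export_go_graph",
]


@dataclass
class EnrichmentRecord:
    set_id: str
    name: str
    K: int          # set members in background
    x: int          # set members in query
    n: int          # query size
    M: int          # background size
    p_value: float
    adjusted_p: float | None = None

    def as_record(self) -> dict:
        return {
            "set_id": self.set_id, "name": self.name, "K": self.K,
            "x": self.x, "n": self.n, "M": self.M, "p_value": self.p_value,
            "adjusted_p": self.adjusted_p if self.adjusted_p is not None else "",
        }


def _check_args(x: int, M: int, K: int, n: int) -> None:
    for v, label in ((x, "x"), (M, "M"), (K, "K"), (n, "n")):
        if int(v) != v or v < 0:
            raise ValueError(f"{label} must be a non-negative integer, got {v}")
    if K > M or n > M:
        raise ValueError(f"need K <= M and n <= M (K={K}, n={n}, M={M})")
    if not (max(0, n + K - M) <= x <= min(n, K)):
        raise ValueError(
            f"x={x} outside the hypergeometric support "
            f"[{max(0, n + K - M)}, {min(n, K)}] for M={M}, K={K}, n={n}"
        )


def _log_comb(a: int, b: int) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_pmf(x: int, M: int, K: int, n: int, method: str = "log") -> float:
    """P(X = x): probability of exactly x marked genes when drawing n from
    an M-gene background containing K marked genes.

    ``method='log'`` (default) evaluates C(K,x) C(M-K,n-x) / C(M,n) via log
    gamma functions; ``method='exact'`` uses integer binomials (slower,
    reference path for modest M).
    """
    _check_args(x, M, K, n)
    if method == "log":
        return float(math.exp(_log_comb(K, x) + _log_comb(M - K, n - x)
                              - _log_comb(M, n)))
    if method == "exact":
        return math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)
    raise ValueError(f"unknown method {method!r}")


def hypergeom_tail(x: int, M: int, K: int, n: int, method: str = "log") -> float:
    """Upper tail P(X >= x), clipped into (0, 1]."""
    _check_args(x, M, K, n)
    hi = min(n, K)
    total = math.fsum(hypergeom_pmf(i, M, K, n, method=method)
                      for i in range(x, hi + 1))
    return float(min(max(total, 5e-324), 1.0))


def _normalize_query(query, background) -> tuple[frozenset, frozenset, int]:
    bg = frozenset(normalize_gene(g) for g in background)
    if not bg:
        raise ValueError("background set is empty")
    q_raw = {normalize_gene(g) for g in query}
    if not q_raw:
        raise ValueError("query set is empty")
    dropped = q_raw - bg
    if dropped:
        logger.warning("dropped %d query gene(s) absent from background",
                       len(dropped))
    q = frozenset(q_raw & bg)
    if not q:
        raise ValueError("no query gene is present in the background")
    return q, bg, len(dropped)


def _test_sets(named_sets, query, background, p_cutoff, pmf_only, fdr_bh):
    M, n = len(background), len(query)
    records = []
    for set_id, name, members in named_sets:
        in_bg = members & background
        K = len(in_bg)
        if K == 0:
            continue
        x = len(in_bg & query)
        if pmf_only:
            p = hypergeom_pmf(x, M, K, n)
        else:
            p = hypergeom_tail(x, M, K, n)
        records.append(EnrichmentRecord(set_id, name, K, x, n, M, float(p)))
    if fdr_bh and records:
        adj = bh_adjust([r.p_value for r in records])
        for r, a in zip(records, adj):
            r.adjusted_p = float(a)
    records = [r for r in records if r.p_value < p_cutoff]
    records.sort(key=lambda r: (r.p_value, r.set_id))
    return records


def enrich_gene_sets(query, background, collection: GeneSetCollection,
                     p_cutoff: float = 0.05, pmf_only: bool = False,
                     fdr_bh: bool = False) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of each gene set in the query.

    K counts set members inside the background, x counts them inside the
    query; sets not intersecting the background are skipped.  Query genes
    absent from the background are dropped with a warning.  Records with
    p < ``p_cutoff`` are returned sorted by ascending p (ties by set name).
    """
    query, background, _ = _normalize_query(query, background)
    named = [(name, desc or name, members)
             for name, (desc, members) in collection.items()]
    return _test_sets(named, query, background, p_cutoff, pmf_only, fdr_bh)


def propagate_annotations(ontology: OntologyGraph) -> dict[str, frozenset[str]]:
    """term -> genes map after ancestor propagation (true-path rule)."""
    term_genes: dict[str, set[str]] = {t: set() for t in ontology.graph.nodes}
    ancestor_cache: dict[str, set[str]] = {}
    for gene, terms in ontology.annotations.items():
        for term in terms:
            if term not in ancestor_cache:
                ancestor_cache[term] = ontology.ancestors(term) | {term}
            for t in ancestor_cache[term]:
                term_genes[t].add(gene)
    return {t: frozenset(g) for t, g in term_genes.items()}


def enrich_go(query, background, ontology: OntologyGraph,
              p_cutoff: float = 0.05, pmf_only: bool = False,
              fdr_bh: bool = False) -> list[EnrichmentRecord]:
    """Per-term hypergeometric over-representation on the ontology DAG.

    Annotations are propagated upward first, so a gene annotated to a leaf
    counts for every ancestor.  Root terms (annotated with essentially the
    whole background) are excluded from the output.
    """
    query, background, _ = _normalize_query(query, background)
    term_genes = propagate_annotations(ontology)
    roots = ontology.roots
    named = [(term, ontology.term_name(term), genes)
             for term, genes in sorted(term_genes.items())
             if term not in roots and genes]
    return _test_sets(named, query, background, p_cutoff, pmf_only, fdr_bh)


_BUCKET_COLORS = ["#fee5d9", "#fcae91", "#fb6a4a", "#de2d26", "#a50f15"]


def _color_bucket(p_value: float) -> str:
    """Bucket -log10 p into one of five reds (light = weak, dark = strong)."""
    neglog = -math.log10(max(p_value, 5e-324))
    idx = min(int(neglog // 3), len(_BUCKET_COLORS) - 1)
    return _BUCKET_COLORS[idx]


def export_go_graph(records: list[EnrichmentRecord], ontology: OntologyGraph,
                    path) -> None:
    """Write a DOT graph of the significant terms plus their ancestry.

    Significant terms are filled with a color bucket encoding -log10 p;
    ancestor terms appear unfilled; edges are the is_a edges induced on the
    union of significant terms and their ancestors.
    """
    significant = {r.set_id: r for r in records}
    nodes: set[str] = set()
    for term in significant:
        nodes.add(term)
        nodes |= ontology.ancestors(term)
    lines = ["digraph ontology {", "  rankdir=BT;",
             '  node [shape=box, style=filled, fillcolor="#ffffff"];']
    for term in sorted(nodes):
        label = f"{term}\\n{ontology.term_name(term)}"
        if term in significant:
            rec = significant[term]
            color = _color_bucket(rec.p_value)
            label += f"\\np={rec.p_value:.3g}"
            lines.append(f'  "{term}" [label="{label}", fillcolor="{color}"];')
        else:
            lines.append(f'  "{term}" [label="{label}"];')
    for child, parent in sorted(ontology.graph.edges):
        if child in nodes and parent in nodes:
            lines.append(f'  "{child}" -> "{parent}";')
    lines.append("}")
    with open(str(path), "w") as fh:
        fh.write("\n".join(lines) + "\n")
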