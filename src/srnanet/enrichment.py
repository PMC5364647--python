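"""Local gene-set enrichment of an sRNA's candidate targets.

For one sRNA, the selection is the set of distinct mRNA targets of its
interactions; each annotation term is tested for over-representation in
the selection against a background gene universe with the
hypergeometric upper tail P(X >= k), and with the conservative
"one-removed" variant (the EASE score: the same tail with one observed
success discounted, so a single-gene hit is never significant).
Benjamini–Hochberg q-values control the FDR across terms.

The annotation catalog is a local, flat gene -> term mapping (2-column
TSV, optional term-description TSV); terms are plain labels with no
ontology-graph propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import MissingNodeError, ParseError, ValidationError
from .model import RegulatoryNetwork

__all__ = [
    "AnnotationCatalog",
    "EnrichmentResult",
    "hypergeom_tail",
    "ease_score",
    "bh_adjust",
    "enrich_targets",
]


@dataclass
class AnnotationCatalog:
    """Flat annotation catalog: term descriptions plus gene -> terms."""

    term_defs: dict[str, str] = field(default_factory=dict)
    gene_terms: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.gene_terms.items():
            self.gene_terms[gene] = set(terms)
            for t in terms:
                self.term_defs.setdefault(t, t)

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_terms.get(gene, set())

    def genes_with(self, term: str, universe: set[str] | None = None) -> set[str]:
        genes = {g for g, ts in self.gene_terms.items() if term in ts}
        return genes if universe is None else genes & universe

    @classmethod
    def from_tsv(
        cls, gene_term_path: str | Path, term_def_path: str | Path | None = None
    ) -> "AnnotationCatalog":
        """Load from a 2-column gene_id<TAB>term_id file, plus an optional
        term_id<TAB>description file."""
        gene_terms: dict[str, set[str]] = {}
        with open(gene_term_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 2:
                    raise ParseError(
                        f"{gene_term_path}:{lineno}: expected 2 columns, got {len(cols)}"
                    )
                gene_terms.setdefault(cols[0], set()).add(cols[1])
        term_defs: dict[str, str] = {}
        if term_def_path is not None:
            with open(term_def_path) as fh:
                for lineno, line in enumerate(fh, 1):
                    line = line.rstrip("\n")
                    if not line or line.startswith("#"):
                        continue
                    cols = line.split("\t")
                    if len(cols) != 2:
                        raise ParseError(
                            f"{term_def_path}:{lineno}: expected 2 columns, got {len(cols)}"
                        )
                    term_defs[cols[0]] = cols[1]
        return cls(term_defs=term_defs, gene_terms=gene_terms)


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one term in a target selection.

    k of the n selected genes carry the term; K of the N background genes
    do.  ``p_raw`` is the hypergeometric tail, ``p_ease`` its one-removed
    variant (always >= p_raw), and ``q`` the BH-adjusted value.
    """

    term_id: str
    description: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_ease: float
    q: float


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValidationError(f"invalid hypergeometric counts k={k} n={n} K={K} N={N}")
    if k > K:
        raise ValidationError(f"k={k} exceeds background hits K={K}")


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    _check_counts(k, n, K, N)
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates this in stable log space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """Conservative one-removed tail: hypergeom_tail(max(k-1, 0), n, K, N).

    Equals 1 whenever k <= 1, so singleton overlaps never look enriched.
    """
    _check_counts(k, n, K, N)
    return hypergeom_tail(max(k - 1, 0), n, K, N)


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def enrich_targets(
    net: RegulatoryNetwork,
    srna_id: str,
    catalog: AnnotationCatalog,
    background: set[str] | None = None,
    use_ease: bool = True,
) -> list[EnrichmentResult]:
    """Term enrichment of one sRNA's distinct mRNA targets.

    ``background`` defaults to all mRNA nodes of the network and must
    contain every target.  One result is returned per term with at least
    one background hit, sorted by ascending p_ease (ties by term_id).
    q-values are BH-adjusted on p_ease by default (``use_ease=False``
    switches to p_raw).
    """
    node = net.nodes.get(srna_id)
    if node is None or node.role != "sRNA":
        raise MissingNodeError(f"unknown sRNA {srna_id!r}")
    selection = {it.mrna_id for it in net.interactions if it.srna_id == srna_id}
    if not selection:
        return []
    if background is None:
        background = set(net.mrna_ids())
    else:
        background = set(background)
    if not selection <= background:
        raise ValidationError(
            f"background is missing target genes: {sorted(selection - background)[:5]}"
        )
    N = len(background)
    n = len(selection)
    terms = sorted({t for g in background for t in catalog.terms_of(g)})
    rows = []
    for term in terms:
        carriers = catalog.genes_with(term, background)
        K = len(carriers)
        if K < 1:
            continue
        k = len(carriers & selection)
        p_raw = hypergeom_tail(k, n, K, N)
        p_ease = ease_score(k, n, K, N)
        rows.append((term, k, K, p_raw, p_ease))
    qs = bh_adjust([(r[4] if use_ease else r[3]) for r in rows])
    results = [
        EnrichmentResult(
            term_id=term,
            description=catalog.term_defs.get(term, term),
            k=k, n=n, K=K, N=N,
            p_raw=p_raw, p_ease=p_ease, q=q,
        )
        for (term, k, K, p_raw, p_ease), q in zip(rows, qs)
    ]
    results.sort(key=lambda r: (r.p_ease, r.term_id))
    return results


def results_to_tsv(results: list[EnrichmentResult]) -> str:
    header = "term_id\tdescription\tk\tn\tK\tN\tp_raw\tp_ease\tq"
    lines = [header]
    for r in results:
        lines.append(
            f"{r.term_id}\t{r.description}\t{r.k}\t{r.n}\t{r.K}\t{r.N}"
            f"\t{r.p_raw:.6g}\t{r.p_ease:.6g}\t{r.q:.6g}"
        )
    return "\n".join(lines) + "\n"
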