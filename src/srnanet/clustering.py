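"""Clustering one RNA's interactions by region proximity or annotation.

Two interactions of the same RNA are *similar* when their interacting
regions on that RNA overlap heavily (region mode) or when their partner
mRNAs share annotation terms (annotation mode).  Both distances are
Jaccard distances (1 - |A∩B|/|A∪B|), hence metrics on their domains.
Similarity = 1 - distance feeds a Markov clustering (MCL) of the
interaction set: random-walk flow on the similarity graph is alternately
expanded (matrix power) and inflated (entrywise power + column
renormalization) until it converges to a forest of attractor systems,
each of which is one cluster.

Region mode recovers groups of interactions sharing a binding site on
the RNA — e.g. an sRNA with two distinct seed regions yields two
clusters whose spans frame those seeds.  Cluster spans may overlap each
other; that is biologically expected when binding sites abut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MissingNodeError, ValidationError
from .model import Region, RegulatoryNetwork

__all__ = [
    "McParams",
    "InteractionCluster",
    "region_distance",
    "annotation_distance",
    "mcl",
    "cluster_interactions",
    "clusters_to_tsv",
]


@dataclass(frozen=True)
class McParams:
    """MCL parameters (canonical defaults: expansion 2, inflation 2.0).

    ``prune_below`` zeroes tiny flow entries between iterations for
    sparsity; ``self_loop`` is the weight added to each diagonal before
    normalization so singletons are their own attractors.
    """

    expansion: int = 2
    inflation: float = 2.0
    prune_below: float = 1e-5
    max_iter: int = 100
    tol: float = 1e-8
    self_loop: float = 1.0

    def __post_init__(self) -> None:
        if self.expansion < 2:
            raise ValidationError("expansion must be >= 2")
        if self.inflation <= 1:
            raise ValidationError("inflation must be > 1")
        if self.tol <= 0:
            raise ValidationError("tol must be positive")


@dataclass(frozen=True)
class InteractionCluster:
    """A group of one RNA's interactions with its covering span."""

    focal_rna: str
    members: frozenset[str]  # interaction keys
    span: Region
    color_index: int


def region_distance(a: Region, b: Region) -> float:
    """Jaccard distance between two intervals as integer position sets."""
    inter = a.intersection_size(b)
    union = len(a) + len(b) - inter
    return 1.0 - inter / union


def annotation_distance(a: set[str], b: set[str]) -> float:
    """Jaccard distance between term sets; two empty sets are maximally
    dissimilar (1.0) so unannotated partners never cluster spuriously."""
    if not a and not b:
        return 1.0
    inter = len(set(a) & set(b))
    union = len(set(a) | set(b))
    return 1.0 - inter / union


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=0)
    dead = sums == 0
    if np.any(dead):
        # a column with no flow keeps its mass on the diagonal
        M = M.copy()
        M[np.where(dead)[0], np.where(dead)[0]] = 1.0
        sums = M.sum(axis=0)
    return M / sums


def mcl(similarity: np.ndarray, p: McParams = McParams()) -> list[set[int]]:
    """Markov clustering of a symmetric non-negative similarity matrix.

    Returns a partition of item indices: disjoint clusters covering all
    items, deterministic for a fixed input ordering.  Clusters are read
    from the converged flow matrix: attractors (rows with positive
    diagonal) and the items they attract form one cluster; attractor
    systems sharing items are merged; any item claimed by several
    systems goes to the one receiving most of its flow (ties to the
    first system in row order).
    """
    A = np.asarray(similarity, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("similarity must be a square matrix")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValidationError("similarity matrix must be symmetric")
    if np.any(A < 0):
        raise ValidationError("similarities must be non-negative")
    n = A.shape[0]
    if n == 0:
        return []
    M = A.copy()
    np.fill_diagonal(M, M.diagonal() + p.self_loop)
    M = _normalize_columns(M)
    for _ in range(p.max_iter):
        new = np.linalg.matrix_power(M, p.expansion)
        new = np.power(new, p.inflation)
        new[new < p.prune_below] = 0.0
        new = _normalize_columns(new)
        delta = float(np.abs(new - M).max())
        M = new
        if delta < p.tol:
            break
    eps = 1e-9
    attractors = [i for i in range(n) if M[i, i] > eps]
    # union attractor systems that share any attracted item
    parent = list(range(len(attractors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rows = [set(np.where(M[i] > eps)[0]) for i in attractors]
    for i in range(len(attractors)):
        for j in range(i + 1, len(attractors)):
            if rows[i] & rows[j]:
                parent[find(i)] = find(j)
    systems: dict[int, set[int]] = {}
    for idx in range(len(attractors)):
        systems.setdefault(find(idx), set()).add(idx)
    cluster_list = []
    for root in sorted(systems, key=lambda r: min(attractors[i] for i in systems[r])):
        members: set[int] = set()
        for i in systems[root]:
            members |= rows[i]
        cluster_list.append(members)
    assigned: dict[int, int] = {}
    for item in range(n):
        claims = [ci for ci, members in enumerate(cluster_list) if item in members]
        if not claims:
            cluster_list.append({item})  # no attractor reaches it: singleton
            assigned[item] = len(cluster_list) - 1
        elif len(claims) == 1:
            assigned[item] = claims[0]
        else:
            flows = [
                sum(M[a, item] for a in cluster_list[ci] if a in set(attractors))
                for ci in claims
            ]
            assigned[item] = claims[int(np.argmax(flows))]
    out: dict[int, set[int]] = {}
    for item, ci in assigned.items():
        out.setdefault(ci, set()).add(item)
    return [out[ci] for ci in sorted(out)]


def cluster_interactions(
    net: RegulatoryNetwork,
    rna_id: str,
    mode: str = "region",
    p: McParams = McParams(),
    sim_threshold: float = 0.0,
) -> list[InteractionCluster]:
    """MCL-cluster the interactions of one RNA.

    ``mode='region'`` measures similarity between the interactions'
    regions on the focal RNA; ``mode='annotation'`` between the partner
    mRNAs' term sets.  Pairwise similarity is 1 - distance; values <=
    ``sim_threshold`` are zeroed before clustering.  Clusters are
    ordered by span start (ties by smallest member key) and that order
    is the stable ``color_index``.
    """
    if mode not in ("region", "annotation"):
        raise ValidationError(f"mode must be region or annotation, got {mode!r}")
    if rna_id not in net.nodes:
        raise MissingNodeError(f"unknown RNA {rna_id!r}")
    items = sorted(net.interactions_of(rna_id), key=lambda it: it.key)
    if not items:
        return []
    focal_is_srna = net.nodes[rna_id].role == "sRNA"

    def focal_region(it) -> Region:
        return it.srna_region if focal_is_srna else it.mrna_region

    n = len(items)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if mode == "region":
                d = region_distance(focal_region(items[i]), focal_region(items[j]))
            else:
                partner_i = items[i].mrna_id if focal_is_srna else items[i].srna_id
                partner_j = items[j].mrna_id if focal_is_srna else items[j].srna_id
                d = annotation_distance(
                    net.nodes[partner_i].terms, net.nodes[partner_j].terms
                )
            s = 1.0 - d
            if s <= sim_threshold:
                s = 0.0
            sim[i, j] = sim[j, i] = s
    partition = mcl(sim, p)
    clusters = []
    for members in partition:
        regions = [focal_region(items[i]) for i in members]
        span = Region(min(r.start for r in regions), max(r.end for r in regions))
        keys = frozenset(items[i].key for i in members)
        clusters.append((span, min(keys), keys))
    clusters.sort(key=lambda c: (c[0].start, c[1]))
    return [
        InteractionCluster(focal_rna=rna_id, members=keys, span=span, color_index=i)
        for i, (span, _first, keys) in enumerate(clusters)
    ]


def clusters_to_tsv(clusters: list[InteractionCluster]) -> str:
    lines = ["focal_rna\tcluster_index\tmembers\tspan_start\tspan_end"]
    for c in clusters:
        lines.append(
            f"{c.focal_rna}\t{c.color_index}\t{','.join(sorted(c.members))}"
            f"\t{c.span.start}\t{c.span.end}"
        )
    return "\n".join(lines) + "\n"
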