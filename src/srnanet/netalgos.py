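"""Filter, Calculation, Coloration and Layout algorithms.

Filters are restrictions: every filter keeps a subset of the input
interactions and induces the sub-network on their endpoints, so filters
are idempotent and compose in any order when their predicates are
independent.  Calculations annotate nodes (degree, betweenness,
per-base interaction coverage); colorations and layouts write display
attributes.  Everything is deterministic.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping

import networkx as nx
from matplotlib import colormaps, colors

from .enrichment import AnnotationCatalog
from .errors import MissingNodeError, ValidationError
from .model import (
    MRNA,
    SRNA,
    Interaction,
    Region,
    RegulatoryNetwork,
    induce_subnetwork,
)

logger = logging.getLogger(__name__)


def _keep(net: RegulatoryNetwork, predicate: Callable[[Interaction], bool]) -> RegulatoryNetwork:
    keys = [it.key for it in net.interactions if predicate(it)]
    return induce_subnetwork(net, keys)


# -- Filter category ---------------------------------------------------


def filter_by_score(net: RegulatoryNetwork, op: str, threshold: float) -> RegulatoryNetwork:
    """Keep interactions whose score satisfies the comparison.

    ``op='le'`` keeps score <= threshold (the natural direction for free
    energies, where more negative means a more stable duplex);
    ``op='ge'`` keeps score >= threshold (natural for alignment scores).
    """
    if op not in ("le", "ge"):
        raise ValidationError(f"score comparator must be 'le' or 'ge', got {op!r}")
    if op == "le":
        return _keep(net, lambda it: it.score <= threshold)
    return _keep(net, lambda it: it.score >= threshold)


def filter_by_region(
    net: RegulatoryNetwork,
    side: str,
    window: Region,
    mode: str = "overlap",
) -> RegulatoryNetwork:
    """Keep interactions whose region on ``side`` ('sRNA' or 'mRNA')
    overlaps (>= 1 shared position) or is contained in ``window``."""
    if side not in (SRNA, MRNA):
        raise ValidationError(f"side must be sRNA or mRNA, got {side!r}")
    if mode not in ("overlap", "contained"):
        raise ValidationError(f"mode must be overlap or contained, got {mode!r}")

    def pred(it: Interaction) -> bool:
        region = it.srna_region if side == SRNA else it.mrna_region
        if mode == "overlap":
            return window.overlaps(region)
        return window.contains(region)

    return _keep(net, pred)


def filter_by_names(
    net: RegulatoryNetwork, ids_or_names: set[str], side: str = "both"
) -> RegulatoryNetwork:
    """Keep interactions with an endpoint matching one of the given ids
    or gene names (case-sensitive) on the requested side."""
    if side not in (SRNA, MRNA, "both"):
        raise ValidationError(f"side must be sRNA, mRNA or both, got {side!r}")
    wanted = set(ids_or_names)

    def node_matches(nid: str) -> bool:
        node = net.nodes[nid]
        return nid in wanted or (node.gene_name is not None and node.gene_name in wanted)

    def pred(it: Interaction) -> bool:
        if side in (SRNA, "both") and node_matches(it.srna_id):
            return True
        if side in (MRNA, "both") and node_matches(it.mrna_id):
            return True
        return False

    out = _keep(net, pred)
    matched = {nid for nid in net.nodes if node_matches(nid)}
    matched_names = matched | {
        net.nodes[nid].gene_name for nid in matched if net.nodes[nid].gene_name
    }
    unmatched = wanted - matched_names
    if unmatched:
        logger.warning("names not found in network: %s", sorted(unmatched))
    return out


def filter_sim_motifs(net: RegulatoryNetwork, min_targets: int) -> RegulatoryNetwork:
    """Single-input-module filter: keep every sRNA regulating at least
    ``min_targets`` distinct mRNAs, with all its interactions."""
    if min_targets < 2:
        raise ValidationError("min_targets must be >= 2")
    targets: dict[str, set[str]] = {}
    for it in net.interactions:
        targets.setdefault(it.srna_id, set()).add(it.mrna_id)
    hubs = {s for s, ms in targets.items() if len(ms) >= min_targets}
    return _keep(net, lambda it: it.srna_id in hubs)


def filter_dor_motifs(
    net: RegulatoryNetwork, min_srnas: int = 2, min_mrnas: int = 2
) -> RegulatoryNetwork:
    """Dense-overlapping-regulon filter.

    Operationally: restrict to mRNAs regulated by >= 2 distinct sRNAs and
    the sRNAs regulating them; keep each connected component of that
    restriction having at least ``min_srnas`` sRNAs and ``min_mrnas``
    mRNAs, with all interactions among kept nodes whose mRNA is
    multiply-regulated in the original network.
    """
    if min_srnas < 2 or min_mrnas < 2:
        raise ValidationError("min_srnas and min_mrnas must be >= 2")
    regulators: dict[str, set[str]] = {}
    for it in net.interactions:
        regulators.setdefault(it.mrna_id, set()).add(it.srna_id)
    shared = {m for m, ss in regulators.items() if len(ss) >= 2}
    g = nx.Graph()
    for it in net.interactions:
        if it.mrna_id in shared:
            g.add_edge(it.srna_id, it.mrna_id)
    kept_nodes: set[str] = set()
    for comp in nx.connected_components(g):
        n_s = sum(1 for nid in comp if net.nodes[nid].role == SRNA)
        n_m = sum(1 for nid in comp if net.nodes[nid].role == MRNA)
        if n_s >= min_srnas and n_m >= min_mrnas:
            kept_nodes |= comp
    return _keep(
        net,
        lambda it: it.mrna_id in shared
        and it.srna_id in kept_nodes
        and it.mrna_id in kept_nodes,
    )


def filter_by_annotation(
    net: RegulatoryNetwork,
    terms_or_keywords: set[str],
    catalog: AnnotationCatalog,
    match: str = "keyword",
) -> RegulatoryNetwork:
    """Keep interactions whose mRNA carries a matching annotation term.

    ``match='term_id'`` requires an exact term id; ``match='keyword'``
    matches a case-insensitive substring of the term description.
    """
    if match not in ("term_id", "keyword"):
        raise ValidationError(f"match must be term_id or keyword, got {match!r}")
    wanted = set(terms_or_keywords)
    if match == "term_id":
        def gene_ok(gene: str) -> bool:
            return bool(catalog.terms_of(gene) & wanted)
    else:
        lowered = {w.lower() for w in wanted}

        def gene_ok(gene: str) -> bool:
            for t in catalog.terms_of(gene):
                desc = catalog.term_defs.get(t, t).lower()
                if any(w in desc for w in lowered):
                    return True
            return False

    return _keep(net, lambda it: gene_ok(it.mrna_id))


# -- Calculation category ----------------------------------------------


def degree(net: RegulatoryNetwork) -> dict[str, int]:
    """Interaction count per node (parallel duplex variants each count)."""
    deg = {nid: 0 for nid in net.nodes}
    for it in net.interactions:
        deg[it.srna_id] += 1
        deg[it.mrna_id] += 1
    return deg


def betweenness(net: RegulatoryNetwork) -> dict[str, float]:
    """Unnormalized shortest-path betweenness (Brandes), undirected,
    parallel edges collapsed, each unordered pair counted once,
    endpoints excluded."""
    g = net.to_graph(multigraph=False)
    return {n: float(v) for n, v in nx.betweenness_centrality(g, normalized=False).items()}


def coverage_curve(net: RegulatoryNetwork, rna_id: str) -> list[int]:
    """Per-base interaction count along one RNA.

    Position p (1-based) of the returned vector holds the number of
    interactions whose region on this RNA contains p.
    """
    node = net.nodes.get(rna_id)
    if node is None:
        raise MissingNodeError(f"unknown RNA {rna_id!r}")
    if node.length is None:
        raise ValidationError(f"RNA {rna_id!r} has no known length")
    curve = [0] * node.length
    for it in net.interactions:
        if it.srna_id == rna_id:
            region = it.srna_region
        elif it.mrna_id == rna_id:
            region = it.mrna_region
        else:
            continue
        for p in range(region.start - 1, min(region.end, node.length)):
            curve[p] += 1
    return curve


# -- Coloration category -----------------------------------------------

ROLE_COLORS = {SRNA: "#4477dd", MRNA: "#ee8822"}  # blue regulators, orange targets


def colorize(
    net: RegulatoryNetwork,
    measure: Mapping[str, float] | None = None,
    palette: str = "viridis",
) -> RegulatoryNetwork:
    """Write a ``color`` attr (hex string) on every node.

    With no measure, nodes get the two role colors.  With a measure, its
    values are min-max normalized and mapped through the named
    matplotlib colormap; nodes missing from the measure default to 0.
    """
    out = net.copy()
    if measure is None:
        for node in out.nodes.values():
            node.attrs["color"] = ROLE_COLORS[node.role]
        return out
    cmap = colormaps[palette]
    vals = {nid: float(measure.get(nid, 0.0)) for nid in out.nodes}
    lo, hi = min(vals.values()), max(vals.values())
    span = hi - lo
    for nid, node in out.nodes.items():
        x = 0.5 if span == 0 else (vals[nid] - lo) / span
        node.attrs["color"] = colors.to_hex(cmap(x))
    return out


# -- Layout category ---------------------------------------------------


def layout_bipartite(net: RegulatoryNetwork, rounds: int = 4) -> dict[str, tuple[float, float]]:
    """Two-column layout: sRNAs at x=0, mRNAs at x=1.

    Vertical order within each column reduces edge crossings by repeated
    barycenter sweeps (ties broken by node id); connected components are
    stacked vertically without interleaving.  Deterministic.
    """
    g = net.to_graph()
    pos: dict[str, tuple[float, float]] = {}
    y_offset = 0.0
    components = sorted(nx.connected_components(g), key=lambda c: min(c))
    isolated = sorted(set(net.nodes) - set(g.nodes))
    for comp in components:
        srnas = sorted(n for n in comp if net.nodes[n].role == SRNA)
        mrnas = sorted(n for n in comp if net.nodes[n].role == MRNA)
        order = {n: i for i, n in enumerate(srnas)}
        order.update({n: i for i, n in enumerate(mrnas)})
        for _ in range(rounds):
            for column in (mrnas, srnas):
                bary = {}
                for n in column:
                    nbrs = list(g.neighbors(n))
                    bary[n] = (
                        sum(order[v] for v in nbrs) / len(nbrs) if nbrs else order[n]
                    )
                column.sort(key=lambda n: (bary[n], n))
                for i, n in enumerate(column):
                    order[n] = i
        height = max(len(srnas), len(mrnas), 1)
        for i, n in enumerate(srnas):
            pos[n] = (0.0, y_offset + i * height / max(len(srnas), 1))
        for i, n in enumerate(mrnas):
            pos[n] = (1.0, y_offset + i * height / max(len(mrnas), 1))
        y_offset += height + 1.0
    for n in isolated:
        x = 0.0 if net.nodes[n].role == SRNA else 1.0
        pos[n] = (x, y_offset)
        y_offset += 1.0
    return pos


def apply_layout(net: RegulatoryNetwork) -> RegulatoryNetwork:
    """Layout written into node attrs ``x`` and ``y`` (new network)."""
    pos = layout_bipartite(net)
    out = net.copy()
    for nid, (x, y) in pos.items():
        out.nodes[nid].attrs["x"] = x
        out.nodes[nid].attrs["y"] = y
    return out
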