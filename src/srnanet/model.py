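"""Bipartite sRNA–mRNA regulatory network data model.

A regulatory network is a strictly bipartite attributed graph: one node
class for small regulatory RNAs (sRNAs), one for their candidate mRNA
targets, and one edge per putative sRNA–mRNA duplex.  Each edge carries
the interval of both RNA sequences engaged in the predicted duplex and a
method-dependent score (a free energy in kcal/mol for energy-based
predictors, an alignment score for the built-in antisense aligner).

Edge identity includes both regions, so a single sRNA–mRNA pair may carry
several alternative duplex predictions (e.g. suboptimal hits).

All coordinates are 1-based inclusive.  mRNA coordinates refer to the
extracted 5'UTR sequence, not the genome; genomic provenance lives in the
node's ``attrs`` map.

Networks are treated as immutable inputs by every algorithm in this
package: operations return new networks and never mutate their argument.
That discipline is what makes exploration-tree states replayable.
"""

from __future__ import annotations

import copy
import hashlib
import io
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .errors import (
    BipartitenessError,
    DuplicateInteractionError,
    MissingNodeError,
    ParseError,
    RegionError,
    ValidationError,
)

logger = logging.getLogger(__name__)

SRNA = "sRNA"
MRNA = "mRNA"

_FORMAT = "srnanet-network"
_VERSION = 1

Scalar = str | int | float | bool


@dataclass(frozen=True, order=True)
class Region:
    """A 1-based inclusive interval on an RNA's primary sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise RegionError(f"region bounds must be integers, got {self!r}")
        if not 1 <= self.start <= self.end:
            raise RegionError(
                f"invalid region [{self.start},{self.end}]: need 1 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return self.start <= other.end and other.start <= self.end

    def contains(self, other: "Region") -> bool:
        """True if *other* lies entirely inside this interval."""
        return self.start <= other.start and other.end <= self.end

    def intersection_size(self, other: "Region") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class RnaNode:
    """One RNA of the network, either a regulator (sRNA) or a target (mRNA).

    ``sequence`` is optional; when present it is an uppercase IUPAC RNA
    string (T is normalized to U on construction) and ``length`` must
    equal its character count.  ``terms`` holds flat annotation-term ids.
    ``attrs`` is an open scalar map used by coloration/layout outputs and
    for provenance (e.g. genomic coordinates of an extracted 5'UTR).
    """

    id: str
    role: str
    gene_name: str | None = None
    sequence: str | None = None
    length: int | None = None
    terms: set[str] = field(default_factory=set)
    attrs: dict[str, Scalar] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in (SRNA, MRNA):
            raise ValidationError(f"node {self.id!r}: role must be sRNA or mRNA, got {self.role!r}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("T", "U")
            if self.length is None:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise ValidationError(
                    f"node {self.id!r}: length {self.length} != sequence length {len(self.sequence)}"
                )
        if self.length is not None and self.length <= 0:
            raise ValidationError(f"node {self.id!r}: length must be positive")
        self.terms = set(self.terms)

    def copy(self) -> "RnaNode":
        return RnaNode(
            id=self.id,
            role=self.role,
            gene_name=self.gene_name,
            sequence=self.sequence,
            length=self.length,
            terms=set(self.terms),
            attrs=dict(self.attrs),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RnaNode):
            return NotImplemented
        return (
            self.id == other.id
            and self.role == other.role
            and self.gene_name == other.gene_name
            and self.sequence == other.sequence
            and self.length == other.length
            and self.terms == other.terms
            and self.attrs == other.attrs
        )


@dataclass
class Interaction:
    """One putative sRNA–mRNA duplex.

    ``method`` records how the interaction was obtained: ``intarna`` for an
    imported energy-based prediction table, ``antisense_align`` for the
    built-in local antisense aligner, or ``manual``.
    """

    srna_id: str
    mrna_id: str
    srna_region: Region
    mrna_region: Region
    score: float
    method: str = "manual"
    attrs: dict[str, Scalar] = field(default_factory=dict)

    METHODS = ("intarna", "antisense_align", "manual")

    def __post_init__(self) -> None:
        if self.method not in self.METHODS:
            raise ValidationError(f"unknown interaction method {self.method!r}")
        self.score = float(self.score)

    @property
    def key(self) -> str:
        """Stable edge identity: endpoints plus both duplex regions."""
        return (
            f"{self.srna_id}|{self.mrna_id}"
            f"|{self.srna_region.start}-{self.srna_region.end}"
            f"|{self.mrna_region.start}-{self.mrna_region.end}"
        )

    def copy(self) -> "Interaction":
        return Interaction(
            srna_id=self.srna_id,
            mrna_id=self.mrna_id,
            srna_region=self.srna_region,
            mrna_region=self.mrna_region,
            score=self.score,
            method=self.method,
            attrs=dict(self.attrs),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interaction):
            return NotImplemented
        return (
            self.key == other.key
            and self.score == other.score
            and self.method == other.method
            and self.attrs == other.attrs
        )


@dataclass
class RegulatoryNetwork:
    """A bipartite attributed sRNA–mRNA interaction network."""

    nodes: dict[str, RnaNode] = field(default_factory=dict)
    interactions: list[Interaction] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    # -- construction -------------------------------------------------

    def add_node(self, node: RnaNode) -> None:
        if node.id in self.nodes:
            raise ValidationError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node

    def interaction_keys(self) -> list[str]:
        return [it.key for it in self.interactions]

    def get_interaction(self, key: str) -> Interaction:
        for it in self.interactions:
            if it.key == key:
                return it
        raise KeyError(key)

    def srna_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.role == SRNA]

    def mrna_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.role == MRNA]

    def interactions_of(self, rna_id: str) -> list[Interaction]:
        if rna_id not in self.nodes:
            raise MissingNodeError(f"unknown RNA {rna_id!r}")
        return [
            it for it in self.interactions if rna_id in (it.srna_id, it.mrna_id)
        ]

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(
            nodes={nid: n.copy() for nid, n in self.nodes.items()},
            interactions=[it.copy() for it in self.interactions],
            meta=copy.deepcopy(self.meta),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and sorted(self.interactions, key=lambda i: i.key)
            == sorted(other.interactions, key=lambda i: i.key)
            and self.meta == other.meta
        )

    def to_graph(self, multigraph: bool = False) -> nx.Graph:
        """Undirected networkx view; parallel duplex variants are collapsed
        unless ``multigraph`` is set."""
        g: nx.Graph = nx.MultiGraph() if multigraph else nx.Graph()
        for nid, node in self.nodes.items():
            g.add_node(nid, role=node.role)
        for it in self.interactions:
            g.add_edge(it.srna_id, it.mrna_id)
        return g


def validate_network(net: RegulatoryNetwork) -> None:
    """Check all structural invariants; raise ``ValidationError`` on the
    first violation.  Run by the test-suite after every operation."""
    seen: set[str] = set()
    for it in net.interactions:
        for nid, role in ((it.srna_id, SRNA), (it.mrna_id, MRNA)):
            node = net.nodes.get(nid)
            if node is None:
                raise MissingNodeError(f"interaction {it.key}: unknown node {nid!r}")
            if node.role != role:
                raise BipartitenessError(
                    f"interaction {it.key}: node {nid!r} has role {node.role}, expected {role}"
                )
        for region, nid in ((it.srna_region, it.srna_id), (it.mrna_region, it.mrna_id)):
            length = net.nodes[nid].length
            if length is not None and region.end > length:
                raise RegionError(
                    f"interaction {it.key}: region [{region.start},{region.end}] "
                    f"exceeds length {length} of {nid!r}"
                )
        if it.key in seen:
            raise DuplicateInteractionError(f"duplicate interaction {it.key}")
        seen.add(it.key)


def add_interaction(net: RegulatoryNetwork, it: Interaction) -> RegulatoryNetwork:
    """Return a new network with *it* appended.

    Both endpoints must already exist with the correct roles, the regions
    must fit the endpoints' known lengths, and the (endpoints, regions)
    key must be new.
    """
    for nid, role in ((it.srna_id, SRNA), (it.mrna_id, MRNA)):
        node = net.nodes.get(nid)
        if node is None:
            raise MissingNodeError(f"unknown node {nid!r}")
        if node.role != role:
            raise BipartitenessError(
                f"edge {it.srna_id!r}->{it.mrna_id!r} is not sRNA->mRNA: "
                f"{nid!r} has role {node.role}"
            )
    for region, nid in ((it.srna_region, it.srna_id), (it.mrna_region, it.mrna_id)):
        length = net.nodes[nid].length
        if length is not None and region.end > length:
            raise RegionError(
                f"region [{region.start},{region.end}] exceeds length {length} of {nid!r}"
            )
    if any(existing.key == it.key for existing in net.interactions):
        raise DuplicateInteractionError(f"duplicate interaction {it.key}")
    out = net.copy()
    out.interactions.append(it.copy())
    return out


def induce_subnetwork(
    net: RegulatoryNetwork, keep_edges: Iterable[str]
) -> RegulatoryNetwork:
    """Sub-network induced by a set of interaction keys.

    The result contains exactly the kept interactions and their endpoint
    nodes; the input network is unchanged.  Idempotent for a fixed keep
    set.
    """
    keep = set(keep_edges)
    known = set(net.interaction_keys())
    unknown = keep - known
    if unknown:
        raise KeyError(f"unknown interaction keys: {sorted(unknown)}")
    kept = [it.copy() for it in net.interactions if it.key in keep]
    node_ids = {it.srna_id for it in kept} | {it.mrna_id for it in kept}
    return RegulatoryNetwork(
        nodes={nid: net.nodes[nid].copy() for nid in node_ids},
        interactions=kept,
        meta=copy.deepcopy(net.meta),
    )


# -- serialization -----------------------------------------------------


def _node_to_dict(node: RnaNode) -> dict:
    return {
        "id": node.id,
        "role": node.role,
        "gene_name": node.gene_name,
        "sequence": node.sequence,
        "length": node.length,
        "terms": sorted(node.terms),
        "attrs": dict(node.attrs),
    }


def _interaction_to_dict(it: Interaction) -> dict:
    return {
        "srna_id": it.srna_id,
        "mrna_id": it.mrna_id,
        "srna_region": [it.srna_region.start, it.srna_region.end],
        "mrna_region": [it.mrna_region.start, it.mrna_region.end],
        "score": it.score,
        "method": it.method,
        "attrs": dict(it.attrs),
    }


def network_to_dict(net: RegulatoryNetwork) -> dict:
    """Canonical dict form: nodes sorted by id, interactions by key."""
    return {
        "format": _FORMAT,
        "version": _VERSION,
        "meta": net.meta,
        "nodes": [_node_to_dict(net.nodes[nid]) for nid in sorted(net.nodes)],
        "interactions": [
            _interaction_to_dict(it)
            for it in sorted(net.interactions, key=lambda i: i.key)
        ],
    }


def serialize_network(net: RegulatoryNetwork) -> str:
    """Byte-deterministic JSON document (stable key and edge ordering)."""
    return json.dumps(network_to_dict(net), sort_keys=True, indent=2) + "\n"


def network_hash(net: RegulatoryNetwork) -> str:
    """Content address of the canonical serialization (sha256 hex)."""
    return hashlib.sha256(serialize_network(net).encode()).hexdigest()


def network_from_dict(doc: dict) -> RegulatoryNetwork:
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT:
        raise ParseError(f"not a {_FORMAT} document")
    net = RegulatoryNetwork(meta=dict(doc.get("meta", {})))
    try:
        for nd in doc["nodes"]:
            net.add_node(
                RnaNode(
                    id=nd["id"],
                    role=nd["role"],
                    gene_name=nd.get("gene_name"),
                    sequence=nd.get("sequence"),
                    length=nd.get("length"),
                    terms=set(nd.get("terms", [])),
                    attrs=dict(nd.get("attrs", {})),
                )
            )
        for i, ed in enumerate(doc["interactions"]):
            it = Interaction(
                srna_id=ed["srna_id"],
                mrna_id=ed["mrna_id"],
                srna_region=Region(*ed["srna_region"]),
                mrna_region=Region(*ed["mrna_region"]),
                score=ed["score"],
                method=ed.get("method", "manual"),
                attrs=dict(ed.get("attrs", {})),
            )
            for nid, role in ((it.srna_id, SRNA), (it.mrna_id, MRNA)):
                if nid not in net.nodes:
                    raise ParseError(
                        f"interactions[{i}]: references absent node {nid!r}"
                    )
            net.interactions.append(it)
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed network document: missing field {exc}") from exc
    validate_network(net)
    return net


def deserialize_network(document: str) -> RegulatoryNetwork:
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}") from exc
    return network_from_dict(doc)


# -- GraphML export ----------------------------------------------------


def export_graphml(net: RegulatoryNetwork) -> str:
    """GraphML text for generic network viewers.

    Nodes carry role, gene_name and attrs; edges carry both regions (as
    four integer attributes), score and method.  Non-scalar attr values
    are coerced to strings with a logged warning.
    """

    def _coerce(value, where: str):
        if isinstance(value, (str, int, float, bool)):
            return value
        logger.warning("coercing non-scalar attribute %s=%r to string", where, value)
        return str(value)

    g = nx.MultiDiGraph()
    for nid in sorted(net.nodes):
        node = net.nodes[nid]
        data = {"role": node.role}
        if node.gene_name is not None:
            data["gene_name"] = node.gene_name
        if node.length is not None:
            data["length"] = node.length
        if node.terms:
            data["terms"] = ",".join(sorted(node.terms))
        for k, v in node.attrs.items():
            data[k] = _coerce(v, f"{nid}.{k}")
        g.add_node(nid, **data)
    for it in sorted(net.interactions, key=lambda i: i.key):
        data = {
            "srna_start": it.srna_region.start,
            "srna_end": it.srna_region.end,
            "mrna_start": it.mrna_region.start,
            "mrna_end": it.mrna_region.end,
            "score": it.score,
            "method": it.method,
        }
        for k, v in it.attrs.items():
            data[k] = _coerce(v, f"{it.key}.{k}")
        g.add_edge(it.srna_id, it.mrna_id, key=it.key, **data)
    buf = io.BytesIO()
    nx.write_graphml(g, buf)
    return buf.getvalue().decode()
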