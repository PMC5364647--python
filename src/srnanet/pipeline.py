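"""Replayable algorithm pipelines and the exploration tree.

Analyses are sequences of named, parameterized steps drawn from a
registry covering the four algorithm categories (filter, calculation,
coloration, layout).  A pipeline is a left-fold: the output network of
one step is the input of the next.  Pipelines serialize to versioned
JSON documents and replay deterministically.

The exploration tree records provenance: each node is an analysis state
(a network), the root holds the entire input network, and applying a
step at a node adds a child holding the step's output.  Applying a
pipeline grows a branch, one node per step.  Network states are stored
content-addressed (sha256 of the canonical serialization) so identical
states dedupe, and every node's state can be re-derived by replaying
its step path from the root (``verify_session``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

from .errors import ParseError, RegistryError, ValidationError
from .model import (
    Region,
    RegulatoryNetwork,
    deserialize_network,
    network_from_dict,
    network_hash,
    network_to_dict,
    serialize_network,
)
from . import netalgos
from .clustering import McParams, cluster_interactions
from .enrichment import AnnotationCatalog

REGISTRY_VERSION = "1"

_PIPELINE_FORMAT = "srnanet-pipeline"
_SESSION_FORMAT = "srnanet-session"

CATEGORIES = ("filter", "calculation", "coloration", "layout")


@dataclass(frozen=True)
class PipelineStep:
    category: str
    name: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PipelineStep):
            return NotImplemented
        return (
            self.category == other.category
            and self.name == other.name
            and self.params == other.params
        )


# -- operation registry ------------------------------------------------
# Each entry: category, callable(net, params, catalog) -> net', and a
# parameter schema {name: (type, required, allowed-or-None)}.


def _p_region(params: dict) -> Region:
    return Region(int(params["start"]), int(params["end"]))


def _op_filter_score(net, params, catalog):
    return netalgos.filter_by_score(net, params["op"], float(params["threshold"]))


def _op_filter_region(net, params, catalog):
    return netalgos.filter_by_region(
        net, params["side"], _p_region(params), params.get("mode", "overlap")
    )


def _op_filter_names(net, params, catalog):
    return netalgos.filter_by_names(net, set(params["names"]), params.get("side", "both"))


def _op_filter_sim(net, params, catalog):
    return netalgos.filter_sim_motifs(net, int(params["min_targets"]))


def _op_filter_dor(net, params, catalog):
    return netalgos.filter_dor_motifs(
        net, int(params.get("min_srnas", 2)), int(params.get("min_mrnas", 2))
    )


def _op_filter_annotation(net, params, catalog):
    if catalog is None:
        raise ValidationError("filter_by_annotation requires an annotation catalog")
    return netalgos.filter_by_annotation(
        net, set(params["terms"]), catalog, params.get("match", "keyword")
    )


def _op_degree(net, params, catalog):
    out = net.copy()
    for nid, d in netalgos.degree(net).items():
        out.nodes[nid].attrs["degree"] = d
    return out


def _op_betweenness(net, params, catalog):
    out = net.copy()
    for nid, b in netalgos.betweenness(net).items():
        out.nodes[nid].attrs["betweenness"] = b
    return out


def _op_coverage(net, params, catalog):
    rna_id = params["rna_id"]
    curve = netalgos.coverage_curve(net, rna_id)
    out = net.copy()
    out.nodes[rna_id].attrs["coverage"] = ",".join(map(str, curve))
    return out


def _op_cluster(net, params, catalog):
    rna_id = params["rna_id"]
    clusters = cluster_interactions(
        net,
        rna_id,
        mode=params.get("mode", "region"),
        p=McParams(inflation=float(params.get("inflation", 2.0))),
        sim_threshold=float(params.get("sim_threshold", 0.0)),
    )
    out = net.copy()
    index = {key: c.color_index for c in clusters for key in c.members}
    for it in out.interactions:
        if it.key in index:
            it.attrs["cluster"] = index[it.key]
    out.meta.setdefault("clusters", {})[rna_id] = [
        {"index": c.color_index, "span": [c.span.start, c.span.end],
         "members": sorted(c.members)}
        for c in clusters
    ]
    return out


def _op_colorize(net, params, catalog):
    measure_name = params.get("measure")
    if measure_name is None or measure_name == "role":
        return netalgos.colorize(net, None)
    if measure_name == "degree":
        measure = {k: float(v) for k, v in netalgos.degree(net).items()}
    elif measure_name == "betweenness":
        measure = netalgos.betweenness(net)
    else:
        raise ValidationError(f"unknown coloration measure {measure_name!r}")
    return netalgos.colorize(net, measure, params.get("palette", "viridis"))


def _op_layout(net, params, catalog):
    return netalgos.apply_layout(net)


REGISTRY: dict[str, dict] = {
    "filter_by_score": {
        "category": "filter", "fn": _op_filter_score,
        "schema": {"op": (str, True, ("le", "ge")), "threshold": ((int, float), True, None)},
    },
    "filter_by_region": {
        "category": "filter", "fn": _op_filter_region,
        "schema": {
            "side": (str, True, ("sRNA", "mRNA")),
            "start": (int, True, None), "end": (int, True, None),
            "mode": (str, False, ("overlap", "contained")),
        },
    },
    "filter_by_names": {
        "category": "filter", "fn": _op_filter_names,
        "schema": {"names": (list, True, None), "side": (str, False, ("sRNA", "mRNA", "both"))},
    },
    "filter_sim_motifs": {
        "category": "filter", "fn": _op_filter_sim,
        "schema": {"min_targets": (int, True, None)},
    },
    "filter_dor_motifs": {
        "category": "filter", "fn": _op_filter_dor,
        "schema": {"min_srnas": (int, False, None), "min_mrnas": (int, False, None)},
    },
    "filter_by_annotation": {
        "category": "filter", "fn": _op_filter_annotation,
        "schema": {"terms": (list, True, None), "match": (str, False, ("term_id", "keyword"))},
    },
    "degree": {"category": "calculation", "fn": _op_degree, "schema": {}},
    "betweenness": {"category": "calculation", "fn": _op_betweenness, "schema": {}},
    "coverage_curve": {
        "category": "calculation", "fn": _op_coverage,
        "schema": {"rna_id": (str, True, None)},
    },
    "cluster_interactions": {
        "category": "calculation", "fn": _op_cluster,
        "schema": {
            "rna_id": (str, True, None),
            "mode": (str, False, ("region", "annotation")),
            "inflation": ((int, float), False, None),
            "sim_threshold": ((int, float), False, None),
        },
    },
    "colorize": {
        "category": "coloration", "fn": _op_colorize,
        "schema": {"measure": (str, False, None), "palette": (str, False, None)},
    },
    "layout_bipartite": {"category": "layout", "fn": _op_layout, "schema": {}},
}


def validate_step(step: PipelineStep) -> None:
    entry = REGISTRY.get(step.name)
    if entry is None:
        raise RegistryError(
            f"unknown operation {step.name!r}; available: {sorted(REGISTRY)}"
        )
    if entry["category"] != step.category:
        raise ValidationError(
            f"operation {step.name!r} has category {entry['category']!r}, "
            f"not {step.category!r}"
        )
    schema = entry["schema"]
    for pname, value in step.params.items():
        if pname not in schema:
            raise ValidationError(f"step {step.name!r}: unknown parameter {pname!r}")
        ptype, _required, allowed = schema[pname]
        if not isinstance(value, ptype) or isinstance(value, bool):
            raise ValidationError(
                f"step {step.name!r}: parameter {pname!r} must be {ptype}, got {value!r}"
            )
        if allowed is not None and value not in allowed:
            raise ValidationError(
                f"step {step.name!r}: parameter {pname!r} must be one of {allowed}"
            )
    for pname, (ptype, required, _allowed) in schema.items():
        if required and pname not in step.params:
            raise ValidationError(f"step {step.name!r}: missing parameter {pname!r}")


def run_step(
    net: RegulatoryNetwork,
    step: PipelineStep,
    catalog: AnnotationCatalog | None = None,
) -> RegulatoryNetwork:
    """Dispatch one step through the registry; returns a new network."""
    validate_step(step)
    return REGISTRY[step.name]["fn"](net, step.params, catalog)


def run_pipeline(
    net: RegulatoryNetwork,
    steps: list[PipelineStep],
    catalog: AnnotationCatalog | None = None,
) -> list[RegulatoryNetwork]:
    """Left-fold of run_step; returns every intermediate state."""
    for step in steps:
        validate_step(step)
    states: list[RegulatoryNetwork] = []
    current = net
    for i, step in enumerate(steps):
        try:
            current = run_step(current, step, catalog)
        except Exception as exc:
            raise type(exc)(f"pipeline step {i} ({step.name}): {exc}") from exc
        states.append(current)
    return states


# -- pipeline documents ------------------------------------------------


def save_pipeline(steps: list[PipelineStep]) -> str:
    doc = {
        "format": _PIPELINE_FORMAT,
        "version": 1,
        "registry_version": REGISTRY_VERSION,
        "steps": [
            {"category": s.category, "name": s.name, "params": s.params} for s in steps
        ],
    }
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def load_pipeline(document: str) -> list[PipelineStep]:
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid pipeline JSON: {exc.msg} (line {exc.lineno})") from exc
    if not isinstance(doc, dict) or doc.get("format") != _PIPELINE_FORMAT:
        raise ParseError(f"not a {_PIPELINE_FORMAT} document")
    steps = []
    for i, sd in enumerate(doc.get("steps", [])):
        try:
            step = PipelineStep(
                category=sd["category"], name=sd["name"], params=dict(sd.get("params", {}))
            )
        except (KeyError, TypeError, ValidationError) as exc:
            raise ParseError(f"steps[{i}]: {exc}") from exc
        validate_step(step)
        steps.append(step)
    return steps


# -- exploration tree / session ----------------------------------------


@dataclass
class ExplorationNode:
    """One analysis state.  ``note`` defaults to the producing step's
    name (the root is labelled 'root')."""

    id: str
    parent_id: str | None
    step: PipelineStep | None
    network_ref: str
    note: str


@dataclass
class Session:
    nodes: dict[str, ExplorationNode]
    networks: dict[str, RegulatoryNetwork]
    root_id: str
    registry_version: str = REGISTRY_VERSION
    seed: int = 0
    _counter: int = 0


def new_session(net: RegulatoryNetwork, seed: int = 0) -> Session:
    ref = network_hash(net)
    root = ExplorationNode(id="n0000", parent_id=None, step=None, network_ref=ref, note="root")
    return Session(
        nodes={root.id: root},
        networks={ref: net.copy()},
        root_id=root.id,
        seed=seed,
        _counter=1,
    )


def tree_apply(
    session: Session,
    node_id: str,
    steps: PipelineStep | list[PipelineStep],
    catalog: AnnotationCatalog | None = None,
) -> Session:
    """Apply a step (one child) or a pipeline (a chain of children) at a
    node.  Existing nodes and their networks are never mutated."""
    if node_id not in session.nodes:
        raise ValidationError(f"unknown exploration node {node_id!r}")
    if isinstance(steps, PipelineStep):
        steps = [steps]
    current_net = session.networks[session.nodes[node_id].network_ref]
    parent = node_id
    counter = session._counter
    new_nodes = dict(session.nodes)
    new_networks = dict(session.networks)
    for step in steps:
        current_net = run_step(current_net, step, catalog)
        ref = network_hash(current_net)
        new_networks.setdefault(ref, current_net.copy())
        child = ExplorationNode(
            id=f"n{counter:04d}",
            parent_id=parent,
            step=step,
            network_ref=ref,
            note=step.name,
        )
        new_nodes[child.id] = child
        parent = child.id
        counter += 1
    return Session(
        nodes=new_nodes,
        networks=new_networks,
        root_id=session.root_id,
        registry_version=session.registry_version,
        seed=session.seed,
        _counter=counter,
    )


def set_note(session: Session, node_id: str, note: str) -> Session:
    if node_id not in session.nodes:
        raise ValidationError(f"unknown exploration node {node_id!r}")
    new_nodes = dict(session.nodes)
    old = new_nodes[node_id]
    new_nodes[node_id] = ExplorationNode(
        id=old.id, parent_id=old.parent_id, step=old.step,
        network_ref=old.network_ref, note=note,
    )
    return Session(
        nodes=new_nodes, networks=dict(session.networks), root_id=session.root_id,
        registry_version=session.registry_version, seed=session.seed,
        _counter=session._counter,
    )


def save_session(session: Session) -> str:
    """Byte-deterministic session document."""
    for node in session.nodes.values():
        if node.network_ref not in session.networks:
            raise ValidationError(
                f"node {node.id}: dangling network_ref {node.network_ref[:12]}..."
            )
    doc = {
        "format": _SESSION_FORMAT,
        "version": 1,
        "registry_version": session.registry_version,
        "seed": session.seed,
        "root_id": session.root_id,
        "counter": session._counter,
        "nodes": {
            nid: {
                "parent_id": node.parent_id,
                "step": (
                    None if node.step is None else
                    {"category": node.step.category, "name": node.step.name,
                     "params": node.step.params}
                ),
                "network_ref": node.network_ref,
                "note": node.note,
            }
            for nid, node in session.nodes.items()
        },
        "networks": {
            ref: network_to_dict(net) for ref, net in session.networks.items()
        },
    }
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def load_session(document: str) -> Session:
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid session JSON: {exc.msg} (line {exc.lineno})") from exc
    if not isinstance(doc, dict) or doc.get("format") != _SESSION_FORMAT:
        raise ParseError(f"not a {_SESSION_FORMAT} document")
    try:
        networks = {
            ref: network_from_dict(nd) for ref, nd in doc["networks"].items()
        }
        nodes = {}
        for nid, nd in doc["nodes"].items():
            step = None
            if nd["step"] is not None:
                step = PipelineStep(
                    category=nd["step"]["category"],
                    name=nd["step"]["name"],
                    params=dict(nd["step"]["params"]),
                )
            if nd["network_ref"] not in networks:
                raise ParseError(f"node {nid}: unresolved network_ref")
            nodes[nid] = ExplorationNode(
                id=nid, parent_id=nd["parent_id"], step=step,
                network_ref=nd["network_ref"], note=nd["note"],
            )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed session document: {exc}") from exc
    return Session(
        nodes=nodes,
        networks=networks,
        root_id=doc["root_id"],
        registry_version=doc.get("registry_version", REGISTRY_VERSION),
        seed=doc.get("seed", 0),
        _counter=doc.get("counter", len(nodes)),
    )


def step_path(session: Session, node_id: str) -> list[PipelineStep]:
    """The step sequence from the root to a node."""
    path: list[PipelineStep] = []
    nid: str | None = node_id
    while nid is not None:
        node = session.nodes[nid]
        if node.step is not None:
            path.append(node.step)
        nid = node.parent_id
    return list(reversed(path))


def verify_session(
    session: Session, catalog: AnnotationCatalog | None = None
) -> list[str]:
    """Replay every node's step path from the root and compare the
    canonical serialization of the result with the stored state.
    Returns the ids of nodes that fail (empty list = session verified).
    """
    root_net = session.networks[session.nodes[session.root_id].network_ref]
    failures = []
    for nid, node in session.nodes.items():
        replayed = root_net
        for step in step_path(session, nid):
            replayed = run_step(replayed, step, catalog)
        if serialize_network(replayed) != serialize_network(
            session.networks[node.network_ref]
        ):
            failures.append(nid)
    return sorted(failures)
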