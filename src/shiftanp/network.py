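"""Decision-network model: clusters of criteria, sub-criteria and
alternatives, the dependency edges among them, and the comparison contexts
those edges induce.

A *comparison context* is the element "with respect to which" a set of
elements from one cluster is pairwise compared; each context yields one
reciprocal judgment matrix.  An edge ``source -> target`` means the source
is among the elements compared with respect to the target, and its local
priority occupies the supermatrix cell (row = source, column = target).

The bundled shift-work network (7 disorder criteria, 20 complaint
sub-criteria, 3 shift alternatives) ships with structural shorthand:
``hierarchy: true`` expands to goal -> criteria -> sub-criteria ->
alternatives edges, and ``criteria_feedback: true`` adds inner dependence
among the criteria.  The published figure does not enumerate its exact
edge set, so this default is a documented assumption and fully
overridable via an explicit ``edges`` list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "Node",
    "Cluster",
    "DependencyEdge",
    "ComparisonContext",
    "NetworkStructure",
    "NetworkValidationError",
    "PublishedWeightsFixture",
    "load_network",
    "load_shiftwork_network",
    "serialize_network",
    "comparison_contexts",
    "published_fixture",
    "GROUPS",
]

#: Study groups, keyed by shift pattern.
GROUPS = ("nurses_8h", "support_12_24", "security_24_48")

CLUSTER_KINDS = ("criteria", "subcriteria", "alternatives")


class NetworkValidationError(ValueError):
    """A structurally invalid network definition."""


@dataclass(frozen=True)
class Node:
    id: str
    label: str
    cluster_id: str
    #: parent criterion for sub-criteria (hierarchy shorthand); None otherwise
    parent: str | None = None


@dataclass(frozen=True)
class Cluster:
    id: str
    label: str
    kind: str
    member_ids: tuple[str, ...]


@dataclass(frozen=True)
class DependencyEdge:
    """``source`` is compared (with its cluster-mates) with respect to
    ``target``; inner-dependence edges may have source == target's cluster."""

    source: str
    target: str


@dataclass(frozen=True)
class ComparisonContext:
    """One pairwise-comparison task: ``node_ids`` (all from ``cluster_id``)
    compared with respect to ``target``.  Contexts with a single compared
    node carry a forced priority of 1 and need no matrix."""

    id: str
    target: str
    cluster_id: str
    node_ids: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.node_ids)


@dataclass(frozen=True)
class NetworkStructure:
    name: str
    goal: Node
    clusters: tuple[Cluster, ...]
    nodes: dict[str, Node]
    edges: tuple[DependencyEdge, ...]
    metadata: dict = field(default_factory=dict)

    def cluster(self, cluster_id: str) -> Cluster:
        for c in self.clusters:
            if c.id == cluster_id:
                return c
        raise KeyError(cluster_id)

    def cluster_of(self, node_id: str) -> str:
        return self.nodes[node_id].cluster_id

    def by_kind(self, kind: str) -> Cluster:
        hits = [c for c in self.clusters if c.kind == kind]
        if len(hits) != 1:
            raise KeyError(f"expected exactly one {kind} cluster, found {len(hits)}")
        return hits[0]

    @property
    def node_order(self) -> tuple[str, ...]:
        """Supermatrix node ordering: cluster order, then member order.
        The goal is not part of the supermatrix."""
        return tuple(nid for c in self.clusters for nid in c.member_ids)


def _require(cond: bool, msg: str):
    if not cond:
        raise NetworkValidationError(msg)


def load_network(config_source) -> NetworkStructure:
    """Load and validate a network from YAML/JSON (path, text or dict).

    Structural shorthand under ``structure:`` is expanded into explicit
    edges; any explicit ``edges`` entries are appended.  Raises
    :class:`NetworkValidationError` naming the offending key or id.
    """
    cfg = _read_config(config_source)
    for key in ("name", "goal", "clusters"):
        _require(key in cfg, f"network config is missing required key {key!r}")
    goal_cfg = cfg["goal"]
    _require(isinstance(goal_cfg, dict) and goal_cfg.get("id"),
             "key 'goal' must be a mapping with an 'id'")
    goal = Node(id=goal_cfg["id"], label=goal_cfg.get("label", goal_cfg["id"]),
                cluster_id="__goal__")

    nodes: dict[str, Node] = {}
    clusters: list[Cluster] = []
    for c in cfg["clusters"]:
        for key in ("id", "members"):
            _require(key in c, f"cluster entry is missing required key {key!r}")
        kind = c.get("kind", c["id"])
        _require(kind in CLUSTER_KINDS,
                 f"cluster {c['id']!r}: kind must be one of {CLUSTER_KINDS}, got {kind!r}")
        _require(len(c["members"]) >= 1, f"cluster {c['id']!r} has no members")
        member_ids = []
        for m in c["members"]:
            _require(isinstance(m, dict) and m.get("id"),
                     f"cluster {c['id']!r}: each member needs an 'id'")
            nid = m["id"]
            _require(nid and nid not in nodes and nid != goal.id,
                     f"duplicate or empty node id {nid!r}")
            nodes[nid] = Node(id=nid, label=m.get("label", nid), cluster_id=c["id"],
                              parent=m.get("parent"))
            member_ids.append(nid)
        clusters.append(Cluster(id=c["id"], label=c.get("label", c["id"]), kind=kind,
                                member_ids=tuple(member_ids)))

    # resolve parents before expanding shorthand
    for node in nodes.values():
        if node.parent is not None:
            _require(node.parent in nodes,
                     f"node {node.id!r} references missing parent {node.parent!r}")

    edges: list[DependencyEdge] = []
    structure = cfg.get("structure", {})
    if structure.get("hierarchy", False):
        edges.extend(_hierarchy_edges(goal, clusters, nodes))
    if structure.get("criteria_feedback", False):
        crit = [c for c in clusters if c.kind == "criteria"]
        _require(len(crit) == 1, "criteria_feedback requires exactly one criteria cluster")
        for j in crit[0].member_ids:
            for i in crit[0].member_ids:
                if i != j:
                    edges.append(DependencyEdge(source=i, target=j))
    for e in cfg.get("edges", []):
        for key in ("source", "target"):
            _require(key in e, f"edge entry is missing required key {key!r}")
        edges.append(DependencyEdge(source=e["source"], target=e["target"]))

    all_ids = set(nodes) | {goal.id}
    for e in edges:
        _require(e.source in nodes, f"edge references unknown source node {e.source!r}")
        _require(e.target in all_ids, f"edge references unknown target node {e.target!r}")
        _require(e.source != e.target, f"self-edge on {e.source!r}")

    net = NetworkStructure(name=cfg["name"], goal=goal, clusters=tuple(clusters),
                           nodes=nodes, edges=tuple(dict.fromkeys(edges)),
                           metadata=cfg.get("metadata", {}))
    _validate_cover(net)
    return net


def _hierarchy_edges(goal, clusters, nodes) -> list[DependencyEdge]:
    """goal -> criteria -> (sub-criteria ->) alternatives.

    Alternatives are compared with respect to each leaf of the criterion
    tree: a sub-criterion when the criterion has children, the criterion
    itself otherwise.
    """
    edges = []
    by_kind = {c.kind: c for c in clusters}
    _require("criteria" in by_kind, "hierarchy shorthand requires a criteria cluster")
    crit = by_kind["criteria"]
    for cid in crit.member_ids:
        edges.append(DependencyEdge(source=cid, target=goal.id))
    children: dict[str, list[str]] = {cid: [] for cid in crit.member_ids}
    if "subcriteria" in by_kind:
        for sid in by_kind["subcriteria"].member_ids:
            parent = nodes[sid].parent
            _require(parent in children,
                     f"sub-criterion {sid!r} must name a criterion as parent, got {parent!r}")
            children[parent].append(sid)
            edges.append(DependencyEdge(source=sid, target=parent))
    leaves = [sid for cid in crit.member_ids for sid in (children[cid] or [cid])]
    if "alternatives" in by_kind:
        for leaf in leaves:
            for aid in by_kind["alternatives"].member_ids:
                edges.append(DependencyEdge(source=aid, target=leaf))
    return edges


def _validate_cover(net: NetworkStructure):
    """Every cluster node must be compared somewhere (no orphans)."""
    compared = {e.source for e in net.edges}
    orphans = [nid for nid in net.node_order if nid not in compared]
    _require(not orphans,
             f"nodes receive no priority (never compared in any context): {orphans}")


def _read_config(source) -> dict:
    if isinstance(source, dict):
        return source
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise NetworkValidationError(f"config does not parse as YAML/JSON: {exc}") from exc
    _require(isinstance(cfg, dict), "network config must be a mapping")
    return cfg


def load_shiftwork_network(criteria_feedback: bool | None = None) -> NetworkStructure:
    """The bundled shift-work disorder network (7 + 20 + 3 nodes).

    ``criteria_feedback`` overrides the bundled default (inner dependence
    among criteria on); ``False`` gives the pure hierarchy.
    """
    path = resources.files("shiftanp.fixtures") / "shiftwork_network.yaml"
    cfg = yaml.safe_load(path.read_text())
    if criteria_feedback is not None:
        cfg["structure"]["criteria_feedback"] = bool(criteria_feedback)
    return load_network(cfg)


def serialize_network(net: NetworkStructure) -> dict:
    """Explicit-edge dict representation; ``load_network`` round-trips it."""
    return {
        "name": net.name,
        "goal": {"id": net.goal.id, "label": net.goal.label},
        "clusters": [
            {
                "id": c.id,
                "label": c.label,
                "kind": c.kind,
                "members": [
                    {"id": nid, "label": net.nodes[nid].label,
                     **({"parent": net.nodes[nid].parent} if net.nodes[nid].parent else {})}
                    for nid in c.member_ids
                ],
            }
            for c in net.clusters
        ],
        "edges": [{"source": e.source, "target": e.target} for e in net.edges],
        "metadata": dict(net.metadata),
    }


def comparison_contexts(net: NetworkStructure) -> list[ComparisonContext]:
    """All comparison contexts, deterministically ordered.

    Targets are visited goal-first then in supermatrix node order; within
    a target, source clusters follow the network's cluster order.  Context
    ids read ``<cluster>_wrt_<target>``.
    """
    incoming: dict[str, dict[str, list[str]]] = {}
    for e in net.edges:
        incoming.setdefault(e.target, {}).setdefault(net.cluster_of(e.source), []).append(e.source)
    cluster_order = [c.id for c in net.clusters]
    contexts = []
    for target in (net.goal.id, *net.node_order):
        for cid in cluster_order:
            sources = incoming.get(target, {}).get(cid)
            if not sources:
                continue
            member_pos = {nid: k for k, nid in enumerate(net.cluster(cid).member_ids)}
            ordered = tuple(sorted(dict.fromkeys(sources), key=member_pos.__getitem__))
            contexts.append(ComparisonContext(id=f"{cid}_wrt_{target}", target=target,
                                              cluster_id=cid, node_ids=ordered))
    return contexts


# ---------------------------------------------------------------------------
# Published group-level weights (validation fixtures; the underlying raw
# questionnaires were never released, so these are transcriptions, not
# recomputable quantities).

#: printed tables round to 3 decimals; deviations beyond this are flagged
_SUM_WARN_TOL = 0.005


@dataclass(frozen=True)
class PublishedWeightsFixture:
    group: str
    label: str
    criteria: dict[str, float]
    subcriteria: dict[str, dict[str, float]]
    alternatives: dict[str, float]
    warnings: tuple[str, ...] = ()

    @property
    def has_warnings(self) -> bool:
        return bool(self.warnings)


def published_fixture(group: str) -> PublishedWeightsFixture:
    """Published weights for one study group, as printed (3 decimals).

    Sum checks attach warnings — never errors — where a printed weight
    family does not sum to 1 (rounding, or errata such as the security
    group's alternative weights summing to 1.26).
    """
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")
    path = resources.files("shiftanp.fixtures") / "published_weights.yaml"
    data = yaml.safe_load(path.read_text())[group]
    warnings = []

    def check(name, weights):
        s = sum(weights.values())
        if abs(s - 1.0) > _SUM_WARN_TOL:
            warnings.append(f"{group}: printed {name} weights sum to {s:.3f}, not 1")

    check("criterion", data["criteria"])
    for crit, subs in data["subcriteria"].items():
        check(f"sub-criterion ({crit})", subs)
    check("alternative", data["alternatives"])
    return PublishedWeightsFixture(
        group=group, label=data["label"],
        criteria=dict(data["criteria"]),
        subcriteria={k: dict(v) for k, v in data["subcriteria"].items()},
        alternatives=dict(data["alternatives"]),
        warnings=tuple(warnings),
    )
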