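"""Readers and writers for heterogeneous network files.

Three dialects are supported:

* a plain-text format: a ``NODES`` section of ``id label group`` records
  followed by an ``EDGES`` section of ``id1 id2 weight`` records
  (whitespace-separated, ``#`` comments);
* GEXF 1.2 with a per-node ``group`` attribute (edge weights default to 1);
* an internal binary container (NumPy ``.npz`` bundle) holding one
  adjacency table per entity subnetwork, one bipartite table per relation,
  the super-adjacency wiring and the node label lists — the round trip
  through the container is lossless.

Numeric node ids are global across groups; positions within a subnetwork
follow declaration order.  Duplicate edges keep the last occurrence with a
warning; self-loops are stripped by the network model.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import networkx as nx
import numpy as np

from .network import (
    EntitySubnetwork,
    HeterogeneousNetwork,
    RelationSubnetwork,
    validate,
)
from .propagate import RankedResult

__all__ = [
    "ParseError",
    "ContainerError",
    "parse_txt",
    "parse_gexf",
    "write_txt",
    "write_gexf",
    "write_container",
    "read_container",
    "write_results",
]


class ParseError(ValueError):
    """A network input file could not be parsed."""


class ContainerError(ValueError):
    """An internal container file is corrupt or incomplete."""


def _assemble(
    nodes: list[tuple[str, str, str]],
    edges: list[tuple[str, str, float]],
) -> HeterogeneousNetwork:
    """Build a network from (id, label, group) nodes and (id, id, w) edges."""
    group_order: list[str] = []
    members: dict[str, list[str]] = {}
    node_group: dict[str, str] = {}
    node_label: dict[str, str] = {}
    for nid, label, group in nodes:
        if nid in node_group:
            raise ParseError(f"duplicate node id {nid!r}")
        if group not in members:
            group_order.append(group)
            members[group] = []
        node_group[nid] = group
        node_label[nid] = label
        members[group].append(nid)

    pos = {nid: i for group in group_order
           for i, nid in enumerate(members[group])}

    entity_w = {g: np.zeros((len(members[g]),) * 2) for g in group_order}
    relation_w: dict[tuple[str, str], np.ndarray] = {}
    seen_edges: set[tuple[str, str]] = set()

    for a, b, w in edges:
        for nid in (a, b):
            if nid not in node_group:
                raise ParseError(f"edge endpoint {nid!r} is not declared")
        if w < 0:
            raise ParseError(f"negative weight on edge ({a!r}, {b!r})")
        ga, gb = node_group[a], node_group[b]
        if ga == gb:
            key = (min(a, b), max(a, b))
            if key in seen_edges:
                warnings.warn(
                    f"duplicate edge ({a!r}, {b!r}); last occurrence wins",
                    stacklevel=3,
                )
            seen_edges.add(key)
            entity_w[ga][pos[a], pos[b]] = w
            entity_w[ga][pos[b], pos[a]] = w
        else:
            # orient the relation by group declaration order
            if group_order.index(ga) > group_order.index(gb):
                a, b, ga, gb = b, a, gb, ga
            pair = (ga, gb)
            if pair not in relation_w:
                relation_w[pair] = np.zeros(
                    (len(members[ga]), len(members[gb]))
                )
            key = (a, b)
            if key in seen_edges:
                warnings.warn(
                    f"duplicate edge ({a!r}, {b!r}); last occurrence wins",
                    stacklevel=3,
                )
            seen_edges.add(key)
            relation_w[pair][pos[a], pos[b]] = w

    entities = [
        EntitySubnetwork(g, [node_label[n] for n in members[g]], entity_w[g])
        for g in group_order
    ]
    relations = [
        RelationSubnetwork(s, t, w) for (s, t), w in relation_w.items()
    ]
    net = HeterogeneousNetwork(entities, relations)
    problems = validate(net)
    if problems:
        raise ParseError("; ".join(problems))
    return net


def parse_txt(path: str | Path) -> HeterogeneousNetwork:
    """Parse the plain-text network dialect into a heterogeneous network."""
    nodes: list[tuple[str, str, str]] = []
    edges: list[tuple[str, str, float]] = []
    section = None
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            upper = line.upper()
            if upper == "NODES":
                section = "nodes"
                continue
            if upper == "EDGES":
                section = "edges"
                continue
            fields = line.split()
            try:
                if section == "nodes":
                    if len(fields) != 3:
                        raise ValueError("expected: id label group")
                    nodes.append((fields[0], fields[1], fields[2]))
                elif section == "edges":
                    if len(fields) != 3:
                        raise ValueError("expected: id1 id2 weight")
                    edges.append((fields[0], fields[1], float(fields[2])))
                else:
                    raise ValueError("record outside NODES/EDGES section")
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: {exc}") from None
    try:
        return _assemble(nodes, edges)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from None


def parse_gexf(path: str | Path, group_attr: str = "group") -> HeterogeneousNetwork:
    """Parse a GEXF 1.2 graph with a per-node group attribute.

    Edge weights default to 1.0 when absent.  The resulting network equals
    the one parsed from the equivalent plain-text file.
    """
    try:
        graph = nx.read_gexf(str(path), relabel=False)
    except Exception as exc:  # lxml/xml parse failures
        raise ParseError(f"{path}: malformed GEXF ({exc})") from None
    nodes = []
    for nid, data in graph.nodes(data=True):
        if group_attr not in data:
            raise ParseError(
                f"{path}: node {nid!r} is missing the {group_attr!r} attribute"
            )
        nodes.append((str(nid), str(data.get("label", nid)), str(data[group_attr])))
    edges = [
        (str(a), str(b), float(data.get("weight", 1.0)))
        for a, b, data in graph.edges(data=True)
    ]
    try:
        return _assemble(nodes, edges)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from None


def _global_ids(net: HeterogeneousNetwork) -> dict[tuple[str, str], int]:
    """Assign consecutive numeric ids over all nodes, entity by entity."""
    ids = {}
    counter = 0
    for ent in net.entities:
        for label in ent.labels:
            ids[(ent.name, label)] = counter
            counter += 1
    return ids


def write_txt(net: HeterogeneousNetwork, path: str | Path) -> None:
    """Write a network in the plain-text dialect (inverse of parse_txt)."""
    ids = _global_ids(net)
    lines = ["NODES"]
    for ent in net.entities:
        for label in ent.labels:
            lines.append(f"{ids[(ent.name, label)]}\t{label}\t{ent.name}")
    lines.append("EDGES")
    for ent in net.entities:
        w = ent.weights
        for i in range(len(ent)):
            for j in range(i + 1, len(ent)):
                if w[i, j] > 0:
                    a = ids[(ent.name, ent.labels[i])]
                    b = ids[(ent.name, ent.labels[j])]
                    lines.append(f"{a}\t{b}\t{float(w[i, j])!r}")
    for rel in net.relations:
        src = net.entity(rel.source)
        dst = net.entity(rel.target)
        for i, j in np.argwhere(rel.weights > 0):
            a = ids[(rel.source, src.labels[i])]
            b = ids[(rel.target, dst.labels[j])]
            lines.append(f"{a}\t{b}\t{float(rel.weights[i, j])!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gexf(net: HeterogeneousNetwork, path: str | Path) -> None:
    """Write a network as GEXF 1.2 with a per-node ``group`` attribute."""
    ids = _global_ids(net)
    graph = nx.Graph()
    for ent in net.entities:
        for label in ent.labels:
            graph.add_node(
                str(ids[(ent.name, label)]), label=label, group=ent.name
            )
    for ent in net.entities:
        w = ent.weights
        for i in range(len(ent)):
            for j in range(i + 1, len(ent)):
                if w[i, j] > 0:
                    graph.add_edge(
                        str(ids[(ent.name, ent.labels[i])]),
                        str(ids[(ent.name, ent.labels[j])]),
                        weight=float(w[i, j]),
                    )
    for rel in net.relations:
        src = net.entity(rel.source)
        dst = net.entity(rel.target)
        for i, j in np.argwhere(rel.weights > 0):
            graph.add_edge(
                str(ids[(rel.source, src.labels[i])]),
                str(ids[(rel.target, dst.labels[j])]),
                weight=float(rel.weights[i, j]),
            )
    nx.write_gexf(graph, str(path), version="1.2draft")


def write_container(net: HeterogeneousNetwork, path: str | Path) -> None:
    """Serialize a network to the internal key→table binary bundle."""
    payload: dict[str, np.ndarray] = {
        "entity_names": np.array(net.entity_names, dtype=object),
        "super_adjacency": net.super_adjacency,
        "relation_pairs": np.array(
            [[r.source, r.target] for r in net.relations], dtype=object
        ).reshape(len(net.relations), 2),
    }
    for ent in net.entities:
        payload[f"entity:{ent.name}:labels"] = np.array(
            ent.labels, dtype=object
        )
        payload[f"entity:{ent.name}:weights"] = ent.weights
    for rel in net.relations:
        payload[f"relation:{rel.source}:{rel.target}:weights"] = rel.weights
    # write through a handle: savez would append ".npz" to a bare path
    with open(path, "wb") as handle:
        np.savez(handle, **payload)


def read_container(path: str | Path) -> HeterogeneousNetwork:
    """Read a network back from the internal container, validating it."""
    try:
        bundle = np.load(path, allow_pickle=True)
    except Exception as exc:
        raise ContainerError(f"{path}: unreadable container ({exc})") from None
    with bundle:
        for required in ("entity_names", "super_adjacency", "relation_pairs"):
            if required not in bundle:
                raise ContainerError(
                    f"{path}: container is missing its {required} component"
                )
        entities = []
        for name in bundle["entity_names"]:
            lkey = f"entity:{name}:labels"
            wkey = f"entity:{name}:weights"
            if lkey not in bundle or wkey not in bundle:
                raise ContainerError(
                    f"{path}: container is missing tables for entity {name!r}"
                )
            entities.append(
                EntitySubnetwork(
                    str(name),
                    [str(x) for x in bundle[lkey]],
                    bundle[wkey],
                )
            )
        relations = []
        for source, target in bundle["relation_pairs"]:
            wkey = f"relation:{source}:{target}:weights"
            if wkey not in bundle:
                raise ContainerError(
                    f"{path}: container is missing the table of relation "
                    f"{source!r}-{target!r}"
                )
            relations.append(
                RelationSubnetwork(str(source), str(target), bundle[wkey])
            )
    net = HeterogeneousNetwork(entities, relations)
    problems = validate(net)
    if problems:
        raise ContainerError(f"{path}: invalid network: " + "; ".join(problems))
    return net


def write_results(ranked: RankedResult, path: str | Path) -> None:
    """Write a ranking as CSV: rank (1-based), node label, score."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["rank", "label", "score"])
        for rank, (label, score) in enumerate(ranked.rows, start=1):
            writer.writerow([rank, label, repr(score)])
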