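"""Heterogeneous network data model.

A heterogeneous network is a graph-of-subnetworks: weighted undirected
*entity subnetworks* (one per biological entity type, e.g. genes, diseases,
long noncoding RNAs) connected pairwise by bipartite *relation
subnetworks*.  A super-adjacency structure records which relation connects
which pair of entity subnetworks, so that influence can be propagated from
a query subnetwork to a target subnetwork along paths of subnetworks.

Edge weights are non-negative relationship strengths.  Propagation operates
on symmetrically degree-normalized tables ``D^{-1/2} W D^{-1/2}``, whose
spectral radius is at most 1 — a requirement for the restart iteration to
converge.  Zero-degree nodes are retained (their normalized rows stay
zero); self-loops are stripped at construction with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EntitySubnetwork",
    "RelationSubnetwork",
    "HeterogeneousNetwork",
    "SubnetPath",
    "NetworkStructureError",
    "normalize_entity",
    "normalize_relation",
    "find_paths",
    "validate",
]


class NetworkStructureError(ValueError):
    """A structural invariant of the network model is violated."""


def _symmetric_degree_normalize(w: np.ndarray) -> np.ndarray:
    """Return ``D^{-1/2} W D^{-1/2}`` with zero-degree rows left zero."""
    deg = w.sum(axis=1)
    inv_sqrt = np.zeros_like(deg, dtype=float)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    return inv_sqrt[:, None] * w * inv_sqrt[None, :]


def _bipartite_normalize(w: np.ndarray) -> np.ndarray:
    """Normalize a bipartite table by sqrt(row sum * column sum) per cell."""
    r = w.sum(axis=1)
    c = w.sum(axis=0)
    ri = np.zeros_like(r, dtype=float)
    ci = np.zeros_like(c, dtype=float)
    ri[r > 0] = 1.0 / np.sqrt(r[r > 0])
    ci[c > 0] = 1.0 / np.sqrt(c[c > 0])
    return ri[:, None] * w * ci[None, :]


@dataclass(eq=False)
class EntitySubnetwork:
    """A weighted undirected network over nodes of a single entity type.

    Parameters
    ----------
    name:
        Short identifier, unique within the heterogeneous network.
    labels:
        Node labels in declaration order; positions index ``weights``.
    weights:
        Square symmetric non-negative adjacency table, zero diagonal.
    """

    name: str
    labels: list[str]
    weights: np.ndarray
    _normalized: np.ndarray | None = field(default=None, repr=False)
    _profile_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkStructureError(
                f"subnetwork {self.name!r}: adjacency table is not square "
                f"(shape {w.shape})"
            )
        if w.shape[0] != len(self.labels):
            raise NetworkStructureError(
                f"subnetwork {self.name!r}: {len(self.labels)} labels for a "
                f"{w.shape[0]}-node table"
            )
        if len(set(self.labels)) != len(self.labels):
            raise NetworkStructureError(
                f"subnetwork {self.name!r}: duplicate node labels"
            )
        neg = np.argwhere(w < 0)
        if neg.size:
            i, j = neg[0]
            raise NetworkStructureError(
                f"subnetwork {self.name!r}: negative weight between nodes "
                f"{self.labels[i]!r} and {self.labels[j]!r}"
            )
        if not np.allclose(w, w.T):
            bad = np.argwhere(~np.isclose(w, w.T))[0]
            raise NetworkStructureError(
                f"subnetwork {self.name!r}: asymmetric weights at node pair "
                f"({self.labels[bad[0]]!r}, {self.labels[bad[1]]!r})"
            )
        if np.any(np.diag(w) != 0):
            warnings.warn(
                f"subnetwork {self.name!r}: self-loops stripped", stacklevel=2
            )
            np.fill_diagonal(w, 0.0)
        self.weights = w

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def normalized(self) -> np.ndarray:
        if self._normalized is None:
            self._normalized = _symmetric_degree_normalize(self.weights)
        return self._normalized

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"label {label!r} not in subnetwork {self.name!r}"
            ) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EntitySubnetwork):
            return NotImplemented
        return (
            self.name == other.name
            and self.labels == other.labels
            and np.array_equal(self.weights, other.weights)
        )

    __hash__ = object.__hash__


@dataclass(eq=False)
class RelationSubnetwork:
    """Bipartite weighted network connecting two entity subnetworks.

    Rows index nodes of the ``source`` subnetwork, columns nodes of the
    ``target`` subnetwork.  The relation is stored once; traversal in the
    reverse orientation uses the transposed table.
    """

    source: str
    target: str
    weights: np.ndarray
    _normalized: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise NetworkStructureError(
                f"relation {self.source!r}-{self.target!r}: a relation must "
                "connect two distinct entity subnetworks"
            )
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise NetworkStructureError(
                f"relation {self.source!r}-{self.target!r}: table must be 2-D"
            )
        if np.any(w < 0):
            raise NetworkStructureError(
                f"relation {self.source!r}-{self.target!r}: negative weight"
            )
        self.weights = w

    @property
    def name(self) -> str:
        return f"{self.source}-{self.target}"

    @property
    def normalized(self) -> np.ndarray:
        if self._normalized is None:
            self._normalized = _bipartite_normalize(self.weights)
        return self._normalized

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RelationSubnetwork):
            return NotImplemented
        return (
            self.source == other.source
            and self.target == other.target
            and np.array_equal(self.weights, other.weights)
        )

    __hash__ = object.__hash__


@dataclass(eq=False)
class HeterogeneousNetwork:
    """Entity subnetworks wired together by bipartite relations."""

    entities: list[EntitySubnetwork]
    relations: list[RelationSubnetwork]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entities]
        if len(set(names)) != len(names):
            raise NetworkStructureError("duplicate entity subnetwork names")
        seen: set[frozenset] = set()
        for rel in self.relations:
            pair = frozenset((rel.source, rel.target))
            if pair in seen:
                raise NetworkStructureError(
                    f"more than one relation between {rel.source!r} and "
                    f"{rel.target!r}; at most one per entity pair is allowed"
                )
            seen.add(pair)

    @property
    def entity_names(self) -> list[str]:
        return [e.name for e in self.entities]

    def entity(self, name: str) -> EntitySubnetwork:
        for e in self.entities:
            if e.name == name:
                return e
        raise KeyError(f"no entity subnetwork named {name!r}")

    def relation_between(
        self, a: str, b: str
    ) -> tuple[RelationSubnetwork, bool] | None:
        """Relation connecting entities *a* and *b*, with orientation.

        Returns ``(relation, forward)`` where ``forward`` is True when the
        relation is stored with ``a`` as source, or None if the entities
        are not connected.
        """
        for rel in self.relations:
            if rel.source == a and rel.target == b:
                return rel, True
            if rel.source == b and rel.target == a:
                return rel, False
        return None

    @property
    def super_adjacency(self) -> np.ndarray:
        """Square object table: cell (p, q) names the relation joining
        entity subnetworks p and q, or the string ``"none"``."""
        n = len(self.entities)
        names = self.entity_names
        table = np.full((n, n), "none", dtype=object)
        for p in range(n):
            for q in range(n):
                if p == q:
                    continue
                hit = self.relation_between(names[p], names[q])
                if hit is not None:
                    table[p, q] = hit[0].name
        return table

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeterogeneousNetwork):
            return NotImplemented
        return (
            self.entities == other.entities
            and sorted(self.relations, key=lambda r: r.name)
            == sorted(other.relations, key=lambda r: r.name)
        )

    __hash__ = object.__hash__


@dataclass(frozen=True)
class SubnetPath:
    """A simple path through the graph-of-subnetworks.

    ``entity_names`` runs from the query subnetwork to the target
    subnetwork; ``relation_refs`` holds the traversed relations as
    ``(relation_name, forward)`` pairs, one per hop.
    """

    entity_names: tuple[str, ...]
    relation_refs: tuple[tuple[str, bool], ...]

    def __len__(self) -> int:
        return len(self.entity_names)


def normalize_entity(net: EntitySubnetwork) -> EntitySubnetwork:
    """Compute (and cache) the symmetric degree normalization of *net*.

    The normalized table is ``D^{-1/2} W D^{-1/2}`` where ``D`` holds the
    row sums; zero-degree rows and columns stay zero.  Its spectral radius
    is at most 1, which bounds the propagation operator.
    """
    net.normalized  # noqa: B018 - force computation into the cache
    return net


def normalize_relation(rel: RelationSubnetwork) -> RelationSubnetwork:
    """Compute (and cache) the bipartite normalization of *rel*:
    ``N[i, j] = W[i, j] / sqrt(r_i * c_j)`` with r/c the row/column sums."""
    rel.normalized  # noqa: B018
    return rel


def find_paths(
    net: HeterogeneousNetwork, src: str, dst: str, max_len: int
) -> list[SubnetPath]:
    """All simple subnetwork paths from *src* to *dst* of at most
    *max_len* entities, sorted lexicographically by entity-name sequence.
    """
    if src == dst:
        raise ValueError("src and dst must be distinct entity subnetworks")
    net.entity(src), net.entity(dst)  # raise KeyError on unknown names
    if max_len < 2:
        raise ValueError("max_len must be at least 2")

    adjacency: dict[str, list[str]] = {e.name: [] for e in net.entities}
    for rel in net.relations:
        adjacency[rel.source].append(rel.target)
        adjacency[rel.target].append(rel.source)
    for neigh in adjacency.values():
        neigh.sort()

    paths: list[tuple[str, ...]] = []

    def dfs(node: str, trail: list[str]) -> None:
        if node == dst:
            paths.append(tuple(trail))
            return
        if len(trail) == max_len:
            return
        for nxt in adjacency[node]:
            if nxt not in trail:
                trail.append(nxt)
                dfs(nxt, trail)
                trail.pop()

    dfs(src, [src])
    paths.sort()

    out = []
    for trail in paths:
        refs = []
        for a, b in zip(trail, trail[1:]):
            rel, forward = net.relation_between(a, b)  # type: ignore[misc]
            refs.append((rel.name, forward))
        out.append(SubnetPath(trail, tuple(refs)))
    return out


def validate(net: HeterogeneousNetwork) -> list[str]:
    """Collect every invariant violation in *net* (empty list = valid).

    Purely a reporting operation: the network is never mutated.  Structural
    errors that the constructors already reject (non-square tables,
    negative weights, duplicate relations) are re-checked here so that a
    hand-assembled network can be audited in one pass.
    """
    problems: list[str] = []
    sizes = {e.name: len(e) for e in net.entities}

    for ent in net.entities:
        w = ent.weights
        if w.shape != (len(ent), len(ent)):
            problems.append(
                f"entity {ent.name!r}: table shape {w.shape} does not match "
                f"{len(ent)} labels"
            )
            continue
        if not np.allclose(w, w.T):
            bad = np.argwhere(~np.isclose(w, w.T))[0]
            problems.append(
                f"entity {ent.name!r}: asymmetric weights at node pair "
                f"({ent.labels[bad[0]]!r}, {ent.labels[bad[1]]!r})"
            )
        if np.any(w < 0):
            problems.append(f"entity {ent.name!r}: negative weight")
        if np.any(np.diag(w) != 0):
            problems.append(f"entity {ent.name!r}: nonzero diagonal")
        if len(set(ent.labels)) != len(ent.labels):
            problems.append(f"entity {ent.name!r}: duplicate labels")

    for rel in net.relations:
        for side, expect in ((rel.source, rel.weights.shape[0]),
                             (rel.target, rel.weights.shape[1])):
            if side not in sizes:
                problems.append(
                    f"relation {rel.name!r}: unknown entity {side!r}"
                )
            elif sizes[side] != expect:
                problems.append(
                    f"relation {rel.name!r}: table side {expect} does not "
                    f"match entity {side!r} of size {sizes[side]}"
                )
        if np.any(rel.weights < 0):
            problems.append(f"relation {rel.name!r}: negative weight")

    return problems
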