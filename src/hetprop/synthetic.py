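"""Deterministic synthetic heterogeneous networks with planted signal.

The generator emulates the kind of input the engine is built for: a few
entity subnetworks (an A/B/C chain, a star, or a complete wiring) holding
sparse random within-type similarity edges, joined by sparse bipartite
relations.  On top of the random background it *plants* query→target
associations: each planted pair (q, t, strength) is written both as a
direct edge in the first–last relation (the association being predicted)
and as an edge chain through every intermediate subnetwork on one
first→last path, so the association stays recoverable after the direct
edge is withheld in cross-validation.

Noise weights are drawn from Uniform(0.05, 0.5) so planted strengths of
0.6 and above dominate the background.  Everything is reproducible from
the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import write_gexf, write_txt
from .network import (
    EntitySubnetwork,
    HeterogeneousNetwork,
    RelationSubnetwork,
    validate,
)

__all__ = ["FixtureSpec", "generate", "emit_txt", "emit_gexf"]

TOPOLOGIES = ("chain", "star", "complete")


@dataclass(frozen=True)
class FixtureSpec:
    """A stated synthetic world, reproducible from its seed.

    ``planted`` holds (query index in the first subnetwork, target index
    in the last subnetwork, strength in (0, 1]) triples.  ``noise``
    scales the background edge densities; 0 silences the background
    entirely.
    """

    sizes: tuple[int, ...] = (5, 5, 5)
    topology: str = "chain"
    within_density: float = 0.15
    relation_density: float = 0.05
    association_density: float = 0.005
    weight_low: float = 0.05
    weight_high: float = 0.5
    planted: tuple[tuple[int, int, float], ...] = ()
    noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sizes) < 2:
            raise ValueError("need at least two subnetworks")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"topology must be one of {TOPOLOGIES}")
        for d in (self.within_density, self.relation_density,
                  self.association_density):
            if not 0 <= d <= 1:
                raise ValueError("densities must lie in [0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        if len(self.planted) > self.sizes[0] * self.sizes[-1]:
            raise ValueError(
                "more planted pairs than query-target node combinations"
            )
        for q, t, s in self.planted:
            if not 0 <= q < self.sizes[0]:
                raise ValueError(f"planted query index {q} out of range")
            if not 0 <= t < self.sizes[-1]:
                raise ValueError(f"planted target index {t} out of range")
            if not 0 < s <= 1:
                raise ValueError("planted strength must lie in (0, 1]")


def _entity_pairs(spec: FixtureSpec) -> tuple[list[tuple[int, int]], bool]:
    """Wiring of the graph-of-subnetworks, always including (first, last).

    Returns the pair list and whether the direct first-last relation was
    appended on top of the topology.  An appended direct relation models
    the validated query-target association table: its background density
    (spurious associations) is ``association_density``, far sparser than
    the knowledge-link relations of the topology wiring.
    """
    n = len(spec.sizes)
    if spec.topology == "chain":
        pairs = [(i, i + 1) for i in range(n - 1)]
    elif spec.topology == "star":
        pairs = [(0, i) for i in range(1, n)]
    else:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    direct = (0, n - 1)
    appended = direct not in pairs
    if appended:
        pairs.append(direct)  # the query-target association relation
    return pairs, appended


def generate(spec: FixtureSpec) -> HeterogeneousNetwork:
    """Build the network a FixtureSpec describes."""
    rng = np.random.default_rng(spec.seed)
    names = [chr(ord("A") + i) for i in range(len(spec.sizes))]
    offsets = np.concatenate([[0], np.cumsum(spec.sizes)])

    def draw(shape, density):
        mask = rng.random(shape) < density * spec.noise
        w = np.where(
            mask, rng.uniform(spec.weight_low, spec.weight_high, shape), 0.0
        )
        return w

    entities = []
    for idx, (name, size) in enumerate(zip(names, spec.sizes)):
        w = draw((size, size), spec.within_density)
        w = np.triu(w, k=1)
        w = w + w.T
        labels = [str(offsets[idx] + i) for i in range(size)]
        entities.append(EntitySubnetwork(name, labels, w))

    pairs, direct_appended = _entity_pairs(spec)
    n = len(spec.sizes)
    rel_w = {}
    for p, q in pairs:
        density = (
            spec.association_density
            if direct_appended and (p, q) == (0, n - 1)
            else spec.relation_density
        )
        rel_w[(p, q)] = draw((spec.sizes[p], spec.sizes[q]), density)

    # plant associations: a direct first-last edge plus a chain through
    # every intermediate subnetwork on the lexicographically first path
    chain_path = _intermediate_path(pairs, n)
    for k, (q, t, s) in enumerate(spec.planted):
        rel_w[(0, n - 1)][q, t] = max(rel_w[(0, n - 1)][q, t], s)
        if chain_path is not None:
            # intermediates assigned by planted-pair index so distinct
            # pairs use distinct signal chains whenever room allows
            nodes = [q]
            for subnet in chain_path[1:-1]:
                nodes.append(k % spec.sizes[subnet])
            nodes.append(t)
            for (a, b), (na, nb) in zip(
                zip(chain_path, chain_path[1:]), zip(nodes, nodes[1:])
            ):
                if (a, b) in rel_w:
                    rel_w[(a, b)][na, nb] = max(rel_w[(a, b)][na, nb], s)
                else:
                    rel_w[(b, a)][nb, na] = max(rel_w[(b, a)][nb, na], s)

    # a wired relation must carry at least one edge: the text dialect
    # cannot express an edgeless relation, and it would contribute nothing
    for (p, q), w in rel_w.items():
        if not np.any(w > 0):
            i = int(rng.integers(spec.sizes[p]))
            j = int(rng.integers(spec.sizes[q]))
            w[i, j] = rng.uniform(spec.weight_low, spec.weight_high)

    relations = [
        RelationSubnetwork(names[p], names[q], w)
        for (p, q), w in rel_w.items()
    ]
    net = HeterogeneousNetwork(entities, relations)
    problems = validate(net)
    if problems:  # pragma: no cover - generator must emit valid networks
        raise AssertionError("generator produced invalid network: "
                             + "; ".join(problems))
    return net


def _intermediate_path(
    pairs: list[tuple[int, int]], n: int
) -> list[int] | None:
    """A first→last path through at least one intermediate subnetwork."""
    if n < 3:
        return None
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for a, b in pairs:
        adj[a].add(b)
        adj[b].add(a)

    # depth-first, preferring small indices, avoiding the direct hop
    def dfs(node, trail):
        if node == n - 1 and len(trail) > 2:
            return trail
        for nxt in sorted(adj[node]):
            if nxt in trail:
                continue
            if node == 0 and nxt == n - 1:
                continue
            hit = dfs(nxt, trail + [nxt])
            if hit:
                return hit
        return None

    return dfs(0, [0])


def emit_txt(spec: FixtureSpec, path: str | Path) -> HeterogeneousNetwork:
    """Generate the network and write it in the plain-text dialect."""
    net = generate(spec)
    write_txt(net, path)
    return net


def emit_gexf(spec: FixtureSpec, path: str | Path) -> HeterogeneousNetwork:
    """Generate the network and write it as GEXF."""
    net = generate(spec)
    write_gexf(net, path)
    return net
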