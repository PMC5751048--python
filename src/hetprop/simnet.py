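"""Build entity subnetworks from DNA sequences.

Long transcripts (e.g. long noncoding RNAs) can be related to each other
through their k-mer composition: each sequence is described by the counts
of all 4^k DNA words of length k (hexamers by default, 4096 dimensions),
and pairwise cosine similarity between the count vectors becomes the edge
weight of a similarity subnetwork.  Because every pair of sequences shares
some composition, the raw similarity network is dense; a pruning step
removes the weakest half of the edges while refusing any removal that
would break a connected component apart, and isolated nodes can then be
dropped explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from Bio import SeqIO

from .network import EntitySubnetwork

__all__ = [
    "KmerProfile",
    "kmer_profile",
    "profiles_from_fasta",
    "cosine_network",
    "prune_keep_connected",
    "drop_isolated",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class KmerProfile:
    """Occurrence counts of every DNA word of length k in one sequence."""

    sequence_id: str
    k: int
    counts: np.ndarray  # length 4**k, non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (4 ** self.k,):
            raise ValueError(
                f"profile of k={self.k} must have 4^k = {4 ** self.k} entries"
            )

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def kmer_profile(
    seq: str, k: int = 6, sequence_id: str = "", allow_soft_masked: bool = False
) -> KmerProfile:
    """Count every k-long window of *seq* over the alphabet {A, C, G, T}.

    Windows containing any other character — N, gaps, and (unless
    *allow_soft_masked*) lowercase repeat-masked letters — are skipped.
    For an unmasked sequence of length L >= k the counts total L - k + 1.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if allow_soft_masked:
        seq = seq.upper()
    counts = np.zeros(4 ** k, dtype=np.int64)
    if len(seq) < k:
        warnings.warn(
            f"sequence {sequence_id!r} shorter than k={k}; empty profile",
            stacklevel=2,
        )
        return KmerProfile(sequence_id, k, counts)

    # rolling base-4 encoding; any invalid character resets the window
    code = 0
    valid = 0
    mask = 4 ** (k - 1)
    for ch in seq:
        idx = _BASE_INDEX.get(ch)
        if idx is None:
            code = 0
            valid = 0
            continue
        code = (code % mask) * 4 + idx
        valid += 1
        if valid >= k:
            counts[code] += 1
    return KmerProfile(sequence_id, k, counts)


def profiles_from_fasta(
    path: str | Path, k: int = 6, allow_soft_masked: bool = False
) -> list[KmerProfile]:
    """k-mer profiles for every record of a FASTA file, in file order."""
    return [
        kmer_profile(str(rec.seq), k, rec.id, allow_soft_masked)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def cosine_network(
    profiles: list[KmerProfile], name: str = "seq"
) -> EntitySubnetwork:
    """Pairwise cosine-similarity subnetwork over k-mer profiles.

    The adjacency entry (i, j) is the cosine of the two count vectors;
    the diagonal is forced to 0 and all-zero profiles contribute zero
    similarity everywhere.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise ValueError(f"profiles mix different k values: {sorted(ks)}")
    matrix = np.array([p.counts for p in profiles], dtype=float)
    norms = np.linalg.norm(matrix, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = matrix / safe[:, None]
    sims = unit @ unit.T
    sims[norms == 0, :] = 0.0
    sims[:, norms == 0] = 0.0
    np.fill_diagonal(sims, 0.0)
    sims = np.clip((sims + sims.T) / 2.0, 0.0, 1.0)  # numeric symmetry
    np.fill_diagonal(sims, 0.0)
    labels = [p.sequence_id or str(i) for i, p in enumerate(profiles)]
    return EntitySubnetwork(name, labels, sims)


def prune_keep_connected(
    net: EntitySubnetwork, fraction: float
) -> tuple[EntitySubnetwork, int]:
    """Drop the weakest edges without splitting any connected component.

    Edges are visited in ascending weight order (ties by node index) and
    removed greedily, skipping any removal that would disconnect the
    component containing its endpoints, until ``floor(fraction * E)``
    removals are made or no removable edge remains.  Nodes are never
    removed here.  Returns the pruned subnetwork and the number of edges
    actually removed.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    w = net.weights.copy()
    edges = [
        (w[i, j], i, j)
        for i, j in zip(*np.triu_indices(len(net), k=1))
        if w[i, j] > 0
    ]
    budget = int(np.floor(fraction * len(edges)))
    graph = nx.Graph()
    graph.add_nodes_from(range(len(net)))
    graph.add_edges_from((i, j) for _, i, j in edges)

    removed = 0
    for _, i, j in sorted(edges):
        if removed >= budget:
            break
        graph.remove_edge(i, j)
        if nx.has_path(graph, i, j):
            w[i, j] = w[j, i] = 0.0
            removed += 1
        else:
            graph.add_edge(i, j)  # bridge: keep it
    return EntitySubnetwork(net.name, list(net.labels), w), removed


def drop_isolated(net: EntitySubnetwork) -> EntitySubnetwork:
    """Remove zero-degree nodes from a subnetwork (an explicit step,
    separate from pruning)."""
    keep = np.flatnonzero(net.weights.sum(axis=1) > 0)
    labels = [net.labels[i] for i in keep]
    return EntitySubnetwork(net.name, labels, net.weights[np.ix_(keep, keep)])
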