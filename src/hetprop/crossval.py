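"""Cross-validated link prediction on a heterogeneous network.

The harness withholds a fraction of the edges of the query–target relation,
re-runs the prioritization engine from each withheld edge's query node on
the masked network, and measures how highly the withheld target is
recovered.  Three edge-removal regimes control how much correlated
information is withheld alongside each test edge:

* ``normal`` — only the fold's tested edges are removed;
* ``semi_strict`` — additionally, *all* edges from the test edge's query
  node into the target network (the direction of propagation) are removed,
  so synonym/redundant links cannot leak the answer;
* ``strict`` — the semi-strict removal in both directions: every edge
  incident to either endpoint of the test edge is removed.

Performance is reported per fold as ROC/AUC over the pooled score lists,
plus the mean 1-based rank of the withheld target (absolute and as a
percentage of the number of candidates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .network import HeterogeneousNetwork, RelationSubnetwork
from .propagate import PropagationConfig, prioritize

__all__ = [
    "CVConfig",
    "CVReport",
    "make_folds",
    "mask_edges",
    "masked_cells",
    "cross_validate",
    "auc",
]

MODES = ("normal", "semi_strict", "strict")


@dataclass(frozen=True)
class CVConfig:
    """Configuration of a k-fold edge-removal cross-validation run."""

    src: str
    dst: str
    folds: int = 5
    mode: str = "normal"
    seed: int = 0
    propagation: PropagationConfig = field(default_factory=PropagationConfig)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


@dataclass
class CVReport:
    """Results of one cross-validation run."""

    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    ranks: list[int]
    mean_rank: float
    mean_rank_pct: float
    roc_points: np.ndarray  # (n, 2) pooled (FPR, TPR)
    cases: list[dict]  # per-test-edge records
    failures: list[dict]

    def summary(self) -> str:
        return (
            f"mean AUC {self.mean_auc:.4f} +/- {self.sd_auc:.4f} over "
            f"{len(self.fold_aucs)} folds; mean rank {self.mean_rank:.2f} "
            f"({self.mean_rank_pct:.2f}%)"
        )


def _relation_oriented(
    net: HeterogeneousNetwork, src: str, dst: str
) -> tuple[RelationSubnetwork, bool]:
    hit = net.relation_between(src, dst)
    if hit is None:
        raise ValueError(f"no relation between {src!r} and {dst!r}")
    return hit


def _positive_edges(weights: np.ndarray) -> list[tuple[int, int]]:
    return [tuple(idx) for idx in np.argwhere(weights > 0)]


def make_folds(
    rel: RelationSubnetwork, k: int, seed: int
) -> list[list[tuple[int, int]]]:
    """Randomly partition the relation's positive edges into *k* folds.

    Fold sizes differ by at most one; the partition is reproducible from
    *seed*.  Edge indices are (source row, target column) pairs.
    """
    edges = _positive_edges(rel.weights)
    if len(edges) < k:
        raise ValueError(
            f"relation {rel.name!r} has {len(edges)} edges, fewer than "
            f"{k} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    return [
        [edges[i] for i in chunk]
        for chunk in np.array_split(order, k)
    ]


def masked_cells(
    rel_weights: np.ndarray, edge: tuple[int, int], mode: str
) -> set[tuple[int, int]]:
    """The set of positive cells a regime removes for one test edge.

    The edge is given in the propagation orientation: row = query-side
    node, column = target-side node of the src→dst relation.
    """
    q, t = edge
    if rel_weights[q, t] <= 0:
        raise ValueError(f"cell {edge} is not a positive edge")
    cells = {(q, t)}
    if mode in ("semi_strict", "strict"):
        cells |= {(q, j) for j in np.flatnonzero(rel_weights[q, :] > 0)}
    if mode == "strict":
        cells |= {(i, t) for i in np.flatnonzero(rel_weights[:, t] > 0)}
    return cells


def mask_edges(
    net: HeterogeneousNetwork,
    test_edge: tuple[int, int],
    mode: str,
    direction: tuple[str, str],
) -> HeterogeneousNetwork:
    """Non-destructively zero the regime's cells for one test edge.

    *test_edge* indexes (query node, target node) in the direction of
    propagation ``direction = (src, dst)``.  The masked relation is
    re-normalized lazily; entity subnetworks are never masked.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    src, dst = direction
    rel, forward = _relation_oriented(net, src, dst)
    oriented = rel.weights if forward else rel.weights.T
    cells = masked_cells(oriented, test_edge, mode)
    new_w = rel.weights.copy()
    for q, t in cells:
        if forward:
            new_w[q, t] = 0.0
        else:
            new_w[t, q] = 0.0
    return _replace_relation(net, rel, new_w)


def _replace_relation(
    net: HeterogeneousNetwork,
    rel: RelationSubnetwork,
    new_weights: np.ndarray,
) -> HeterogeneousNetwork:
    """Shallow-copy the network, swapping one relation's weight table.

    Entity subnetworks are shared with the original so their normalized
    tables and target-profile caches stay valid.
    """
    relations = [
        RelationSubnetwork(r.source, r.target, new_weights)
        if r is rel
        else r
        for r in net.relations
    ]
    return HeterogeneousNetwork(net.entities, relations)


def auc(positives, negatives) -> float:
    """Mann–Whitney AUC: P(pos > neg) + 0.5 * P(pos == neg).

    Equals the trapezoidal area under the ROC curve.
    """
    positives = np.asarray(positives, dtype=float)
    negatives = np.asarray(negatives, dtype=float)
    if positives.size == 0 or negatives.size == 0:
        raise ValueError("both score classes must be non-empty")
    pooled = np.concatenate([positives, negatives])
    ranks = stats.rankdata(pooled)  # midranks handle ties
    u = ranks[: positives.size].sum() - positives.size * (positives.size + 1) / 2
    return float(u / (positives.size * negatives.size))


def cross_validate(
    net: HeterogeneousNetwork,
    cfg: CVConfig,
    scorer=None,
) -> CVReport:
    """k-fold edge-removal cross-validation of src→dst prioritization.

    For each fold, the fold's edges are removed from the src–dst relation;
    for each removed edge (q, t) the regime's extra masking is applied,
    ``prioritize({q}, src → dst)`` runs on the masked network, and the
    1-based rank of t plus the full score list are recorded.  Candidates
    with no edge to q in the *unmasked* relation are the negatives; known
    positives other than t are excluded.  AUC is computed per fold from
    the pooled scores; ROC points are pooled over all folds.

    *scorer* may replace the propagation engine (for null-model testing):
    a callable ``scorer(masked_net, q_label, src, dst, pcfg) -> scores``
    returning values aligned to the dst label order.
    """
    rel, forward = _relation_oriented(net, cfg.src, cfg.dst)
    oriented = rel.weights if forward else rel.weights.T
    src_net = net.entity(cfg.src)
    dst_net = net.entity(cfg.dst)
    folds = make_folds(rel, cfg.folds, cfg.seed)
    if not forward:
        folds = [[(t, q) for (q, t) in fold] for fold in folds]
        # edges now (query row, target column) in the propagation direction

    fold_aucs: list[float] = []
    ranks: list[int] = []
    cases: list[dict] = []
    failures: list[dict] = []
    pooled_labels: list[np.ndarray] = []
    pooled_scores: list[np.ndarray] = []
    n_cases = 0

    for fold_id, fold in enumerate(folds):
        base_w = rel.weights.copy()
        for q, t in fold:
            if forward:
                base_w[q, t] = 0.0
            else:
                base_w[t, q] = 0.0
        base_net = _replace_relation(net, rel, base_w)

        fold_pos: list[float] = []
        fold_neg: list[float] = []
        for q, t in fold:
            n_cases += 1
            q_label = src_net.labels[q]
            t_label = dst_net.labels[t]
            try:
                if cfg.mode == "normal":
                    masked = base_net
                else:
                    # regime cells are defined on the unmasked relation;
                    # the fold's edges are already gone from base_w
                    cells = masked_cells(oriented, (q, t), cfg.mode)
                    case_w = base_w.copy()
                    for i, j in cells:
                        if forward:
                            case_w[i, j] = 0.0
                        else:
                            case_w[j, i] = 0.0
                    masked = _replace_relation(net, rel, case_w)
                if scorer is None:
                    ranked = prioritize(
                        masked, [q_label], cfg.src, cfg.dst, cfg.propagation
                    )
                    rank = ranked.rank_of(t_label)
                    score_by_label = dict(ranked.rows)
                    scores = np.array(
                        [score_by_label[lab] for lab in dst_net.labels]
                    )
                else:
                    scores = np.asarray(
                        scorer(masked, q_label, cfg.src, cfg.dst,
                               cfg.propagation),
                        dtype=float,
                    )
                    order = sorted(
                        range(len(dst_net)),
                        key=lambda i: (-scores[i], dst_net.labels[i]),
                    )
                    rank = order.index(t) + 1
            except Exception as exc:  # propagation failure on this case
                warnings.warn(
                    f"CV case (query {q_label!r}, target {t_label!r}) "
                    f"failed: {exc}",
                    stacklevel=2,
                )
                failures.append(
                    {"fold": fold_id, "query": q_label, "target": t_label,
                     "error": str(exc)}
                )
                continue

            known = set(np.flatnonzero(oriented[q, :] > 0))
            neg_idx = [
                i for i in range(len(dst_net)) if i not in known
            ]
            fold_pos.append(float(scores[t]))
            fold_neg.extend(float(scores[i]) for i in neg_idx)
            pooled_labels.append(
                np.array([1] + [0] * len(neg_idx))
            )
            pooled_scores.append(
                np.array([scores[t]] + [scores[i] for i in neg_idx])
            )
            ranks.append(rank)
            cases.append(
                {"fold": fold_id, "query": q_label, "target": t_label,
                 "rank": rank, "score": float(scores[t])}
            )

        if fold_pos and fold_neg:
            fold_aucs.append(auc(fold_pos, fold_neg))

    if n_cases and len(failures) > n_cases / 2:
        raise RuntimeError(
            f"{len(failures)} of {n_cases} cross-validation cases failed"
        )

    labels = np.concatenate(pooled_labels) if pooled_labels else np.array([])
    scores_all = (
        np.concatenate(pooled_scores) if pooled_scores else np.array([])
    )
    if labels.size and labels.sum() and labels.sum() < labels.size:
        fpr, tpr, _ = roc_curve(labels, scores_all)
        roc_points = np.column_stack([fpr, tpr])
    else:
        roc_points = np.array([[0.0, 0.0], [1.0, 1.0]])

    mean_rank = float(np.mean(ranks)) if ranks else float("nan")
    return CVReport(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
        sd_auc=(
            float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0
        ),
        ranks=ranks,
        mean_rank=mean_rank,
        mean_rank_pct=100.0 * mean_rank / len(dst_net),
        roc_points=roc_points,
        cases=cases,
        failures=failures,
    )
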