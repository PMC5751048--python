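# Methods

## Model

A heterogeneous network is a pair (D, R): entity subnetworks D (weighted
undirected graphs, one per entity type) and bipartite relation
subnetworks R, at most one per unordered pair of types, stored once and
transposed when traversed in reverse.  Entity weights are non-negative
relationship strengths with zero diagonal; self-loops are stripped at
construction with a warning.  Zero-degree nodes are retained throughout —
real similarity networks contain them, and the engine must tolerate them
rather than fail.

## Propagation

Within a subnetwork the engine iterates

    F ← α S F + (1 − α) F₀,    S = D^(−1/2) W D^(−1/2),

to the fixed point of (I − αS) F = (1 − α) F₀.  The symmetric degree
normalization is a deliberate choice — the standard operator for flow
propagation / RWR-style diffusion — and is isolated behind the
`normalized` property so alternative kernels can be plugged in.  Its
spectral radius is ≤ 1, which makes the iteration a contraction for any
α ∈ (0, 1).  Zero-degree rows stay zero; consequently influence mass
leaks at such nodes and the stationary vector of an isolated seeded node
is (1 − α) F₀, not F₀.  Total mass is therefore ≤ 1, with equality when
the seeded component has no zero-degree sinks.

Across a relation, values are projected through the bipartite table
normalized per cell by √(rᵢ·cⱼ) (row and column sums); nodes without
cross-edges receive 0.  The bipartite normalization is the natural
two-sided analogue of the within-network operator; nothing in the model
prescribes it uniquely, so it too is a committed, replaceable choice.

### Parameters

| parameter      | default | meaning |
|----------------|---------|---------|
| `alpha`        | 0.5     | fraction of flow following edges per step; 1 − α restarts at the seed. Unitless, (0, 1). |
| `tol`          | 1e−8    | L1 threshold on successive iterates; matches the linear-solve oracle tolerance used in tests. |
| `max_iter`     | 1000    | iteration cap; non-convergence returns the last iterate with a warning. |
| `corr`         | pearson | scoring correlation; spearman selectable. |
| `path_combine` | mean    | merge rule for per-path arrivals; averaging prevents one uninformative path from dominating. |
| `max_path_len` | 5       | entity count cap for path enumeration. |

The restart weight, convergence criterion, seed normalization and
multi-path combination rule are all under-determined by the method's
published descriptions; each is a config field rather than a constant.

### Prioritization pipeline

1. Enumerate all simple subnetwork paths from query to target subnetwork
   (≤ `max_path_len` entities), in lexicographic order.
2. Seed the query subnetwork uniformly with 1/|Q| per query node
   (unbiased multi-query seeding; per-node weights are an extension
   point), propagate within it, then alternately project across each
   relation and propagate within each intermediate subnetwork and the
   target.  Arrival values entering an intermediate subnetwork are used
   directly as its (unit-sum renormalized) seed.
3. Max-normalize each path's nonzero arrival vector and merge by
   `path_combine`.
4. Score each target node t by correlating the merged arrival vector with
   t's target profile — the within-target propagation seeded at t alone.
   Profiles are query-independent and cached per (subnetwork, α, tol,
   max_iter).
5. Rank by descending score; ties break by ascending node label so output
   files are deterministic.  Prioritization contains no randomness:
   repeated runs are bit-identical.

Degenerate cases score 0 instead of erroring: a zero-variance profile, a
single-candidate target subnetwork, and the all-zero arrival of a query
disconnected from the target (the result is then flagged).  Disconnected
candidates must still appear in the ranking.

A note on linearity: the un-renormalized pipeline is linear in the seed,
so the multi-query arrival equals the mean of singleton arrivals exactly.
The intermediate renormalization rescales each path's arrival by a
seed-dependent scalar — direction is preserved, raw values are not.  Since
per-path arrivals are max-normalized before combination, the final
ranking is unaffected; the test suite asserts additivity on the linear
operator and direction-equality for the engine.

## Cross-validation

The fold unit is the edge (the relation's positive cells), partitioned
uniformly at random into k near-equal folds, reproducibly from a seed.
For each fold all its edges are removed at once; per test edge (q, t) the
regime then removes, in addition: nothing (normal), every remaining edge
from q into the target network (semi-strict; "direction of propagation"
is read as the query side losing its edges into the target relation), or
those plus every edge into t (strict).  Masked relations are re-normalized
before propagation; entity subnetworks are never masked; masking is
non-destructive (the input network is untouched, and entity objects are
shared so cached target profiles stay valid — masking only alters
relations).

Scoring follows the standard link-prediction protocol: the withheld
target is the positive; target nodes with no edge to q in the *unmasked*
relation are the negatives; q's other known positives are excluded.  AUC
is the Mann–Whitney pair statistic P(pos > neg) + ½P(=), computed per
fold from the fold's pooled scores and reported as mean ± sample standard
deviation over folds; ROC points are pooled over all folds (fold-wise AUC
plus pooled-curve reporting is a committed choice — averaging fold-wise
curves would be equally defensible).  Mean rank is the average 1-based
position of the withheld target in the full ranking; mean rank % divides
by the full target-subnetwork size.  Per-case propagation failures are
recorded and excluded with a warning; a run with more than half its cases
failing raises.

## Sequence-similarity networks

`kmer_profile` counts all 4^k words of length k (default k = 6, 4096
hexamers) in a sliding window; windows containing any non-ACGT character
are skipped, and lowercase (soft-masked) letters count as invalid by
default — consistent with building networks from repeat-masked genomes —
with an opt-out flag.  `cosine_network` turns profiles into a similarity
adjacency (diagonal forced to 0, zero profiles contribute 0).
`prune_keep_connected` removes edges greedily in ascending weight order,
skipping any removal that would disconnect the component containing its
endpoints, until ⌊fraction·E⌋ removals (default intent: half the edges).
The greedy-with-bridge-skipping scheme is a committed reconciliation of
"remove half the edges" with "stay connected"; a global threshold plus
repair pass would be an alternative.  Dropping isolated nodes is a
separate, explicit operation (`drop_isolated`), never folded into pruning.

## Synthetic worlds

The generator emulates the tool's intended inputs: 2–n entity subnetworks
(chain, star or complete wiring) with sparse random within-type edges
(density 0.15), sparse bipartite knowledge relations along the wiring
(density 0.05), and a direct first–last *association* relation carrying
the planted query→target pairs over a much thinner spurious background
(density 0.005).  The separation mirrors real prioritization datasets,
where the cross-validated association table consists almost entirely of
curated true links (at paper scale, hundreds of associations over tens of
millions of possible pairs) while intermediate knowledge links are denser.
Background weights are Uniform(0.05, 0.5) so planted strengths ≥ 0.6
dominate; each planted pair (q, t, s) is written as the direct association
edge plus an edge chain through every intermediate subnetwork on one
first→last path (intermediates assigned deterministically by planted-pair
index, so distinct pairs get distinct chains whenever room allows),
keeping the association recoverable after its direct edge is withheld.
Every wired relation is guaranteed at least one edge (the text dialect
cannot express an edgeless relation).  Generation is a pure function of
the spec; identical specs yield byte-identical container files.

What a green planted-recovery test establishes: the engine recovers
associations whose evidence survives edge removal, on networks with
uniform random background.  What it does not establish: performance on
real data with scale-free degree structure, correlated noise, or the
block structure of ontology-derived similarity networks — none of which
the generator models.

## Numerical choices

* Convergence: L1 norm of successive-iterate difference < `tol`; the
  iterative result agrees with a dense direct solve to 1e−8 L1 on all
  tested graphs (α up to 0.9 with tol tightened to 1e−12 in the oracle
  tests, since the α/(1−α) error amplification at α = 0.9 makes the
  stopping increment an underestimate of the true residual).
* Ties: descending score, then ascending label, everywhere a ranking is
  produced (prioritization, CV ranks, result CSVs).
* Degree normalization divides only positive degrees; no epsilon floors.
* Duplicate edges in input files: last occurrence wins, with a warning.
* Permutation equivariance of normalization holds to machine precision,
  not bitwise: degree sums accumulate in permutation-dependent order.

## Known limitations

* Dense NumPy tables throughout: comfortable to a few thousand nodes per
  subnetwork; very large networks would need the sparse backend the
  design leaves room for.
* One relation per entity pair; multigraphs, directed entity subnetworks
  and signed weights are out of scope.
* Alternative diffusion kernels (heat kernel, Katz) are pluggable by
  design but not implemented.
* The internal container is a NumPy `.npz` bundle; it is documented and
  stable but not byte-compatible with any other tool's matrix format.
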