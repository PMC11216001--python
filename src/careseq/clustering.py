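"""Weighted Ward clustering of sequence dissimilarities into typologies.

Agglomerative clustering where every observation carries an analysis weight
(survey weight), implemented with the weighted Lance-Williams update for the
Ward criterion on squared dissimilarities, using the nearest-neighbour-chain
algorithm (Ward's criterion is reducible, so NN-chain yields the same merge
tree as greedy global search in O(n^2)).

With all weights equal the partition coincides with classical Ward linkage;
with integer weights it coincides with Ward on the correspondingly
replicated sample — both are cross-checked against scipy in the test suite.
Merge ties are broken by the smallest pair of representative indices so
results are reproducible across platforms.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alphabet import TYPOLOGY_NAMES
from .sequences import CostScheme, SequenceSet, aggregate_unique, unique_distances

logger = logging.getLogger(__name__)

STATE_TO_TYPOLOGY_NAME = {
    "None": TYPOLOGY_NAMES["PFF"],
    "FamilyFriends": TYPOLOGY_NAMES["PFF"],
    "Grandparent": TYPOLOGY_NAMES["GP"],
    "PrivateGroup": TYPOLOGY_NAMES["PG"],
    "SingleProfessional": TYPOLOGY_NAMES["SP"],
    "LAGroup": "Local authority group childcare",
    "Other": "Other childcare",
}


@dataclass
class TypologyAssignment:
    """Cluster labels in {1..k} plus the merge tree and optional metadata."""

    labels: np.ndarray                 # (n,) ints in 1..k
    merge_tree: np.ndarray             # (n-1, 4): idx_a, idx_b, height, mass
    k: int
    typology_names: dict[int, str] | None = None
    stability: dict[int, float] | None = None
    _sorted_merges: np.ndarray | None = field(default=None, repr=False)

    def named_labels(self) -> np.ndarray:
        if not self.typology_names:
            raise ValueError("no typology names assigned; run label_typologies first")
        return np.asarray([self.typology_names[int(l)] for l in self.labels])


# ---------------------------------------------------------------------------
# weighted Ward via NN-chain
# ---------------------------------------------------------------------------

def _nn_chain_ward(d2: np.ndarray, w: np.ndarray) -> np.ndarray:
    """NN-chain agglomeration; returns (n-1, 3) raw merges (rep_i, rep_j, height).

    ``d2`` holds the Ward merge criterion between singletons,
    2 w_i w_j / (w_i + w_j) * d_ij^2 (twice the within-cluster sum-of-squares
    increase were d Euclidean), updated in place with the weighted
    Lance-Williams rule; ``w`` holds cluster masses.  Representatives are
    original row indices.
    """
    n = len(w)
    d2 = d2.copy()
    w = w.astype(float).copy()
    active = np.ones(n, dtype=bool)
    np.fill_diagonal(d2, np.inf)
    merges = np.empty((n - 1, 3))
    chain: list[int] = []
    for step in range(n - 1):
        if not chain:
            chain.append(int(np.flatnonzero(active)[0]))
        while True:
            a = chain[-1]
            row = np.where(active, d2[a], np.inf)
            row[a] = np.inf
            b = int(np.argmin(row))  # ties -> smallest index
            if len(chain) > 1 and d2[a, chain[-2]] <= row[b]:
                b = chain[-2]
                break
            chain.append(b)
        chain.pop()
        chain.pop()
        a, b = (a, b) if a < b else (b, a)
        height = d2[a, b]
        merges[step] = (a, b, height)
        # weighted Lance-Williams update for Ward's criterion, result kept in a
        wa, wb = w[a], w[b]
        other = active.copy()
        other[[a, b]] = False
        wk = w[other]
        tot = wa + wb + wk
        d2_new = ((wa + wk) * d2[a, other] + (wb + wk) * d2[b, other] - wk * height) / tot
        d2[a, other] = d2_new
        d2[other, a] = d2_new
        w[a] = wa + wb
        active[b] = False
        d2[b, :] = np.inf
        d2[:, b] = np.inf
    return merges


def _sorted_merge_tree(raw: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order NN-chain merges by height into a scipy-style linkage array.

    Returns (Z, sorted_raw): Z rows are (cluster_a, cluster_b, height, mass)
    with new clusters numbered n, n+1, ... in merge order.
    """
    n = len(w)
    order = np.argsort(raw[:, 2], kind="stable")
    sorted_raw = raw[order]
    parent = np.arange(2 * n - 1)
    cluster_of = np.arange(n)  # current cluster id containing each representative
    mass = np.concatenate([w.astype(float), np.zeros(n - 1)])

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    Z = np.empty((n - 1, 4))
    for t in range(n - 1):
        i, j, h = sorted_raw[t]
        ci, cj = cluster_of[int(i)], cluster_of[int(j)]
        new = n + t
        Z[t] = (min(ci, cj), max(ci, cj), h, mass[ci] + mass[cj])
        mass[new] = mass[ci] + mass[cj]
        cluster_of[int(i)] = new
        cluster_of[int(j)] = new
    return Z, sorted_raw


def _cut(sorted_raw: np.ndarray, n: int, k: int) -> np.ndarray:
    """Labels 1..k from applying the first n-k sorted merges (union-find)."""
    parent = np.arange(n)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for t in range(n - k):
        i, j, _ = sorted_raw[t]
        ri, rj = find(int(i)), find(int(j))
        parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels + 1


def weighted_ward_cluster(D, weights, k: int) -> TypologyAssignment:
    """Cluster a dissimilarity matrix into k groups by weighted Ward linkage.

    ``D`` may be a :class:`~careseq.sequences.DistanceMatrix` or a square
    array of (unsquared) dissimilarities; squaring happens internally.
    """
    values = getattr(D, "values", D)
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = values.shape[0]
    if values.shape != (n, n) or len(weights) != n:
        raise ValueError("distance matrix and weights must align")
    if not np.all(np.isfinite(values)):
        raise ValueError("distances must be finite")
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for n={n}")
    if n == 1:
        return TypologyAssignment(np.array([1]), np.empty((0, 4)), k=1)
    # singleton merge criterion: 2 w_i w_j / (w_i + w_j) * d_ij^2; reduces to
    # the classical squared-dissimilarity input at unit weights
    wi, wj = np.meshgrid(weights, weights, indexing="ij")
    crit = (2.0 * wi * wj / (wi + wj)) * values**2
    raw = _nn_chain_ward(crit, weights)
    Z, sorted_raw = _sorted_merge_tree(raw, weights)
    labels = _cut(sorted_raw, n, k)
    return TypologyAssignment(labels=labels, merge_tree=Z, k=k, _sorted_merges=sorted_raw)


def cut_at(assignment: TypologyAssignment, k: int) -> np.ndarray:
    """Labels from cutting the stored merge tree at ``k`` clusters."""
    if assignment._sorted_merges is None:
        raise ValueError("assignment lacks the merge record needed for re-cutting")
    n = len(assignment.labels)
    return _cut(assignment._sorted_merges, n, k)


# ---------------------------------------------------------------------------
# quality statistics
# ---------------------------------------------------------------------------

def cluster_quality(D, labels, weights) -> dict[str, float]:
    """Weighted average silhouette width and within/between SS statistics.

    Silhouette of a point with zero distance spread (all distances equal, or
    a lone cluster member with no other cluster) is defined as 0; a fully
    degenerate input (all points identical) therefore scores 0 by convention.
    """
    values = np.asarray(getattr(D, "values", D), dtype=float)
    labels = np.asarray(labels)
    w = np.asarray(weights, dtype=float)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("cluster_quality needs at least 2 clusters")
    n = len(labels)
    if np.all(np.bincount(np.unique(labels, return_inverse=True)[1]) <= 1) and len(uniq) == n:
        raise ValueError("all clusters are singletons; quality undefined")
    sil = np.zeros(n)
    masks = {c: labels == c for c in uniq}
    for i in range(n):
        own = masks[labels[i]].copy()
        own[i] = False
        wown = w[own].sum()
        a = (values[i, own] * w[own]).sum() / wown if wown > 0 else 0.0
        b = np.inf
        for c in uniq:
            if c == labels[i]:
                continue
            m = masks[c]
            wc = w[m].sum()
            if wc > 0:
                b = min(b, (values[i, m] * w[m]).sum() / wc)
        denom = max(a, b)
        sil[i] = 0.0 if (not np.isfinite(b) or denom == 0) else (b - a) / denom
    asw = float(np.average(sil, weights=w))

    # weighted within/total pseudo sum-of-squares from pairwise distances
    def _ss(mask: np.ndarray) -> float:
        wm = w[mask]
        sub = values[np.ix_(mask, mask)] ** 2
        return float((wm[:, None] * wm[None, :] * sub).sum() / (2.0 * wm.sum()))

    total = _ss(np.ones(n, dtype=bool))
    within = sum(_ss(masks[c]) for c in uniq)
    return {
        "k": int(len(uniq)),
        "avg_silhouette_width": asw,
        "within_ss": within,
        "total_ss": total,
        "between_within_r2": 1.0 - within / total if total > 0 else 0.0,
    }


def quality_profile(seqs: SequenceSet, costs: CostScheme, k_range=range(2, 9)) -> list[dict]:
    """Quality statistics per k along one weighted Ward merge tree."""
    uniq, wu, inverse = aggregate_unique(seqs)
    d = unique_distances(uniq, costs)
    base = weighted_ward_cluster(d, wu, k=max(k_range))
    out = []
    for k in k_range:
        if k > len(uniq):
            continue
        lab = cut_at(base, k)
        out.append(cluster_quality(d, lab, wu))
    return out


# ---------------------------------------------------------------------------
# bootstrap stability
# ---------------------------------------------------------------------------

def bootstrap_stability(
    seqs: SequenceSet,
    costs: CostScheme,
    k: int,
    B: int = 50,
    seed: int = 0,
) -> dict[int, float]:
    """Per-cluster Jaccard bootstrap stability of the k-cluster solution.

    For each of B bootstrap resamples (children drawn with replacement with
    probability proportional to analysis weight), the resample is
    re-clustered and each reference cluster is matched to the bootstrap
    cluster with maximum Jaccard overlap (computed on the set of distinct
    resampled children).  Stability is the mean maximum overlap across
    resamples; a reference cluster absent from a resample contributes 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    ref = cluster_sequences(seqs, costs, k).labels
    n = len(seqs)
    p = seqs.weights / seqs.weights.sum()
    scores = {c: [] for c in range(1, k + 1)}
    for b in range(B):
        draw = rng.choice(n, size=n, replace=True, p=p)
        uniq_idx = np.unique(draw)
        boot = SequenceSet(
            ids=seqs.ids[draw],
            states=seqs.states[draw],
            weights=np.ones(len(draw)),
            alphabet=seqs.alphabet,
        )
        blab_per_draw = cluster_sequences(boot, costs, k).labels
        # label per distinct original child (identical sequences share labels)
        blab = np.zeros(n, dtype=int)
        blab[draw] = blab_per_draw
        for c in range(1, k + 1):
            ref_set = set(uniq_idx[ref[uniq_idx] == c])
            if not ref_set:
                logger.warning("reference cluster %d empty in resample %d", c, b)
                scores[c].append(0.0)
                continue
            best = 0.0
            for cb in range(1, k + 1):
                boot_set = set(uniq_idx[blab[uniq_idx] == cb])
                if boot_set:
                    inter = len(ref_set & boot_set)
                    union = len(ref_set | boot_set)
                    best = max(best, inter / union)
            scores[c].append(best)
    return {c: float(np.mean(v)) for c, v in scores.items()}


# ---------------------------------------------------------------------------
# high-level helpers
# ---------------------------------------------------------------------------

def cluster_sequences(seqs: SequenceSet, costs: CostScheme, k: int) -> TypologyAssignment:
    """Aggregate identical sequences, cluster them, and expand the labels.

    Exactly equivalent to weighted Ward on the full distance matrix (identical
    sequences always merge first at height 0) but linear in the number of
    distinct sequences.
    """
    uniq, wu, inverse = aggregate_unique(seqs)
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds the {len(uniq)} distinct sequences")
    d = unique_distances(uniq, costs)
    assign = weighted_ward_cluster(d, wu, k)
    return TypologyAssignment(
        labels=assign.labels[inverse],
        merge_tree=assign.merge_tree,
        k=k,
        _sorted_merges=assign._sorted_merges,
    )


def label_typologies(
    assignment: TypologyAssignment,
    seqs: SequenceSet,
    pre_entitlement_sweeps: int = 3,
) -> dict[int, str]:
    """Name clusters by their weighted modal state over the early sweeps.

    Most variation in childcare use occurs before the universal entitlement
    at age three, so names derive from sweeps 1..3.  Parental-only and
    family/friends care share the "Parents, friends & family" name.  With
    k != 4 generic names are used.  Naming collisions are resolved
    deterministically: the larger (by weight) cluster keeps the plain name,
    later ones get a numeric suffix (logged).
    """
    labels = assignment.labels
    k = assignment.k
    if k != 4:
        names = {c: f"cluster_{c}" for c in range(1, k + 1)}
        assignment.typology_names = names
        return names
    codes = seqs.alphabet.codes
    order = sorted(
        range(1, k + 1),
        key=lambda c: -seqs.weights[labels == c].sum(),
    )
    names: dict[int, str] = {}
    used: dict[str, int] = {}
    for c in order:
        mask = labels == c
        sub = seqs.states[mask][:, :pre_entitlement_sweeps].ravel()
        wrep = np.repeat(seqs.weights[mask], pre_entitlement_sweeps)
        counts = np.bincount(sub, weights=wrep, minlength=len(codes))
        modal = codes[int(np.argmax(counts))]
        name = STATE_TO_TYPOLOGY_NAME.get(modal, modal)
        if name in used:
            used[name] += 1
            logger.warning(
                "typology name collision on %r; cluster %d gets suffix %d",
                name, c, used[name],
            )
            name = f"{name} ({used[name]})"
        else:
            used[name] = 1
        names[c] = name
    assignment.typology_names = names
    return names
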