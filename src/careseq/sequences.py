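"""State sequences and optimal-matching (OM) dissimilarities.

A child's childcare history is a length-4 categorical sequence over the
7-state alphabet.  The OM distance between two sequences is the minimum
total cost of transforming one into the other using substitutions (cost
from a symmetric matrix) and insertions/deletions (constant cost),
computed by dynamic programming.  Although sequences here share a common
length, indels remain enabled: a shifted alignment can be cheaper than
position-wise substitution when the indel cost is low relative to
substitution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import CHILDCARE_ALPHABET, SWEEP_COLUMNS, StateAlphabet


@dataclass
class SequenceSet:
    """Aligned state sequences: one row per child, one column per sweep."""

    ids: np.ndarray            # (n,)
    states: np.ndarray         # (n, T) integer codes into alphabet
    weights: np.ndarray        # (n,) positive analysis weights
    alphabet: StateAlphabet = field(default=CHILDCARE_ALPHABET)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.states = np.asarray(self.states, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        n, _ = self.states.shape
        if len(self.ids) != n or len(self.weights) != n:
            raise ValueError("ids, states and weights must align")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be strictly positive")
        if self.states.min(initial=0) < 0 or self.states.max(initial=0) >= self.alphabet.size:
            raise ValueError("state codes outside alphabet")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_sweeps(self) -> int:
        return self.states.shape[1]

    def state_codes(self) -> np.ndarray:
        """Sequences as an (n, T) array of alphabet code strings."""
        return np.asarray(self.alphabet.codes)[self.states]

    # -- I/O -------------------------------------------------------------
    def to_wide_frame(self) -> pd.DataFrame:
        codes = self.state_codes()
        df = pd.DataFrame({"child_id": self.ids, "weight": self.weights})
        for t in range(self.n_sweeps):
            df[f"sweep{t + 1}"] = codes[:, t]
        return df

    def to_long_frame(self) -> pd.DataFrame:
        wide = self.to_wide_frame()
        return wide.melt(
            id_vars=["child_id", "weight"], var_name="sweep", value_name="state"
        ).assign(sweep=lambda d: d["sweep"].str.removeprefix("sweep").astype(int)).sort_values(
            ["child_id", "sweep"]
        ).reset_index(drop=True)


@dataclass(frozen=True)
class CostScheme:
    """Substitution matrix (symmetric, zero diagonal) plus indel cost."""

    substitution: np.ndarray
    indel: float

    def __post_init__(self) -> None:
        sub = np.asarray(self.substitution, dtype=float)
        object.__setattr__(self, "substitution", sub)
        if sub.ndim != 2 or sub.shape[0] != sub.shape[1]:
            raise ValueError("substitution matrix must be square")
        if np.any(sub < 0):
            raise ValueError("substitution costs must be nonnegative")
        if not np.allclose(sub, sub.T):
            raise ValueError("substitution matrix must be symmetric")
        if np.any(np.diag(sub) != 0):
            raise ValueError("substitution matrix must have zero diagonal")
        if not self.indel > 0:
            raise ValueError("indel cost must be positive")

    @classmethod
    def constant(cls, alphabet: StateAlphabet = CHILDCARE_ALPHABET,
                 substitution: float = 2.0, indel: float = 1.0) -> "CostScheme":
        """Constant substitution cost (default 2) and indel cost (default 1)."""
        sub = np.full((alphabet.size, alphabet.size), float(substitution))
        np.fill_diagonal(sub, 0.0)
        return cls(sub, float(indel))

    @classmethod
    def transition_rates(cls, seqs: SequenceSet, indel: float | None = None) -> "CostScheme":
        """Substitution costs from observed transition rates.

        sub(i, j) = 2 - p(i -> j) - p(j -> i), where p are weighted
        probabilities of transitioning between adjacent sweeps; indel
        defaults to half the maximum substitution cost.
        """
        k = seqs.alphabet.size
        counts = np.zeros((k, k))
        for t in range(seqs.n_sweeps - 1):
            np.add.at(counts, (seqs.states[:, t], seqs.states[:, t + 1]), seqs.weights)
        rowsum = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(rowsum > 0, counts / rowsum, 0.0)
        sub = 2.0 - p - p.T
        np.fill_diagonal(sub, 0.0)
        sub = np.maximum(sub, 0.0)
        sub = (sub + sub.T) / 2.0
        return cls(sub, float(indel) if indel is not None else sub.max() / 2.0)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise OM dissimilarities aligned to a sequence set."""

    values: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("ids must align with the matrix")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def build_sequences(
    cohort: pd.DataFrame,
    recode: dict[str, str] | None = None,
    alphabet: StateAlphabet = CHILDCARE_ALPHABET,
    sweep_columns: tuple[str, ...] = SWEEP_COLUMNS,
    weight_column: str = "design_weight",
) -> SequenceSet:
    """Build one state sequence per child from per-sweep state columns.

    ``recode`` maps raw category labels onto alphabet codes (identity for
    codes already in the alphabet).  Missing sweep states and unmapped raw
    categories raise with the offending child_id and sweep named.
    """
    n = len(cohort)
    states = np.empty((n, len(sweep_columns)), dtype=int)
    lookup = {c: i for i, c in enumerate(alphabet.codes)}
    ids = cohort["child_id"].to_numpy()
    for t, col in enumerate(sweep_columns):
        if col not in cohort.columns:
            raise ValueError(f"cohort lacks sweep column {col!r}")
        raw = cohort[col]
        missing = raw.isna()
        if missing.any():
            bad = ids[missing.to_numpy()][0]
            raise ValueError(f"missing state for child_id {bad} at sweep column {col!r}")
        vals = raw.astype(str)
        if recode:
            vals = vals.map(lambda v: recode.get(v, v))
        codes = vals.map(lookup)
        if codes.isna().any():
            i = int(np.flatnonzero(codes.isna().to_numpy())[0])
            raise ValueError(
                f"unmapped category {vals.iloc[i]!r} for child_id {ids[i]} "
                f"at sweep column {col!r}"
            )
        states[:, t] = codes.to_numpy(dtype=int)
    weights = cohort[weight_column].to_numpy(dtype=float)
    return SequenceSet(ids=ids, states=states, weights=weights, alphabet=alphabet)


# ---------------------------------------------------------------------------
# optimal matching
# ---------------------------------------------------------------------------

def om_distance(a: np.ndarray, b: np.ndarray, costs: CostScheme) -> float:
    """Minimal substitution/indel cost transforming sequence ``a`` into ``b``.

    ``a`` and ``b`` are integer code vectors over the same alphabet.
    Symmetric in its arguments because the substitution matrix is symmetric
    and indels pair off as insertion/deletion.
    """
    a = np.asarray(a, dtype=int).ravel()
    b = np.asarray(b, dtype=int).ravel()
    k = costs.substitution.shape[0]
    if a.size and a.max() >= k or b.size and b.max() >= k:
        raise ValueError("sequence states exceed the cost-matrix alphabet")
    return float(_om_batch(a[None, :], b[None, :], costs)[0])


def _om_batch(A: np.ndarray, B: np.ndarray, costs: CostScheme) -> np.ndarray:
    """Vectorised DP over P aligned sequence pairs: A (P, T1), B (P, T2)."""
    sub, indel = costs.substitution, costs.indel
    P, t1 = A.shape
    t2 = B.shape[1]
    prev = np.tile(np.arange(t2 + 1) * indel, (P, 1))
    for i in range(1, t1 + 1):
        cur = np.empty_like(prev)
        cur[:, 0] = i * indel
        ai = A[:, i - 1]
        for j in range(1, t2 + 1):
            stay = prev[:, j - 1] + sub[ai, B[:, j - 1]]
            gap = np.minimum(prev[:, j], cur[:, j - 1]) + indel
            cur[:, j] = np.minimum(stay, gap)
        prev = cur
    return prev[:, -1]


def pairwise_distances(seqs: SequenceSet, costs: CostScheme) -> DistanceMatrix:
    """All-pairs OM distances, computed once per unique sequence pair."""
    if costs.substitution.shape[0] != seqs.alphabet.size:
        raise ValueError("cost matrix does not match the sequence alphabet")
    uniq, inverse = np.unique(seqs.states, axis=0, return_inverse=True)
    m = len(uniq)
    iu, ju = np.triu_indices(m, k=1)
    du = np.zeros((m, m))
    if len(iu):
        du[iu, ju] = _om_batch(uniq[iu], uniq[ju], costs)
        du += du.T
    full = du[np.ix_(inverse, inverse)]
    return DistanceMatrix(values=full, ids=seqs.ids)


def aggregate_unique(seqs: SequenceSet):
    """Collapse identical sequences, summing weights.

    Returns (unique_states, summed_weights, inverse) with ``inverse`` mapping
    each child to its unique-sequence row.  Weighted Ward clustering of the
    aggregated set is equivalent to clustering the full set, which makes the
    n x n problem linear in the number of distinct sequences.
    """
    uniq, inverse = np.unique(seqs.states, axis=0, return_inverse=True)
    w = np.zeros(len(uniq))
    np.add.at(w, inverse, seqs.weights)
    return uniq, w, inverse


def unique_distances(uniq: np.ndarray, costs: CostScheme) -> np.ndarray:
    """Square OM distance matrix between unique sequences."""
    m = len(uniq)
    iu, ju = np.triu_indices(m, k=1)
    d = np.zeros((m, m))
    if len(iu):
        d[iu, ju] = _om_batch(uniq[iu], uniq[ju], costs)
        d += d.T
    return d
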