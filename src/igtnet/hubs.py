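"""Hub topography comparison across conditions.

Hubs are the top 20% of a network's degree distribution.  Pairwise Jaccard
indices between hub sets across all networks form a similarity matrix; the
ratio of mean within-condition to mean between-condition similarity is the
test statistic, and its null distribution is built by permuting condition
labels (by default within subject, respecting the repeated-measures
structure).  The p-value uses the add-one estimator, so with 512
permutations the attainable floor is 1/513.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class HubSet:
    """Top-degree nodes of one network."""

    member_nodes: frozenset[int]
    n_nodes: int  # size of the node universe
    fraction: float = 0.20
    source: dict = field(default_factory=dict)


def hub_set(
    degrees: np.ndarray,
    fraction: float = 0.20,
    source: dict | None = None,
) -> HubSet:
    """The ceil(fraction*N) highest-degree nodes, extended across ties.

    Every node whose degree equals the cutoff degree is included, so the
    result is deterministic and order-independent (the realized fraction may
    exceed the nominal one; it is recoverable from the set size).
    """
    degrees = np.asarray(degrees)
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    N = len(degrees)
    m = math.ceil(fraction * N)
    cutoff = np.sort(degrees)[::-1][m - 1]
    members = frozenset(np.flatnonzero(degrees >= cutoff).tolist())
    return HubSet(member_nodes=members, n_nodes=N, fraction=fraction,
                  source=dict(source or {}))


def jaccard(a: HubSet, b: HubSet) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets count as identical (1)."""
    if a.n_nodes != b.n_nodes:
        raise ValueError(
            f"hub sets live on different node universes ({a.n_nodes} vs {b.n_nodes})"
        )
    union = a.member_nodes | b.member_nodes
    if not union:
        return 1.0
    return len(a.member_nodes & b.member_nodes) / len(union)


@dataclass
class SimilarityMatrix:
    """All-pairs Jaccard similarities with condition/subject bookkeeping."""

    entries: np.ndarray  # (n, n) symmetric, unit diagonal
    labels: np.ndarray  # condition per network
    subjects: np.ndarray  # subject per network

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        self.labels = np.asarray(self.labels)
        self.subjects = np.asarray(self.subjects)
        n = self.entries.shape[0]
        if self.entries.shape != (n, n):
            raise ValueError("similarity matrix must be square")
        if len(self.labels) != n or len(self.subjects) != n:
            raise ValueError("labels/subjects must align with the matrix")

    @property
    def n_networks(self) -> int:
        return self.entries.shape[0]


def similarity_matrix(
    hubs: list[HubSet],
    labels,
    subjects,
) -> SimilarityMatrix:
    """Jaccard index between every pair of hub sets."""
    if len(hubs) < 2:
        raise ValueError("need at least 2 networks")
    n = len(hubs)
    J = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        J[i, j] = J[j, i] = jaccard(hubs[i], hubs[j])
    return SimilarityMatrix(entries=J, labels=np.asarray(labels),
                            subjects=np.asarray(subjects))


def consistency_statistic(
    sim: SimilarityMatrix, labels: np.ndarray | None = None
) -> float:
    """Mean within-condition JI divided by mean between-condition JI.

    Diagonal entries (self-pairs) are excluded; each unordered pair counts
    once.  A value of 1 means condition labels carry no information about
    hub-set similarity.
    """
    labels = sim.labels if labels is None else np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two distinct condition labels")
    n = sim.n_networks
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    within = sim.entries[iu][same]
    between = sim.entries[iu][~same]
    if len(within) == 0 or len(between) == 0:
        raise ValueError("labels yield no within- or no between-condition pairs")
    between_mean = between.mean()
    if between_mean == 0:
        raise ValueError("between-condition similarity is zero (degenerate)")
    return float(within.mean() / between_mean)


@dataclass
class PermutationResult:
    observed_stat: float
    null_stats: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None
    scheme: str
    min_attainable_p: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


def _within_subject_permutation(
    rng: np.random.Generator, labels: np.ndarray, subjects: np.ndarray
) -> np.ndarray:
    out = labels.copy()
    for s in np.unique(subjects):
        rows = np.flatnonzero(subjects == s)
        out[rows] = out[rows[rng.permutation(len(rows))]]
    return out


def permutation_test(
    sim: SimilarityMatrix,
    n_perm: int = 512,
    seed: int | None = 0,
    scheme: str = "within-subject",
) -> PermutationResult:
    """Permutation null for the within/between similarity ratio.

    Schemes: "within-subject" shuffles condition labels independently within
    each subject (respects the repeated-measures exchangeability); "free-label"
    shuffles the whole label vector.  Exceedance uses ">= observed" and the
    add-one p estimator (1 + #exceed) / (1 + n_perm), never returning 0.

    When the within-subject scheme admits fewer distinct label patterns than
    ``n_perm``, the null is enumerated exhaustively instead (with a warning).
    """
    if scheme not in ("within-subject", "free-label"):
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = consistency_statistic(sim)
    labels, subjects = sim.labels, sim.subjects
    rng = np.random.default_rng(seed)

    null: list[float] = []
    exhaustive = _distinct_within_subject(labels, subjects) if (
        scheme == "within-subject"
    ) else None
    if exhaustive is not None and exhaustive[0] <= n_perm:
        warnings.warn(
            f"only {exhaustive[0]} distinct within-subject label patterns; "
            "enumerating exhaustively",
            stacklevel=2,
        )
        for perm_labels in exhaustive[1]:
            null.append(consistency_statistic(sim, labels=perm_labels))
        n_perm = len(null)
    else:
        for _ in range(n_perm):
            if scheme == "free-label":
                perm = labels[rng.permutation(len(labels))]
            else:
                perm = _within_subject_permutation(rng, labels, subjects)
            null.append(consistency_statistic(sim, labels=perm))

    null_arr = np.asarray(null)
    p = (1 + int(np.count_nonzero(null_arr >= observed))) / (1 + n_perm)
    return PermutationResult(
        observed_stat=observed,
        null_stats=null_arr,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        scheme=scheme,
        min_attainable_p=1.0 / (1 + n_perm),
    )


def _distinct_within_subject(labels, subjects):
    """Count distinct within-subject label rearrangements; enumerate if small."""
    total = 1
    per_subject = []
    for s in np.unique(subjects):
        rows = np.flatnonzero(subjects == s)
        vals, counts = np.unique(labels[rows], return_counts=True)
        n_arr = math.factorial(len(rows))
        for c in counts:
            n_arr //= math.factorial(int(c))
        per_subject.append((rows, vals, counts))
        total *= n_arr
        if total > 10**6:
            return None  # plenty of permutations; sample instead
    if total > 4096:
        return None
    # enumerate the distinct multiset permutations per subject, then products
    def multiset_perms(rows, lab):
        seen = set()
        for p in itertools.permutations(lab[rows]):
            if p not in seen:
                seen.add(p)
                yield p

    all_labels = []
    subject_rows = [rows for rows, _, _ in per_subject]
    subject_opts = [list(multiset_perms(rows, labels)) for rows in subject_rows]
    for combo in itertools.product(*subject_opts):
        perm = labels.copy()
        for rows, vals in zip(subject_rows, combo):
            perm[rows] = vals
        all_labels.append(perm)
    return total, all_labels


def consistency_map(hubs: list[HubSet], n_nodes: int | None = None) -> np.ndarray:
    """Per-node fraction of networks in which the node is a hub."""
    if not hubs:
        raise ValueError("need at least one network")
    n = n_nodes if n_nodes is not None else hubs[0].n_nodes
    counts = np.zeros(n)
    for h in hubs:
        if h.n_nodes != n:
            raise ValueError("hub sets live on different node universes")
        counts[list(h.member_nodes)] += 1
    return counts / len(hubs)
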