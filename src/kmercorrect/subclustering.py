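"""Bayesian subclustering of Hamming components (pipeline Step 3).

Each connected component is split into subclusters by repeated m-means over
Hamming distance.  Cluster centers are consensus strings (the maximum
likelihood center under the independent-error model).  The objective is the
quality-weighted log-likelihood

    L(x|c) = prod_{j: x[j] != c[j]} q_x[j] * prod_{j: x[j] = c[j]} (1 - q_x[j])

penalized by the Bayesian information criterion,

    l_m = 2 log L_m(C_1..C_m) - (3km + m - 1) log N,

where the parameter count is m-1 subcluster probabilities, km center letters
and 2km conditional error probabilities, and N is the number of observations
(the component's total occurrence count by default).  m grows until the
objective stops increasing.

Likelihood contributions are weighted by occurrence counts: a k-mer seen ten
times is ten observations.  Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from ._encode import decode, encode
from .hamming_graph import HammingComponent
from .io_fastq import DEFAULT_CLAMP
from .kmer_stats import KmerIndex

#: per-position error probability of the uniform (HAMMER-style) model
DEFAULT_EPSILON = 0.01


class ErrorProfile:
    """Clamped per-k-mer per-position combined error probabilities q_x[j]."""

    def __init__(self, q: np.ndarray, clamp=DEFAULT_CLAMP):
        self.q = np.clip(q, clamp[0], clamp[1])
        self.logq = np.log(self.q)
        self.log1mq = np.log1p(-self.q)

    @classmethod
    def from_index(cls, index: KmerIndex, clamp=DEFAULT_CLAMP) -> "ErrorProfile":
        return cls(np.exp(index.log_error), clamp)


@dataclass
class Subcluster:
    member_ids: np.ndarray
    center: str

    @property
    def center_enc(self) -> np.ndarray:
        return encode(self.center)


@dataclass
class Subclustering:
    """A partition of one component into subclusters with consensus centers."""

    clusters: List[Subcluster]
    objective: Optional[float] = None

    @property
    def m(self) -> int:
        return len(self.clusters)

    def member_ids(self) -> np.ndarray:
        return np.concatenate([c.member_ids for c in self.clusters])


def hammer_likelihood(x: str, y: str, epsilon: float = DEFAULT_EPSILON) -> float:
    """Log-likelihood (k-d) log(1-eps) + d log(eps) of the uniform-error model."""
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    if len(x) != len(y):
        raise ValueError("length mismatch")
    d = sum(a != b for a, b in zip(x, y))
    k = len(x)
    return (k - d) * np.log1p(-epsilon) + d * np.log(epsilon)


def kmer_log_likelihood(x: str, c: str, q_x: np.ndarray,
                        clamp=DEFAULT_CLAMP) -> float:
    """Log-likelihood that k-mer x was generated from center c.

    ``q_x`` holds x's per-position combined error probabilities; mismatching
    positions contribute log q_x[j], matching ones log(1 - q_x[j]).
    """
    if len(x) != len(c):
        raise ValueError("length mismatch")
    q = np.clip(np.asarray(q_x, dtype=float), clamp[0], clamp[1])
    mism = np.frombuffer(x.encode(), np.uint8) != np.frombuffer(c.encode(), np.uint8)
    return float(np.where(mism, np.log(q), np.log1p(-q)).sum())


def _consensus_enc(rows: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Position-wise weighted majority base; ties resolved in A<C<G<T order."""
    k = rows.shape[1]
    votes = np.zeros((k, 4))
    for b in range(4):
        votes[:, b] = ((rows == b) * weights[:, None]).sum(axis=0)
    return votes.argmax(axis=1).astype(np.uint8)  # argmax takes first max: A<C<G<T


def consensus_center(members, index: KmerIndex) -> str:
    """Consensus string of a member set, weighting each k-mer by its count.

    A k-mer observed ten times votes ten times (multiset semantics).
    """
    ids = np.asarray(sorted(members), dtype=np.int64)
    if ids.size == 0:
        raise ValueError("empty member set")
    return decode(_consensus_enc(index.matrix[ids], index.counts[ids].astype(float)))


def _member_loglik(rows: np.ndarray, center: np.ndarray,
                   logq: np.ndarray, log1mq: np.ndarray) -> np.ndarray:
    """Per-member log L(x|c) for one cluster (vectorized over members)."""
    mism = rows != center[None, :]
    return np.where(mism, logq, log1mq).sum(axis=1)


def _init_order(members: np.ndarray, index: KmerIndex) -> np.ndarray:
    """Members ordered by least error probability (highest p_x); ties by
    higher count, then lexicographic (= code order)."""
    logp = index.error_free_log_prob()[members]
    order = np.lexsort((index.codes[members], -index.counts[members], -logp))
    return members[order]


def m_means(members, m: int, index: KmerIndex, profile: ErrorProfile,
            max_iter: int = 100) -> Subclustering:
    """m-means over Hamming distance with consensus-center updates.

    Initial centers are the m member k-mers with the least error probability.
    Members are assigned to the nearest center (ties to the lowest-index
    center); centers are recomputed as count-weighted consensus strings.
    Stops when the assignment repeats or after ``max_iter`` rounds.  An
    empty cluster is reseeded with the member farthest from its own center.
    """
    members = np.asarray(sorted(members), dtype=np.int64)
    if not 1 <= m <= len(members):
        raise ValueError(f"m={m} out of range for {len(members)} members")
    rows = index.matrix[members]
    weights = index.counts[members].astype(float)
    centers = rows[np.searchsorted(members, _init_order(members, index)[:m])].copy()
    seen = set()
    assign = None
    for _ in range(max_iter):
        dist = (rows[:, None, :] != centers[None, :, :]).sum(axis=2)
        new_assign = dist.argmin(axis=1)
        # reseed empty clusters with the member farthest from its center
        used: set = set()
        for ci in range(m):
            if not (new_assign == ci).any():
                own = dist[np.arange(len(members)), new_assign].astype(float)
                if used:
                    own[list(used)] = -1.0
                far = int(own.argmax())
                used.add(far)
                new_assign[far] = ci
                centers[ci] = rows[far]
        key = new_assign.tobytes()
        if assign is not None and (key in seen):
            assign = new_assign
            break
        seen.add(key)
        assign = new_assign
        for ci in range(m):
            sel = assign == ci
            centers[ci] = _consensus_enc(rows[sel], weights[sel])
    clusters = [Subcluster(member_ids=members[assign == ci], center=decode(centers[ci]))
                for ci in range(m)]
    return Subclustering(clusters=clusters)


def bic_objective(clustering: Subclustering, index: KmerIndex,
                  profile: ErrorProfile, k: Optional[int] = None,
                  distinct_n: bool = False) -> float:
    """BIC-penalized objective 2 log L_m - (3km + m - 1) log N.

    N is the component's total occurrence count (sum of member counts), or
    the number of distinct member k-mers when ``distinct_n`` is set.  The
    likelihood is count-weighted accordingly in the default mode.
    """
    if not clustering.clusters:
        raise ValueError("empty clustering")
    k = index.k if k is None else k
    m = clustering.m
    loglik = 0.0
    all_ids = clustering.member_ids()
    n_obs = len(all_ids) if distinct_n else int(index.counts[all_ids].sum())
    for cl in clustering.clusters:
        ids = cl.member_ids
        if ids.size == 0:
            continue
        per = _member_loglik(index.matrix[ids], cl.center_enc,
                             profile.logq[ids], profile.log1mq[ids])
        w = np.ones(len(ids)) if distinct_n else index.counts[ids].astype(float)
        loglik += float((per * w).sum())
    penalty = (3 * k * m + m - 1) * np.log(n_obs) if n_obs > 0 else 0.0
    return 2.0 * loglik - penalty


def subcluster_component(component: HammingComponent, index: KmerIndex,
                         profile: ErrorProfile, k: Optional[int] = None,
                         distinct_n: bool = False,
                         max_iter: int = 100) -> Subclustering:
    """Greedy m-sweep: evaluate m = 1, 2, ... and stop once the BIC objective
    ceases to increase; returns the clustering for the last improving m."""
    members = np.asarray(component.member_ids, dtype=np.int64)
    if members.size == 0:
        raise ValueError("empty component")
    best = m_means(members, 1, index, profile, max_iter)
    best.objective = bic_objective(best, index, profile, k, distinct_n)
    if members.size == 1:
        return best
    m = 2
    while m <= members.size:
        cand = m_means(members, m, index, profile, max_iter)
        cand.objective = bic_objective(cand, index, profile, k, distinct_n)
        if cand.objective <= best.objective:
            return best
        best = cand
        m += 1
    return best


def dump_subclusterings(subclusterings: Sequence[Subclustering],
                        index: KmerIndex, path) -> None:
    """TSV dump: component-id, m, center, member count, objective."""
    with open(path, "w") as out:
        out.write("component\tm\tcenter\tn_members\tobjective\n")
        for ci, sc in enumerate(subclusterings):
            for cl in sc.clusters:
                obj = "" if sc.objective is None else f"{sc.objective:.6g}"
                out.write(f"{ci}\t{sc.m}\t{cl.center}\t{len(cl.member_ids)}\t{obj}\n")
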