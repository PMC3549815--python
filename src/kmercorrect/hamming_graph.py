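"""Connected components of the Hamming graph on k-mers (pipeline Step 2).

The Hamming graph HG_tau(X) joins k-mers at Hamming distance <= tau.  Its
components are found without all-pairs comparison: if two k-mers differ in
at most tau positions and the index set [0, k-1] is split into tau+1 parts,
at least one part carries identical subsequences in both (pigeonhole).  We
therefore sort copies of X by each part, compare only within equivalence
blocks, and merge with a disjoint-set structure.  Two partition families
are used: contiguous index runs first, then a strided partition to re-split
blocks that are too large for quadratic processing; any block still too
large after the second split is processed pairwise regardless, which keeps
the result exact at worst-case cost.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import DisjointSet

from ._encode import pack
from .kmer_stats import KmerIndex


@dataclass
class IndexPartition:
    """A partition of the index set [0, k-1] into tau+1 near-equal parts."""

    parts: List[np.ndarray]

    def __post_init__(self):
        allidx = np.concatenate(self.parts) if self.parts else np.empty(0, np.int64)
        k = allidx.size
        if len(np.unique(allidx)) != k or (k and (allidx.min() != 0 or allidx.max() != k - 1)):
            raise ValueError("parts must partition [0, k-1]")
        sizes = [len(p) for p in self.parts]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("part sizes must differ by at most 1")


@dataclass(frozen=True)
class HammingComponent:
    """A connected component of HG_tau(X) as a sorted tuple of k-mer ids."""

    member_ids: Tuple[int, ...]

    def __len__(self) -> int:
        return len(self.member_ids)


def hamming_distance(x: str, y: str) -> int:
    """Number of positions where two equal-length strings differ."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    return sum(a != b for a, b in zip(x, y))


def make_partitions(k: int, tau: int) -> Tuple[IndexPartition, IndexPartition]:
    """The contiguous and strided partitions of [0, k-1] into tau+1 parts.

    When (tau+1) divides k, the contiguous parts are {s*sigma, ..., s*sigma+sigma-1}
    and the strided parts {s, s+tau+1, s+2(tau+1), ...} with sigma = k/(tau+1).
    Otherwise part sizes are ceil/floor of k/(tau+1), which preserves the
    pigeonhole guarantee verbatim.
    """
    p = tau + 1
    if p > k:
        raise ValueError(f"tau+1={p} exceeds k={k}")
    contiguous = IndexPartition([np.asarray(a, dtype=np.int64)
                                 for a in np.array_split(np.arange(k), p)])
    strided = IndexPartition([np.arange(s, k, p, dtype=np.int64) for s in range(p)])
    return contiguous, strided


def _blocks_for_part(matrix: np.ndarray, ids: np.ndarray, part: np.ndarray,
                     min_size: int = 2) -> List[np.ndarray]:
    """Equivalence blocks of `ids` under equality on the columns in `part`."""
    sub = np.ascontiguousarray(matrix[ids][:, part])
    keys = pack(sub)
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    boundaries = np.flatnonzero(np.diff(sorted_keys)) + 1
    groups = np.split(ids[order], boundaries)
    return [g for g in groups if len(g) >= min_size]


def find_blocks(kmer_ids: Iterable[int], partition: IndexPartition,
                index: KmerIndex) -> List[np.ndarray]:
    """All equivalence blocks (size >= 2) of the given k-mers, over every part.

    A k-mer may appear in blocks of several parts; singleton blocks are
    dropped since they contribute no candidate pairs.
    """
    ids = np.asarray(sorted(kmer_ids), dtype=np.int64)
    out: List[np.ndarray] = []
    for part in partition.parts:
        out.extend(_blocks_for_part(index.matrix, ids, part))
    return out


def _process_block(matrix: np.ndarray, ids: np.ndarray, tau: int,
                   dsu: DisjointSet, chunk: int = 512) -> None:
    """Pairwise scan of one block; joins pairs at distance <= tau."""
    rows = matrix[ids]
    n = len(ids)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        d = (rows[lo:hi, None, :] != rows[None, :, :]).sum(axis=2)
        ii, jj = np.nonzero(d <= tau)
        for a, b in zip(ii, jj):
            ga = lo + a
            if ga < b:  # upper triangle only
                dsu.merge(int(ids[ga]), int(ids[b]))


def connected_components(index: KmerIndex, tau: int = 1,
                         max_quadratic: int = 1000) -> List[HammingComponent]:
    """Connected components of HG_tau over the observed k-mers of the index.

    Equals the brute-force all-pairs result for any ``max_quadratic``; the
    parameter only bounds the size of blocks processed quadratically before
    re-splitting with the strided partition.  Output is sorted by smallest
    member id for determinism.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if max_quadratic < 2:
        raise ValueError("max_quadratic must be >= 2")
    n = index.n_observed
    if n == 0:
        return []
    contiguous, strided = make_partitions(index.k, tau)
    dsu = DisjointSet(range(n))
    all_ids = np.arange(n, dtype=np.int64)
    for part in contiguous.parts:
        for block in _blocks_for_part(index.matrix, all_ids, part):
            if len(block) > max_quadratic:
                for spart in strided.parts:
                    for sblock in _blocks_for_part(index.matrix, block, spart):
                        _process_block(index.matrix, sblock, tau, dsu)
            else:
                _process_block(index.matrix, block, tau, dsu)
    comps = [HammingComponent(tuple(sorted(s))) for s in dsu.subsets()]
    comps.sort(key=lambda c: c.member_ids[0])
    return comps


def dump_components(components: Sequence[HammingComponent], index: KmerIndex,
                    path) -> None:
    """TSV dump: component-id, size, comma-joined member k-mers."""
    with open(path, "w") as out:
        out.write("component\tsize\tmembers\n")
        for ci, comp in enumerate(components):
            members = ",".join(index.kmer(i) for i in comp.member_ids)
            out.write(f"{ci}\t{len(comp)}\t{members}\n")
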