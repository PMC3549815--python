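"""Solid k-mer selection, iterative expansion and consensus read correction
(pipeline Steps 4-6).

A k-mer's quality p_x = prod_j (1 - q_x[j]) is the probability that it is
error-free; a cluster's quality p_C = 1 - prod_{x in C} (1 - p_x) is the
probability that at least one member is correct (singletons are not treated
specially).  Centers of clusters whose quality exceeds a strict threshold
form the initial solid set, which then grows iteratively: whenever a read
is completely covered by solid k-mer occurrences, all of its k-mers become
solid.  Finally each read is corrected position by position by the
consensus vote of the solid k-mers covering it and of the solid cluster
centers of its non-solid k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from ._encode import N_CODE, decode, encode, pack, windows_enc
from .io_fastq import DEFAULT_CLAMP, Read
from .kmer_stats import KmerIndex, KmerStat, _error_free_log_prob
from .subclustering import Subclustering

#: default cluster-quality threshold for the initial solid set
DEFAULT_SOLID_THRESHOLD = 1.0 - 1e-3


def kmer_quality(stat: KmerStat, clamp=DEFAULT_CLAMP) -> float:
    """p_x = prod_j (1 - q_x[j]), computed stably in log-space."""
    return float(np.exp(_error_free_log_prob(stat.log_error, clamp)))


def cluster_quality(member_stats: Sequence[KmerStat]) -> float:
    """p_C = 1 - prod_x (1 - p_x): probability at least one member is correct."""
    if not member_stats:
        raise ValueError("empty cluster")
    log1mp = [np.log1p(-np.exp(_error_free_log_prob(s.log_error)))
              for s in member_stats]
    return float(-np.expm1(sum(log1mp)))


class SolidSet:
    """The evolving set of solid k-mers plus the total center map.

    ``solid_mask`` covers the index's full id space (observed k-mers and
    synthetic centers appended by :func:`select_solid`); ``center_of[i]`` is
    the id of k-mer i's subcluster center.  The set only ever grows.
    """

    def __init__(self, n_total: int, n_observed: int):
        self.solid_mask = np.zeros(n_total, dtype=bool)
        self.center_of = np.full(n_total, -1, dtype=np.int64)
        self.n_observed = n_observed
        self.expansion_passes = 0

    @property
    def solid(self) -> set:
        return set(np.flatnonzero(self.solid_mask).tolist())

    def is_solid(self, kmer_id: int) -> bool:
        return bool(self.solid_mask[kmer_id])

    def center_is_solid(self, kmer_id: int) -> bool:
        return bool(self.solid_mask[self.center_of[kmer_id]])

    def add(self, kmer_ids) -> None:
        self.solid_mask[np.asarray(kmer_ids, dtype=np.int64)] = True

    def __len__(self) -> int:
        return int(self.solid_mask.sum())


@dataclass
class CorrectionOutcome:
    corrected: Read
    n_changed_positions: int
    changed: bool


def _synthetic_center_log_error(center_enc: np.ndarray, member_rows: np.ndarray,
                                member_log_error: np.ndarray) -> np.ndarray:
    """Per-position log error product for an unobserved consensus center:
    aggregate members' products at positions where they agree with the center."""
    agree = member_rows == center_enc[None, :]
    contrib = np.where(agree, member_log_error, 0.0)
    return contrib.sum(axis=0)


def select_solid(subclusterings: Sequence[Subclustering], index: KmerIndex,
                 threshold: float = DEFAULT_SOLID_THRESHOLD) -> SolidSet:
    """Mark as solid the centers of clusters whose quality exceeds ``threshold``.

    Consensus centers that are not observed k-mers are appended to the index
    as synthetic entries (count 0); they may later vote during correction but
    never cover read positions during expansion (coverage is defined over
    observed occurrences only).  ``center_of`` is filled for every k-mer.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    log1mp = np.log1p(-np.clip(index.error_free_prob()[: index.n_observed],
                               0.0, 1.0 - 1e-12))
    pending: List[Tuple[np.ndarray, np.ndarray, float]] = []
    centers_solid: List[bool] = []
    center_members: List[np.ndarray] = []
    center_ids: List[int] = []
    for sc in subclusterings:
        for cl in sc.clusters:
            ids = np.asarray(cl.member_ids, dtype=np.int64)
            p_c = float(-np.expm1(log1mp[ids].sum()))
            cid = index.lookup(cl.center)
            if cid is None:
                enc = cl.center_enc
                cid = index.add_synthetic(
                    enc, _synthetic_center_log_error(enc, index.matrix[ids],
                                                     index.log_error[ids]))
            center_ids.append(cid)
            center_members.append(ids)
            centers_solid.append(p_c > threshold)
    solid = SolidSet(index.n_total, index.n_observed)
    for cid, ids, is_solid in zip(center_ids, center_members, centers_solid):
        solid.center_of[ids] = cid
        if is_solid:
            solid.add([cid])
    # a center that is itself a member keeps its own cluster's center;
    # synthetic / non-member centers map to themselves
    unset = solid.center_of < 0
    solid.center_of[unset] = np.flatnonzero(unset)
    return solid


def _covered(read_len: int, offsets: np.ndarray, k: int) -> bool:
    """Whether the union of [o, o+k-1] over solid offsets covers [0, read_len-1]."""
    if offsets.size == 0:
        return False
    if offsets[0] != 0 or offsets[-1] != read_len - k:
        return False
    return bool((np.diff(offsets) <= k).all())


def expand_solid(reads: Sequence[Read], solid: SolidSet,
                 index: KmerIndex) -> SolidSet:
    """Iteratively mark all k-mers of completely covered reads as solid.

    A read is completely covered when every position lies inside at least one
    solid k-mer occurrence.  Each pass evaluates coverage against the solid
    set as of the start of the pass (so the fixed point and the number of
    growing passes are independent of read order); passes repeat until the
    set stops growing.  ``reads`` must be the reads the index was built from.
    """
    k = index.k
    solid.expansion_passes = 0
    while True:
        snapshot = solid.solid_mask.copy()
        additions: List[np.ndarray] = []
        for read, pos in zip(reads, index.positions):
            if len(read) < k or pos.ids.size == 0:
                continue
            sel = snapshot[pos.ids]
            if _covered(len(read), pos.offsets[sel], k):
                additions.append(pos.ids)
        if not additions:
            break
        new_ids = np.unique(np.concatenate(additions))
        if snapshot[new_ids].all():
            break
        solid.add(new_ids)
        solid.expansion_passes += 1
    return solid


def _read_window_ids(read: Read, index: KmerIndex):
    """Valid window offsets of a read mapped to index ids (-1 for unknown),
    with canonical-orientation flags."""
    enc = encode(read.seq)
    win = windows_enc(enc, index.k)
    if win.shape[0] == 0:
        return (np.empty(0, np.int64),) * 3
    valid = ~(win == N_CODE).any(axis=1)
    offsets = np.flatnonzero(valid)
    codes = pack(np.ascontiguousarray(win[valid]))
    flipped = np.zeros(len(codes), dtype=bool)
    if index.canonical and len(codes):
        rc = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[win[valid]][:, ::-1]
        rc_codes = pack(np.ascontiguousarray(rc))
        flipped = rc_codes < codes
        codes = np.where(flipped, rc_codes, codes)
    return offsets, index.lookup_codes(codes), flipped


def correct_read(read: Read, solid: SolidSet, index: KmerIndex) -> CorrectionOutcome:
    """Correct one read by the consensus vote of solid k-mers and solid centers.

    Each solid k-mer occurrence votes its own letters over the positions it
    covers; a non-solid occurrence whose subcluster center is solid votes the
    center's aligned letters.  A position with votes becomes the argmax base
    (ties keep the original base when it is among the argmax set, otherwise
    A<C<G<T); zero-vote positions keep the original base.  Read length is
    always preserved.
    """
    k = index.k
    L = len(read)
    if L < k:
        return CorrectionOutcome(read, 0, False)
    offsets, ids, flipped = _read_window_ids(read, index)
    if offsets.size == 0:
        return CorrectionOutcome(read, 0, False)
    enc = encode(read.seq)
    votes = np.zeros((L, 4), dtype=np.int64)
    span = np.arange(k)
    known = ids >= 0
    own_solid = np.zeros(len(ids), dtype=bool)
    own_solid[known] = solid.solid_mask[ids[known]]
    center_solid = np.zeros(len(ids), dtype=bool)
    center_solid[known] = solid.solid_mask[solid.center_of[ids[known]]]

    def _vote(offs: np.ndarray, letters: np.ndarray) -> None:
        if offs.size == 0:
            return
        rows = (offs[:, None] + span[None, :]).ravel()
        np.add.at(votes, (rows, letters.ravel()), 1)

    # solid k-mers vote the read's own letters
    sel = own_solid
    _vote(offsets[sel], np.lib.stride_tricks.sliding_window_view(enc, k)[offsets[sel]])
    # non-solid k-mers with solid centers vote the center's aligned letters
    sel = (~own_solid) & center_solid
    if sel.any():
        c_rows = index.matrix[solid.center_of[ids[sel]]]
        if index.canonical and flipped[sel].any():
            fl = flipped[sel]
            c_rows = c_rows.copy()
            c_rows[fl] = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[c_rows[fl]][:, ::-1]
        _vote(offsets[sel], c_rows)

    maxv = votes.max(axis=1)
    best = votes.argmax(axis=1).astype(np.uint8)  # first max: A<C<G<T
    orig_ok = enc < 4
    orig_votes = np.where(orig_ok, votes[np.arange(L), np.minimum(enc, 3)], -1)
    keep = (maxv == 0) | (orig_ok & (orig_votes == maxv))
    new_enc = np.where(keep, enc, best).astype(np.uint8)
    n_changed = int((new_enc != enc).sum())
    if n_changed == 0:
        return CorrectionOutcome(read, 0, False)
    corrected = Read(id=read.id, seq=decode(new_enc), qual=read.qual,
                     raw_qual=read.raw_qual)
    return CorrectionOutcome(corrected, n_changed, True)


def correct_reads(reads: Sequence[Read], solid: SolidSet,
                  index: KmerIndex) -> Tuple[List[Read], int, int]:
    """Correct every read; returns (reads, n_reads_changed, n_positions_changed)."""
    out: List[Read] = []
    n_reads_changed = 0
    n_positions = 0
    for r in reads:
        res = correct_read(r, solid, index)
        out.append(res.corrected)
        n_reads_changed += int(res.changed)
        n_positions += res.n_changed_positions
    return out, n_reads_changed, n_positions
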