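"""k-mer statistics collection (pipeline Step 1).

Every k-mer occurrence in the reads contributes to a per-distinct-k-mer
statistics triple ``(count, quality, error-vector)``: ``count`` is the
number of occurrences, the error vector holds, per position j, the product
over occurrences of the per-base error probabilities q_r[i+j] (kept in
log-space to avoid underflow once counts grow), and the quality is the
probability that the k-mer is erroneous, derived from the error vector.

k-mers containing an uncertain base (N) are discarded; that is the only
masking mechanism in the pipeline.

Two counting paths are provided: an in-memory vectorized hash/unique path
(:func:`collect_statistics`, the default) and a disk-bucketed
sort-and-scan path (:func:`bucketed_count`) that hashes k-mers into spill
files, sorts each file lexicographically and aggregates equal runs.  Both
produce identical indexes (log-aggregates up to summation order).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np

from ._encode import (N_CODE, decode, encode, pack, revcomp_enc, unpack,
                      windows_enc)
from .io_fastq import DEFAULT_CLAMP, Read


def _log_clamped(p: np.ndarray, clamp=DEFAULT_CLAMP) -> np.ndarray:
    return np.log(np.clip(p, clamp[0], clamp[1]))


def _error_free_log_prob(log_error: np.ndarray, clamp=DEFAULT_CLAMP) -> np.ndarray:
    """log p_x = sum_j log(1 - q_x[j]) from log-space error products (stable)."""
    q = np.clip(np.exp(log_error), clamp[0], clamp[1])
    return np.log1p(-q).sum(axis=-1)


@dataclass
class KmerStat:
    """Statistics triple for one distinct k-mer.

    ``log_error[j]`` is the log of the product over all occurrences of the
    per-base error probability at position j.  ``quality`` (the probability
    that the k-mer contains a sequencing error) is 1 - p_x where
    p_x = prod_j (1 - exp(log_error[j])).
    """

    kmer: str
    count: int
    log_error: np.ndarray

    @property
    def error(self) -> np.ndarray:
        """Per-position combined error probabilities q_x[j]."""
        return np.clip(np.exp(self.log_error), *DEFAULT_CLAMP)

    @property
    def log_quality(self) -> float:
        """log of the probability that the k-mer is erroneous (1 - p_x)."""
        return float(np.log1p(-np.exp(_error_free_log_prob(self.log_error))))

    @property
    def quality(self) -> float:
        return float(-np.expm1(_error_free_log_prob(self.log_error)))


@dataclass
class ReadPositions:
    """Valid k-mer occurrences of one read: parallel offset/kmer-id arrays."""

    offsets: np.ndarray
    ids: np.ndarray
    flipped: np.ndarray  # True when the occurrence was reverse-complemented (canonical mode)


class KmerIndex:
    """Aggregated statistics for all distinct k-mers of a read set.

    Observed k-mers are stored in lexicographic order (ids 0..n_observed-1);
    synthetic entries (unobserved consensus centers, count 0) may be appended
    after them and share the same id space but never appear in ``positions``.
    """

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray,
                 log_error: np.ndarray, positions: List[ReadPositions],
                 canonical: bool = False):
        self.k = int(k)
        self.codes = codes
        self.counts = counts
        self.log_error = log_error
        self.positions = positions
        self.canonical = bool(canonical)
        self.n_observed = len(codes)
        self.matrix = unpack(codes, self.k) if len(codes) else np.empty((0, self.k), np.uint8)
        self._synthetic_rows: List[np.ndarray] = []
        self._eflp_cache: Optional[np.ndarray] = None

    # -- basic container interface -------------------------------------------------
    def __len__(self) -> int:
        return self.n_observed

    @property
    def n_total(self) -> int:
        return self.matrix.shape[0]

    def kmer(self, i: int) -> str:
        return decode(self.matrix[i])

    @property
    def kmers(self) -> List[str]:
        return [decode(row) for row in self.matrix[: self.n_observed]]

    def stat(self, i: int) -> KmerStat:
        return KmerStat(kmer=self.kmer(i), count=int(self.counts[i]),
                        log_error=self.log_error[i])

    @property
    def stats(self) -> List[KmerStat]:
        return [self.stat(i) for i in range(self.n_observed)]

    def lookup(self, kmer: str) -> Optional[int]:
        """Id of a k-mer string, or None when absent (searches synthetic too)."""
        code = pack(encode(kmer)[None, :])[0]
        i = self.lookup_codes(np.array([code], dtype=np.uint64))[0]
        return None if i < 0 else int(i)

    def lookup_codes(self, codes: np.ndarray) -> np.ndarray:
        """Vectorized code -> id lookup over observed k-mers; -1 for misses."""
        idx = np.searchsorted(self.codes, codes)
        idx_c = np.minimum(idx, max(self.n_observed - 1, 0))
        hit = (self.n_observed > 0) & (self.codes[idx_c] == codes)
        out = np.where(hit, idx_c, -1)
        if self._synthetic_rows:
            miss = out < 0
            if miss.any():
                synth = {int(pack(r[None, :])[0]): self.n_observed + j
                         for j, r in enumerate(self._synthetic_rows)}
                for pos in np.flatnonzero(miss):
                    out[pos] = synth.get(int(codes[pos]), -1)
        return out

    # -- derived quantities --------------------------------------------------------
    def q_matrix(self, clamp=DEFAULT_CLAMP) -> np.ndarray:
        """Per-k-mer per-position combined error probabilities (clamped)."""
        return np.clip(np.exp(self.log_error), clamp[0], clamp[1])

    def error_free_log_prob(self) -> np.ndarray:
        """log p_x for every indexed k-mer (observed and synthetic); cached."""
        if self._eflp_cache is None or len(self._eflp_cache) != self.n_total:
            self._eflp_cache = _error_free_log_prob(self.log_error)
        return self._eflp_cache

    def error_free_prob(self) -> np.ndarray:
        return np.exp(self.error_free_log_prob())

    # -- synthetic centers ---------------------------------------------------------
    def add_synthetic(self, enc_row: np.ndarray, log_error_row: np.ndarray) -> int:
        """Append an unobserved k-mer (count 0) and return its id."""
        self._synthetic_rows.append(enc_row.copy())
        self.matrix = np.vstack([self.matrix, enc_row[None, :]])
        self.counts = np.append(self.counts, 0)
        self.log_error = np.vstack([self.log_error, log_error_row[None, :]])
        return self.matrix.shape[0] - 1


def enumerate_kmers(read: Read, k: int) -> Iterator[Tuple[int, str]]:
    """Yield (offset, k-mer) for every N-free length-k window of a read."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = read.seq
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if "N" not in w:
            yield i, w


def _read_occurrences(read: Read, k: int, canonical: bool, clamp):
    """Vectorized valid windows of one read.

    Returns (offsets, codes, logq_windows, flipped) with log-q windows already
    oriented to match the stored (possibly canonicalized) k-mer.
    """
    enc = encode(read.seq)
    win = windows_enc(enc, k)
    if win.shape[0] == 0:
        empty = np.empty(0, np.int64)
        return empty, np.empty(0, np.uint64), np.empty((0, k)), np.empty(0, bool)
    valid = ~(win == N_CODE).any(axis=1)
    offsets = np.flatnonzero(valid)
    win = win[valid]
    codes = pack(win)
    logq = np.lib.stride_tricks.sliding_window_view(
        _log_clamped(read.qual, clamp), k)[valid]
    flipped = np.zeros(len(codes), dtype=bool)
    if canonical and len(codes):
        rc_enc = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[win][:, ::-1]
        rc_codes = pack(np.ascontiguousarray(rc_enc))
        flipped = rc_codes < codes
        codes = np.where(flipped, rc_codes, codes)
        logq = np.where(flipped[:, None], logq[:, ::-1], logq)
    return offsets, codes, np.ascontiguousarray(logq), flipped


def collect_statistics(reads: Sequence[Read], k: int, canonical: bool = False,
                       clamp=DEFAULT_CLAMP) -> KmerIndex:
    """Aggregate the statistics triple for every distinct k-mer of the reads."""
    if k < 1:
        raise ValueError("k must be >= 1")
    per_read = [_read_occurrences(r, k, canonical, clamp) for r in reads]
    all_codes = (np.concatenate([p[1] for p in per_read])
                 if per_read else np.empty(0, np.uint64))
    if all_codes.size == 0:
        return KmerIndex(k, np.empty(0, np.uint64), np.empty(0, np.int64),
                         np.empty((0, k)),
                         [ReadPositions(p[0], np.empty(0, np.int64), p[3]) for p in per_read],
                         canonical)
    codes, inverse = np.unique(all_codes, return_inverse=True)
    counts = np.bincount(inverse, minlength=len(codes)).astype(np.int64)
    log_error = np.zeros((len(codes), k))
    all_logq = np.concatenate([p[2] for p in per_read])
    np.add.at(log_error, inverse, all_logq)
    positions, start = [], 0
    for offsets, rc, _, flipped in per_read:
        ids = inverse[start:start + len(rc)].astype(np.int64)
        start += len(rc)
        positions.append(ReadPositions(offsets, ids, flipped))
    return KmerIndex(k, codes, counts, log_error, positions, canonical)


def bucketed_count(reads: Sequence[Read], k: int, n_files: int, workdir,
                   canonical: bool = False, clamp=DEFAULT_CLAMP) -> KmerIndex:
    """Disk-bucketed counting: hash k-mers to spill files, sort, scan.

    Produces the same index as :func:`collect_statistics` (bit-equal counts,
    log-aggregates equal up to floating summation order).  The hash is the
    packed 2-bit code modulo ``n_files`` — stable across runs.
    """
    if n_files < 1:
        raise ValueError("n_files must be >= 1")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    files = [open(workdir / f"bucket_{i}.tsv", "w") for i in range(n_files)]
    try:
        for ri, read in enumerate(reads):
            offsets, codes, logq, flipped = _read_occurrences(read, k, canonical, clamp)
            for o, c, lq, fl in zip(offsets, codes, logq, flipped):
                h = int(c) % n_files
                files[h].write(
                    f"{int(c):016x}\t{ri}\t{int(o)}\t{int(fl)}\t"
                    + ",".join(repr(float(v)) for v in lq) + "\n")
    finally:
        for f in files:
            f.close()

    # sort each bucket lexicographically and aggregate equal runs sequentially
    agg: List[Tuple[int, int, np.ndarray, list]] = []  # (code, count, log_error, occs)
    for i in range(n_files):
        lines = (workdir / f"bucket_{i}.tsv").read_text().splitlines()
        lines.sort()  # hex codes sort like the packed integers, i.e. lexicographically
        run_code, run_count, run_le, run_occ = None, 0, None, []
        for line in lines:
            code_s, ri, off, fl, lq = line.split("\t")
            code = int(code_s, 16)
            lqv = np.array([float(v) for v in lq.split(",")])
            if code != run_code:
                if run_code is not None:
                    agg.append((run_code, run_count, run_le, run_occ))
                run_code, run_count, run_le, run_occ = code, 0, np.zeros(k), []
            run_count += 1
            run_le += lqv
            run_occ.append((int(ri), int(off), bool(int(fl))))
        if run_code is not None:
            agg.append((run_code, run_count, run_le, run_occ))

    agg.sort(key=lambda t: t[0])
    codes = np.array([t[0] for t in agg], dtype=np.uint64)
    counts = np.array([t[1] for t in agg], dtype=np.int64)
    log_error = (np.vstack([t[2] for t in agg]) if agg else np.empty((0, k)))
    per_read_occ: List[List[Tuple[int, int, bool]]] = [[] for _ in reads]
    for kid, t in enumerate(agg):
        for ri, off, fl in t[3]:
            per_read_occ[ri].append((off, kid, fl))
    positions = []
    for occ in per_read_occ:
        occ.sort()
        positions.append(ReadPositions(
            np.array([o for o, _, _ in occ], dtype=np.int64),
            np.array([i for _, i, _ in occ], dtype=np.int64),
            np.array([f for _, _, f in occ], dtype=bool)))
    return KmerIndex(k, codes, counts, log_error, positions, canonical)


def dump_kmer_table(index: KmerIndex, path) -> None:
    """TSV dump: kmer, count, quality (error probability), per-position error products."""
    with open(path, "w") as out:
        out.write("kmer\tcount\tquality\t" +
                  "\t".join(f"err_{j}" for j in range(index.k)) + "\n")
        for i in range(index.n_observed):
            s = index.stat(i)
            out.write(f"{s.kmer}\t{s.count}\t{s.quality:.6g}\t"
                      + "\t".join(f"{v:.6g}" for v in s.error) + "\n")
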