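"""Shared fixtures: tiny worked-example read sets, index builders and the
brute-force Hamming-component oracle."""

from __future__ import annotations

import itertools
from typing import List, Sequence

import networkx as nx
import numpy as np
import pytest

from kmercorrect import Read, collect_statistics
from kmercorrect.kmer_stats import KmerIndex

BASES = "ACGT"


def make_read(seq: str, err_p: float = 0.01, rid: str = "r",
              phred_char: str | None = None) -> Read:
    """A read with uniform per-base error probability."""
    if phred_char is None:
        q = max(2, min(41, round(-10 * np.log10(err_p))))
        phred_char = chr(q + 33)
    return Read(id=rid, seq=seq, qual=np.full(len(seq), err_p),
                raw_qual=phred_char * len(seq))


def index_from_kmers(kmers: Sequence[str], err_p: float = 0.01,
                     counts: Sequence[int] | None = None) -> KmerIndex:
    """Build a KmerIndex whose observed k-mers are exactly `kmers`.

    Each k-mer becomes `count` reads of length k with uniform quality.
    """
    counts = [1] * len(kmers) if counts is None else counts
    reads = []
    for i, (km, c) in enumerate(zip(kmers, counts)):
        for j in range(c):
            reads.append(make_read(km, err_p, rid=f"r{i}_{j}"))
    return collect_statistics(reads, k=len(kmers[0]))


def brute_force_components(kmers: Sequence[str], tau: int) -> List[frozenset]:
    """Independent oracle: all-pairs distances + graph connected components."""
    g = nx.Graph()
    g.add_nodes_from(kmers)
    for x, y in itertools.combinations(kmers, 2):
        if sum(a != b for a, b in zip(x, y)) <= tau:
            g.add_edge(x, y)
    return sorted((frozenset(c) for c in nx.connected_components(g)),
                  key=lambda c: min(c))


def random_kmer_set(rng: np.random.Generator, n: int, k: int) -> List[str]:
    """Distinct k-mers with clustered structure: noisy copies of a few seeds
    plus uniform-random strings."""
    n_seeds = max(1, n // 20)
    seeds = rng.integers(0, 4, size=(n_seeds, k))
    out = set()
    while len(out) < n // 2:
        base = seeds[rng.integers(n_seeds)].copy()
        n_mut = rng.integers(0, 4)
        pos = rng.choice(k, size=min(n_mut, k), replace=False)
        base[pos] = rng.integers(0, 4, size=len(pos))
        out.add("".join(BASES[b] for b in base))
    while len(out) < n:
        out.add("".join(BASES[b] for b in rng.integers(0, 4, size=k)))
    return sorted(out)


def make_noisy_component(centers: Sequence[str], count_each: int, seed: int,
                         phred: int = 30):
    """A synthetic Hamming component: noisy occurrences of each true center.

    Occurrences are reads of length k carrying Phred-`phred` qualities with
    matching substitution probability.  Returns (index, component-over-all).
    """
    from kmercorrect.hamming_graph import HammingComponent

    rng = np.random.default_rng(seed)
    p = 10.0 ** (-phred / 10.0)
    reads = []
    for ci, center in enumerate(centers):
        enc = np.frombuffer(center.encode(), np.uint8)
        for j in range(count_each):
            cur = enc.copy()
            for i in np.flatnonzero(rng.random(len(center)) < p):
                choices = [b for b in b"ACGT" if b != cur[i]]
                cur[i] = choices[rng.integers(3)]
            reads.append(make_read(cur.tobytes().decode(), p, rid=f"c{ci}_{j}"))
    idx = collect_statistics(reads, len(centers[0]))
    return idx, HammingComponent(tuple(range(len(idx))))


# ---- worked example: three overlapping reads and their nine 5-mers ----------

FIG_READS = ["ACGTGTG", "ACATGTG", "ACCTGTC"]


@pytest.fixture
def trio_reads() -> List[Read]:
    return [make_read(s, 0.01, rid=f"t{i}") for i, s in enumerate(FIG_READS)]


@pytest.fixture
def trio_index(trio_reads) -> KmerIndex:
    return collect_statistics(trio_reads, k=5)
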