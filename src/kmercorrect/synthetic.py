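"""Ground-truthed synthetic data emulating the single-cell sequencing regime.

The generator produces a random genome (optionally with near-identical
repeat pairs, which are what makes subclustering necessary), reads sampled
with a smoothly varying lognormal per-locus amplification profile (the
hallmark of MDA single-cell libraries, where coverage swings from ones to
thousands along the genome), and substitution errors injected per base with
probability 10^(-Q/10) for the emitted quality Q — so quality strings are
honest estimates of the true error probabilities.  Both strands are
sampled.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._encode import BASES, decode, encode, revcomp
from .io_fastq import DEFAULT_CLAMP, Read


@dataclass
class RepeatSpec:
    """Plant ``n_copies`` of a segment differing pairwise at ``divergence`` sites."""

    n_copies: int = 2
    length: int = 100
    divergence: int = 2


@dataclass
class CoverageModel:
    """Smooth lognormal amplification profile.

    ``sigma`` is the log-scale standard deviation of the per-locus
    amplification weight (0 means uniform, multi-cell-like coverage);
    ``correlation_bp`` sets how slowly the profile varies along the genome.
    """

    sigma: float = 1.0
    correlation_bp: float = 500.0


@dataclass
class ErrorModel:
    """Per-base qualities ~ round(Normal(mean_phred, sd_phred)), clipped;
    a base is substituted with probability 10^(-Q/10)."""

    mean_phred: float = 20.0
    sd_phred: float = 3.0
    min_phred: int = 2
    max_phred: int = 41
    enabled: bool = True


@dataclass
class GroundTruth:
    """Everything needed to reconstruct each read from the genome."""

    genome: str
    starts: np.ndarray
    strands: np.ndarray           # +1 forward, -1 reverse
    error_positions: List[np.ndarray]   # read-coordinate offsets of injected errors
    read_len: int
    seed: int
    coverage: CoverageModel = field(default_factory=CoverageModel)
    errors: Optional[ErrorModel] = None

    def true_sequence(self, i: int) -> str:
        s = self.genome[self.starts[i]: self.starts[i] + self.read_len]
        return s if self.strands[i] > 0 else revcomp(s)


def make_genome(length: int, gc_fraction: float = 0.5,
                repeat_spec: Optional[RepeatSpec] = None, seed: int = 0) -> str:
    """A random genome; ``repeat_spec`` plants near-identical segment copies."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    enc = rng.choice(4, size=length, p=p).astype(np.uint8)
    if repeat_spec is not None:
        rs = repeat_spec
        if rs.n_copies * rs.length > length:
            raise ValueError("repeat_spec does not fit in the genome")
        if rs.divergence > rs.length:
            raise ValueError("divergence exceeds repeat length")
        slots = length // rs.n_copies
        if slots < rs.length:
            raise ValueError("repeat copies would overlap")
        template = enc[:rs.length].copy()
        for c in range(rs.n_copies):
            copy = template.copy()
            if c > 0:
                sites = rng.choice(rs.length, size=rs.divergence, replace=False)
                copy[sites] = (copy[sites] + rng.integers(1, 4, rs.divergence)) % 4
            enc[c * slots: c * slots + rs.length] = copy
    return decode(enc)


def _start_weights(n_starts: int, model: CoverageModel,
                   rng: np.random.Generator) -> np.ndarray:
    if model.sigma == 0:
        return np.full(n_starts, 1.0 / n_starts)
    g = rng.standard_normal(n_starts)
    if model.correlation_bp > 0:
        g = gaussian_filter1d(g, sigma=model.correlation_bp, mode="wrap")
        sd = g.std()
        if sd > 1e-8:
            g = g / sd  # restore unit variance after smoothing
        else:  # smoothing scale >> genome: profile is flat
            g = np.zeros(n_starts)
    w = np.exp(model.sigma * (g - g.max()))  # shift avoids overflow
    return w / w.sum()


def make_reads(genome: str, n_reads: int, read_len: int,
               coverage_model: Optional[CoverageModel] = None,
               error_model: Optional[ErrorModel] = None,
               seed: int = 0, both_strands: bool = True,
               phred_offset: int = 33) -> Tuple[List[Read], GroundTruth]:
    """Sample reads with MDA-like coverage and quality-consistent errors.

    ``error_model=None`` means the default :class:`ErrorModel` (mean
    Phred 20, ~1% substitutions).  A model with ``enabled=False`` yields
    exact genome substrings (qualities are still emitted).
    """
    if read_len > len(genome):
        raise ValueError("read_len exceeds genome length")
    coverage_model = coverage_model or CoverageModel()
    error_model = ErrorModel() if error_model is None else error_model
    rng = np.random.default_rng(seed)
    n_starts = len(genome) - read_len + 1
    weights = _start_weights(n_starts, coverage_model, rng)
    starts = rng.choice(n_starts, size=n_reads, p=weights)
    strands = (rng.integers(0, 2, n_reads) * 2 - 1) if both_strands \
        else np.ones(n_reads, dtype=np.int64)
    genome_enc = encode(genome)
    em = error_model
    inject = em.enabled
    reads: List[Read] = []
    error_positions: List[np.ndarray] = []
    for i in range(n_reads):
        seg = genome_enc[starts[i]: starts[i] + read_len]
        if strands[i] < 0:
            seg = np.array([3, 2, 1, 0, 4], dtype=np.uint8)[seg][::-1]
        seg = seg.copy()
        q_phred = np.clip(np.rint(rng.normal(em.mean_phred, em.sd_phred, read_len)),
                          em.min_phred, em.max_phred).astype(np.int64)
        err_p = 10.0 ** (-q_phred / 10.0)
        if inject:
            mask = rng.random(read_len) < err_p
            errs = np.flatnonzero(mask)
            seg[errs] = (seg[errs] + rng.integers(1, 4, errs.size)) % 4
        else:
            errs = np.empty(0, dtype=np.int64)
        raw_qual = (q_phred + phred_offset).astype(np.uint8).tobytes().decode("latin-1")
        reads.append(Read(id=f"read_{i}", seq=decode(seg),
                          qual=np.clip(err_p, *DEFAULT_CLAMP), raw_qual=raw_qual))
        error_positions.append(errs)
    truth = GroundTruth(genome=genome, starts=starts, strands=strands,
                        error_positions=error_positions, read_len=read_len,
                        seed=seed, coverage=coverage_model, errors=error_model)
    return reads, truth


def base_error_rate(reads: Sequence[Read], truth: GroundTruth) -> float:
    """Fraction of bases differing from the truth across all reads."""
    n_err = 0
    n_tot = 0
    for i, r in enumerate(reads):
        t = truth.true_sequence(i)[: len(r)]
        n_err += sum(a != b for a, b in zip(r.seq, t))
        n_tot += len(r)
    return n_err / n_tot if n_tot else 0.0


def write_truth_tsv(truth: GroundTruth, reads: Sequence[Read], path) -> None:
    """TSV: read-id, start, strand, comma-joined error offsets."""
    with open(path, "w") as out:
        out.write("read_id\tstart\tstrand\terror_offsets\n")
        for i, r in enumerate(reads):
            errs = ",".join(map(str, truth.error_positions[i].tolist()))
            out.write(f"{r.id}\t{truth.starts[i]}\t"
                      f"{'+' if truth.strands[i] > 0 else '-'}\t{errs}\n")
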