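"""End-to-end correction pipeline and the scikit-learn style estimator.

One iteration executes Steps 1-6 in order: count k-mer statistics, build
Hamming-graph components, subcluster them under the BIC-penalized
quality-weighted likelihood, select and expand the solid set, and correct
every read by consensus voting.  The full pipeline repeats iterations while
a substantial fraction of reads keeps changing (default: stop below 0.2%
of reads changed, or after 3 iterations).

:class:`ReadCorrector` is the primary interface: a transformer whose
``fit`` learns the solid k-mer model from the reads and whose ``transform``
applies consensus correction; ``fit_transform`` runs the full iterative
pipeline.  The module-level :func:`run_iteration` / :func:`run_pipeline`
are thin functional wrappers over it.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .hamming_graph import connected_components
from .io_fastq import DEFAULT_CLAMP, Read
from .kmer_stats import KmerIndex, bucketed_count, collect_statistics
from .solid_correction import (DEFAULT_SOLID_THRESHOLD, SolidSet,
                               correct_reads, expand_solid, select_solid)
from .subclustering import (ErrorProfile, Subcluster, Subclustering,
                            consensus_center, subcluster_component)

logger = logging.getLogger("kmercorrect")


@dataclass
class PipelineConfig:
    """All tunable parameters of the correction pipeline."""

    k: int = 21
    tau: int = 1
    solid_threshold: float = DEFAULT_SOLID_THRESHOLD
    max_iterations: int = 3
    change_fraction_stop: float = 0.002
    phred_offset: int = 33
    max_quadratic: int = 1000
    counting: str = "hash"          # "hash" (in-memory) or "bucketed" (disk)
    n_files: int = 16
    workdir: Optional[str] = None
    seed: int = 0
    canonical: bool = False
    hammer_emulate: bool = False    # skip subclustering: one consensus center per component
    no_expansion: bool = False      # skip iterative solid-set expansion
    bic_distinct: bool = False      # BIC N = distinct k-mers instead of total count
    trim_quality: Optional[float] = None
    epsilon: float = 0.01

    def validate(self) -> None:
        if self.k < self.tau + 1:
            raise ValueError(f"k={self.k} must be >= tau+1={self.tau + 1}")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if not 0.0 < self.solid_threshold < 1.0:
            raise ValueError("solid_threshold must be in (0, 1)")
        if not 0.0 < self.change_fraction_stop <= 1.0:
            raise ValueError("change_fraction_stop must be in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.counting not in ("hash", "bucketed"):
            raise ValueError(f"unknown counting mode {self.counting!r}")
        if self.counting == "bucketed" and self.workdir is None:
            raise ValueError("bucketed counting requires a workdir")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")


@dataclass
class IterationReport:
    """Counters produced by one pipeline iteration."""

    iteration: int
    n_distinct_kmers: int
    n_components: int
    n_subclusters: int
    n_solid_before_expansion: int
    n_solid_after_expansion: int
    n_reads_changed: int
    fraction_reads_changed: float
    n_positions_changed: int = 0


class ReadCorrector(TransformerMixin, BaseEstimator):
    """Quality-aware k-mer spectrum read corrector.

    Parameters mirror :class:`PipelineConfig`.  ``fit`` runs Steps 1-5 on
    the reads (statistics, components, subclustering, solid selection and
    expansion); ``transform`` applies Step 6 (consensus correction) to a
    read set; ``fit_transform`` runs the full iterative pipeline,
    re-fitting on the progressively corrected reads.

    Attributes (after ``fit``)
    --------------------------
    index_ : KmerIndex
        Statistics for every distinct k-mer.
    components_ : list of HammingComponent
    subclusterings_ : list of Subclustering, aligned with ``components_``.
    solid_ : SolidSet
    iteration_reports_ : list of IterationReport (after ``fit_transform``).
    """

    def __init__(self, k: int = 21, tau: int = 1,
                 solid_threshold: float = DEFAULT_SOLID_THRESHOLD,
                 max_iterations: int = 3, change_fraction_stop: float = 0.002,
                 max_quadratic: int = 1000, counting: str = "hash",
                 n_files: int = 16, workdir: Optional[str] = None,
                 seed: int = 0, canonical: bool = False,
                 hammer_emulate: bool = False, no_expansion: bool = False,
                 bic_distinct: bool = False,
                 trim_quality: Optional[float] = None, epsilon: float = 0.01):
        self.k = k
        self.tau = tau
        self.solid_threshold = solid_threshold
        self.max_iterations = max_iterations
        self.change_fraction_stop = change_fraction_stop
        self.max_quadratic = max_quadratic
        self.counting = counting
        self.n_files = n_files
        self.workdir = workdir
        self.seed = seed
        self.canonical = canonical
        self.hammer_emulate = hammer_emulate
        self.no_expansion = no_expansion
        self.bic_distinct = bic_distinct
        self.trim_quality = trim_quality
        self.epsilon = epsilon

    # ------------------------------------------------------------------
    def _config(self) -> PipelineConfig:
        cfg = PipelineConfig(
            k=self.k, tau=self.tau, solid_threshold=self.solid_threshold,
            max_iterations=self.max_iterations,
            change_fraction_stop=self.change_fraction_stop,
            max_quadratic=self.max_quadratic, counting=self.counting,
            n_files=self.n_files, workdir=self.workdir, seed=self.seed,
            canonical=self.canonical, hammer_emulate=self.hammer_emulate,
            no_expansion=self.no_expansion, bic_distinct=self.bic_distinct,
            trim_quality=self.trim_quality, epsilon=self.epsilon)
        cfg.validate()
        return cfg

    def fit(self, X: Sequence[Read], y=None) -> "ReadCorrector":
        """Learn the solid k-mer model (Steps 1-5) from a read set."""
        cfg = self._config()
        t0 = time.perf_counter()
        if cfg.counting == "bucketed":
            index = bucketed_count(X, cfg.k, cfg.n_files, cfg.workdir,
                                   canonical=cfg.canonical)
        else:
            index = collect_statistics(X, cfg.k, canonical=cfg.canonical)
        logger.info("counted %d distinct %d-mers in %.2fs",
                    index.n_observed, cfg.k, time.perf_counter() - t0)

        t0 = time.perf_counter()
        components = connected_components(index, tau=cfg.tau,
                                          max_quadratic=cfg.max_quadratic)
        logger.info("%d components in %.2fs", len(components),
                    time.perf_counter() - t0)

        t0 = time.perf_counter()
        profile = ErrorProfile.from_index(index)
        subclusterings: List[Subclustering] = []
        for comp in components:
            if cfg.hammer_emulate:
                ids = np.asarray(comp.member_ids, dtype=np.int64)
                sc = Subclustering([Subcluster(ids, consensus_center(ids, index))])
            else:
                sc = subcluster_component(comp, index, profile,
                                          distinct_n=cfg.bic_distinct)
            subclusterings.append(sc)
        logger.info("subclustered in %.2fs", time.perf_counter() - t0)

        solid = select_solid(subclusterings, index, cfg.solid_threshold)
        n_before = len(solid)
        if not cfg.no_expansion:
            solid = expand_solid(X, solid, index)
        self.index_ = index
        self.profile_ = profile
        self.components_ = components
        self.subclusterings_ = subclusterings
        self.solid_ = solid
        self.n_solid_before_expansion_ = n_before
        return self

    def transform(self, X: Sequence[Read]) -> List[Read]:
        """Consensus-correct a read set with the fitted solid k-mer model."""
        if not hasattr(self, "solid_"):
            raise RuntimeError("ReadCorrector is not fitted")
        corrected, n_changed, n_pos = correct_reads(X, self.solid_, self.index_)
        self.n_reads_changed_ = n_changed
        self.n_positions_changed_ = n_pos
        return corrected

    def fit_transform(self, X: Sequence[Read], y=None) -> List[Read]:
        """Run the full iterative pipeline; equivalent to :func:`run_pipeline`."""
        cfg = self._config()
        reads = list(X)
        reports: List[IterationReport] = []
        for it in range(1, cfg.max_iterations + 1):
            self.fit(reads)
            reads = self.transform(reads)
            frac = self.n_reads_changed_ / len(reads) if reads else 0.0
            reports.append(IterationReport(
                iteration=it,
                n_distinct_kmers=self.index_.n_observed,
                n_components=len(self.components_),
                n_subclusters=sum(sc.m for sc in self.subclusterings_),
                n_solid_before_expansion=self.n_solid_before_expansion_,
                n_solid_after_expansion=len(self.solid_),
                n_reads_changed=self.n_reads_changed_,
                fraction_reads_changed=frac,
                n_positions_changed=self.n_positions_changed_))
            logger.info("iteration %d: %d/%d reads changed (%.4f)",
                        it, self.n_reads_changed_, len(reads), frac)
            if frac < cfg.change_fraction_stop:
                break
        if cfg.trim_quality is not None:
            reads = [trim_read(r, cfg.trim_quality) for r in reads]
        self.iteration_reports_ = reports
        return reads

    def correct(self, reads: Sequence[Read]) -> List[Read]:
        """Alias for :meth:`fit_transform`."""
        return self.fit_transform(reads)


def trim_read(read: Read, q_threshold: float) -> Read:
    """Trim trailing bases whose error probability exceeds 10^(-Q/10)."""
    cutoff = 10.0 ** (-q_threshold / 10.0)
    keep = len(read)
    while keep > 0 and read.qual[keep - 1] > cutoff:
        keep -= 1
    if keep == len(read):
        return read
    return Read(id=read.id, seq=read.seq[:keep], qual=read.qual[:keep],
                raw_qual=read.raw_qual[:keep])


def run_iteration(reads: Sequence[Read],
                  config: Optional[PipelineConfig] = None
                  ) -> Tuple[List[Read], IterationReport]:
    """One pass of Steps 1-6 over the reads."""
    config = config or PipelineConfig()
    est = ReadCorrector(**_config_kwargs(config))
    est.fit(reads)
    corrected = est.transform(reads)
    report = IterationReport(
        iteration=1,
        n_distinct_kmers=est.index_.n_observed,
        n_components=len(est.components_),
        n_subclusters=sum(sc.m for sc in est.subclusterings_),
        n_solid_before_expansion=est.n_solid_before_expansion_,
        n_solid_after_expansion=len(est.solid_),
        n_reads_changed=est.n_reads_changed_,
        fraction_reads_changed=(est.n_reads_changed_ / len(reads) if reads else 0.0),
        n_positions_changed=est.n_positions_changed_)
    return corrected, report


def run_pipeline(reads: Sequence[Read],
                 config: Optional[PipelineConfig] = None
                 ) -> Tuple[List[Read], List[IterationReport]]:
    """Iterate Steps 1-6 until reads stop changing substantially."""
    config = config or PipelineConfig()
    est = ReadCorrector(**_config_kwargs(config))
    corrected = est.fit_transform(reads)
    return corrected, est.iteration_reports_


def _config_kwargs(config: PipelineConfig) -> dict:
    d = asdict(config)
    d.pop("phred_offset")  # an io_fastq concern, not a model parameter
    return d
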