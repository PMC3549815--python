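import numpy as np
import pytest

from kmercorrect import (ErrorProfile, ReadCorrector, cluster_quality,
                         collect_statistics, connected_components,
                         correct_read, expand_solid, kmer_quality,
                         select_solid, subcluster_component)
from kmercorrect.kmer_stats import KmerStat
from kmercorrect.solid_correction import SolidSet, _covered
from kmercorrect.synthetic import (CoverageModel, ErrorModel, base_error_rate,
                                   make_genome, make_reads)

from conftest import index_from_kmers, make_read


def _stat(q):
    q = np.asarray(q, dtype=float)
    return KmerStat(kmer="A" * len(q), count=1, log_error=np.log(q))


def test_kmer_quality_uniform():
    assert kmer_quality(_stat([0.1, 0.1, 0.1])) == pytest.approx(0.729, rel=1e-9)

def test_kmer_quality_limits():
    assert kmer_quality(_stat([1e-10] * 5)) == pytest.approx(1.0, abs=1e-8)
    assert kmer_quality(_stat([0.5, 1 - 1e-12, 0.5])) == pytest.approx(0.0, abs=1e-6)


def test_cluster_quality_singleton():
    assert cluster_quality([_stat([0.1] * 3)]) == pytest.approx(0.729, rel=1e-9)

def test_cluster_quality_two_halves():
    # p_x = 0.5 each: p_C = 1 - 0.25 = 0.75
    q = 1 - 0.5 ** (1 / 3)
    s = _stat([q] * 3)
    assert cluster_quality([s, s]) == pytest.approx(0.75, rel=1e-6)

def test_cluster_quality_monotone_in_members():
    base = [_stat([0.2] * 3)]
    bigger = base + [_stat([0.4] * 3)]
    assert cluster_quality(bigger) >= cluster_quality(base)

def test_cluster_quality_empty_rejected():
    with pytest.raises(ValueError):
        cluster_quality([])


def _subcluster_all(index):
    prof = ErrorProfile.from_index(index)
    comps = connected_components(index, tau=1)
    return [subcluster_component(c, index, prof) for c in comps]

def test_select_solid_threshold_behaviour():
    # two singleton components with very different qualities
    idx = index_from_kmers(["AAAAA", "TTTTT"], err_p=0.01, counts=[10, 1])
    scs = _subcluster_all(idx)
    p = idx.error_free_prob()
    mid = np.sort(p)[:2].mean()
    solid = select_solid(scs, idx, threshold=float(mid))
    assert len(solid) == 1
    high = select_solid(scs, idx, threshold=float(p.max()))
    assert len(high) == 0
    low = select_solid(scs, idx, threshold=1e-9)
    assert len(low) == 2

def test_select_solid_center_map_total():
    idx = index_from_kmers(["AAAAA", "AAAAT", "TTTTT"], counts=[5, 1, 5])
    scs = _subcluster_all(idx)
    solid = select_solid(scs, idx, threshold=0.5)
    assert (solid.center_of >= 0).all()
    # the satellite's center is the high-count consensus
    sat = idx.lookup("AAAAT")
    assert idx.kmer(solid.center_of[sat]) == "AAAAA"

def test_select_solid_threshold_validated():
    idx = index_from_kmers(["AAAAA"])
    with pytest.raises(ValueError):
        select_solid(_subcluster_all(idx), idx, threshold=1.5)


def _seed_solid(index, kmers):
    solid = SolidSet(index.n_total, index.n_observed)
    solid.center_of = np.arange(index.n_total, dtype=np.int64)
    solid.add([index.lookup(k) for k in kmers])
    return solid

def test_coverage_arithmetic():
    # len 7, k=5: offsets 0 and 2 cover 0-6; offset 2 alone leaves 0-1 bare
    assert _covered(7, np.array([0, 2]), 5)
    assert not _covered(7, np.array([2]), 5)
    assert not _covered(7, np.array([0]), 5)
    assert not _covered(7, np.array([]), 5)

def test_expansion_covered_read_promotes_middle_kmer():
    reads = [make_read("ACGTGTG")]
    idx = collect_statistics(reads, 5)
    solid = _seed_solid(idx, ["ACGTG", "GTGTG"])
    expand_solid(reads, solid, idx)
    assert solid.is_solid(idx.lookup("CGTGT"))
    assert solid.expansion_passes == 1

def test_expansion_uncovered_read_contributes_nothing():
    reads = [make_read("ACGTGTG")]
    idx = collect_statistics(reads, 5)
    solid = _seed_solid(idx, ["ACGTG"])  # positions 5-6 uncovered
    before = len(solid)
    expand_solid(reads, solid, idx)
    assert len(solid) == before and solid.expansion_passes == 0

def test_expansion_chain_takes_two_passes():
    # expanding read A makes read B fully covered on the next pass
    reads = [make_read("ACGTGTG", rid="A"), make_read("CGTGTGCATG", rid="B")]
    idx = collect_statistics(reads, 5)
    solid = _seed_solid(idx, ["ACGTG", "GTGTG", "GTGCA", "TGCAT", "GCATG"])
    expand_solid(reads, solid, idx)
    assert solid.expansion_passes == 2
    assert len(solid) == len(idx)  # every k-mer solid at the fixed point

def _random_expansion_fixture(seed):
    rng = np.random.default_rng(seed)
    genome = make_genome(150, seed=seed)
    reads, _ = make_reads(genome, 15, 40,
                          coverage_model=CoverageModel(sigma=0),
                          error_model=ErrorModel(enabled=False), seed=seed)
    idx = collect_statistics(reads, 11)
    seed_ids = rng.choice(len(idx), size=max(1, len(idx) // 3), replace=False)
    return reads, idx, seed_ids

@pytest.mark.parametrize("seed", range(20))
def test_expansion_monotone_and_order_independent(seed):
    reads, idx, seed_ids = _random_expansion_fixture(seed)
    solid = SolidSet(idx.n_total, idx.n_observed)
    solid.center_of = np.arange(idx.n_total, dtype=np.int64)
    solid.add(seed_ids)
    before = solid.solid_mask.copy()
    expand_solid(reads, solid, idx)
    assert (solid.solid_mask | before).sum() == solid.solid_mask.sum()  # grew only

    # reversing read order: permute the index positions consistently
    idx_rev = collect_statistics(reads[::-1], 11)
    assert np.array_equal(idx.codes, idx_rev.codes)
    solid_rev = SolidSet(idx_rev.n_total, idx_rev.n_observed)
    solid_rev.center_of = np.arange(idx_rev.n_total, dtype=np.int64)
    solid_rev.add(seed_ids)
    expand_solid(reads[::-1], solid_rev, idx_rev)
    assert np.array_equal(solid.solid_mask, solid_rev.solid_mask)


def test_correct_read_all_solid_is_identity():
    reads = [make_read("ACGTGTG")]
    idx = collect_statistics(reads, 5)
    solid = _seed_solid(idx, ["ACGTG", "CGTGT", "GTGTG"])
    out = correct_read(reads[0], solid, idx)
    assert not out.changed and out.corrected.seq == "ACGTGTG"

def test_correct_read_shorter_than_k_unchanged():
    reads = [make_read("ACG")]
    idx = collect_statistics(reads, 5)
    solid = SolidSet(max(idx.n_total, 1), idx.n_observed)
    out = correct_read(reads[0], solid, idx)
    assert not out.changed

def test_correct_read_zero_votes_keep_original():
    reads = [make_read("ACGTGTG")]
    idx = collect_statistics(reads, 5)
    solid = _seed_solid(idx, [])  # nothing solid, no centers solid
    out = correct_read(reads[0], solid, idx)
    assert not out.changed and out.corrected.seq == "ACGTGTG"

def test_correct_read_fixes_single_error():
    """Flanking solid k-mers and solid centers of the erroneous k-mers vote
    the true base: exactly one nucleotide is changed."""
    genome = make_genome(60, seed=7)
    reads, truth = make_reads(genome, 24, 30,
                              coverage_model=CoverageModel(sigma=0),
                              error_model=ErrorModel(enabled=False),
                              seed=8, both_strands=False)
    # inject one error in the middle of read 0
    r0 = reads[0]
    pos = 15
    wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[r0.seq[pos]]
    bad = r0.seq[:pos] + wrong + r0.seq[pos + 1:]
    reads[0] = type(r0)(id=r0.id, seq=bad, qual=r0.qual, raw_qual=r0.raw_qual)

    est = ReadCorrector(k=15, solid_threshold=0.99)
    corrected = est.fit_transform(reads)
    assert corrected[0].seq == truth.true_sequence(0)
    assert sum(a != b for a, b in zip(corrected[0].seq, bad)) == 1
    # untouched reads stay identical
    assert all(c.seq == r.seq for c, r in zip(corrected[1:], reads[1:]))

def test_correction_preserves_length_and_quality():
    genome = make_genome(500, seed=3)
    reads, _ = make_reads(genome, 150, 60, seed=4)
    est = ReadCorrector(k=15)
    corrected = est.fit_transform(reads)
    assert [len(c) for c in corrected] == [len(r) for r in reads]
    assert [c.raw_qual for c in corrected] == [r.raw_qual for r in reads]


def test_pipeline_idempotent_on_clean_reads():
    genome = make_genome(2000, seed=21)
    reads, _ = make_reads(genome, 600, 100,
                          error_model=ErrorModel(mean_phred=30, enabled=False),
                          seed=22)
    est = ReadCorrector()
    corrected = est.fit_transform(reads)
    assert all(c.seq == r.seq for c, r in zip(corrected, reads))
    assert est.iteration_reports_[0].n_reads_changed == 0


def test_error_reduction_across_seeds():
    """Corrected base error rate is at least 10x below the input rate on an
    MDA-like fixture (3 kb genome, ~30x mean lognormal coverage, ~1% errors)
    for at least 9 of 10 seeds."""
    reductions = []
    for seed in range(10):
        genome = make_genome(3000, seed=100 + seed)
        reads, truth = make_reads(genome, 900, 100, seed=200 + seed)
        r_in = base_error_rate(reads, truth)
        corrected = ReadCorrector().fit_transform(reads)
        r_out = base_error_rate(corrected, truth)
        reductions.append(r_in / max(r_out, 1e-12))
    passing = sum(1 for v in reductions if v >= 10.0)
    assert passing >= 9, f"reductions: {reductions}"
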