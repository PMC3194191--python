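import numpy as np
import pytest

from segext.classify import (CONCORDANT, DISCORDANT, FLAG_OEA, FLAG_ORPHAN,
                             OEA, ORPHAN, CoverageProfile,
                             InsertSizeModel, build_irs, classify_pair,
                             classify_pairs, cluster_oea, compute_coverage,
                             over_coverage_probability, select_over_coverage)
from segext.mapping import FORWARD, REVERSE, MappingLoc, MappingTable


def F(pos, mm=0):
    return MappingLoc(pos, FORWARD, mm)


def R(pos, mm=0):
    return MappingLoc(pos, REVERSE, mm)


def make_table(per_pair, l=36, d=2):
    """Build a MappingTable from [(plus_locs, minus_locs), ...]."""
    n = len(per_pair)
    table = MappingTable(n_pairs=n, read_length=l, d=d)
    for mate in (0, 1):
        rows, pos, strand, mism = [], [], [], []
        for i, locs in enumerate(per_pair):
            for loc in locs[mate]:
                rows.append(i)
                pos.append(loc.position)
                strand.append(loc.strand)
                mism.append(loc.mismatches)
        counts = np.bincount(np.array(rows, dtype=np.int64), minlength=n)
        table.offsets.append(
            np.concatenate([[0], np.cumsum(counts)]).astype(np.int64))
        order = np.argsort(np.array(rows), kind="stable")
        table.pos.append(np.array(pos, dtype=np.int64)[order])
        table.strand.append(np.array(strand, dtype=np.uint8)[order])
        table.mism.append(np.array(mism, dtype=np.int32)[order])
    return table


class TestClassifyPair:
    def test_textbook_examples(self, model):
        # span 264 + 36 - 100 = 200 within [125, 275]
        assert classify_pair([F(100)], [R(264)], model, 36) == CONCORDANT
        assert classify_pair([F(100)], [], model, 36) == OEA
        assert classify_pair([], [], model, 36) == ORPHAN
        assert classify_pair([F(100)], [R(5100)], model, 36) == DISCORDANT

    def test_orientation_required(self, model):
        assert classify_pair([F(100)], [F(264)], model, 36) == DISCORDANT
        # reverse-then-forward order also concordant when span fits
        assert classify_pair([R(264)], [F(100)], model, 36) == CONCORDANT

    def test_existential_over_location_sets(self, model):
        plus = [F(100), F(9000)]
        minus = [R(5000), R(264)]
        assert classify_pair(plus, minus, model, 36) == CONCORDANT

    def test_monotone_in_interval(self, model):
        wide = InsertSizeModel(mu=200, sigma=60)
        rng = np.random.default_rng(0)
        for _ in range(200):
            plus = [F(int(rng.integers(0, 5000)))]
            minus = [R(int(rng.integers(0, 5000)))]
            if classify_pair(plus, minus, model, 36) == CONCORDANT:
                assert classify_pair(plus, minus, wide, 36) == CONCORDANT

    def test_vectorised_equals_scalar(self, model):
        rng = np.random.default_rng(1)
        per_pair = []
        for _ in range(300):
            def locs():
                k = int(rng.integers(0, 3))
                return [MappingLoc(int(rng.integers(0, 3000)),
                                   int(rng.integers(0, 2)), 0)
                        for _ in range(k)]
            per_pair.append((locs(), locs()))
        table = make_table(per_pair)
        labels = classify_pairs(table, model)
        for i, (p, m) in enumerate(per_pair):
            assert labels[i] == classify_pair(p, m, model, 36)

    def test_partition_property(self, small_pipeline, model):
        labels = small_pipeline["labels"]
        assert set(np.unique(labels)) <= {OEA, ORPHAN, CONCORDANT, DISCORDANT}


class TestCoverage:
    def test_single_read_depth(self):
        table = make_table([([F(0)], [])], l=36)
        prof = compute_coverage(table, 100, seed=0)
        assert prof.depth[:36].tolist() == [1] * 36
        assert prof.depth[36:].sum() == 0
        assert prof.mu_doc == 1.0

    def test_duplicate_reads_double_per_read_depth(self):
        one = compute_coverage(make_table([([F(10)], [])]), 100, seed=0)
        two = compute_coverage(make_table([([F(10)], []), ([F(10)], [])]),
                               100, seed=0)
        r1 = one.mu_doc_read[0][0]
        r2 = two.mu_doc_read[0][0]
        assert r2 == pytest.approx(2 * r1)

    def test_uniform_simulation_hits_nominal_coverage(self, small_pipeline,
                                                      small_ds):
        prof = small_pipeline["profile"]
        assert abs(prof.mu_doc - small_ds.spec.coverage) < 1.0


class TestOverCoverage:
    def test_probability_rule(self):
        assert over_coverage_probability(40.0, 80.0) == pytest.approx(0.5)
        assert over_coverage_probability(40.0, 40.0) == 0.0
        assert over_coverage_probability(40.0, 10.0) == 0.0
        with pytest.raises(RuntimeError):
            over_coverage_probability(0.0, 80.0)

    def test_admitted_fraction_at_three_fold(self):
        # region at 3x mean: expected admitted fraction (k-1)/k = 2/3
        n = 30_000
        labels = np.full(n, CONCORDANT, dtype=np.uint8)
        prof = CoverageProfile(
            depth=np.ones(10, dtype=np.int64), mu_doc=1.0,
            mu_doc_read=[np.full(n, 3.0), np.full(n, 3.0)],
            placement=[np.zeros(n, np.int64), np.zeros(n, np.int64)])
        irs = build_irs(labels, prof, seed=5)
        frac = len(irs) / n
        assert abs(frac - 2 / 3) < 0.01

    def test_single_pair_draw(self):
        prof = CoverageProfile(
            depth=np.ones(10, dtype=np.int64), mu_doc=1.0,
            mu_doc_read=[np.array([2.0]), np.array([2.0])],
            placement=[np.zeros(1, np.int64), np.zeros(1, np.int64)])
        rng = np.random.default_rng(0)
        draws = [select_over_coverage(0, prof, rng) for _ in range(4000)]
        assert abs(np.mean(draws) - 0.5) < 0.03


class TestInsertionReadSet:
    def test_no_insertions_yields_no_oea_or_orphans(self, model):
        from segext.mapping import build_reference_index, map_reads
        from segext.simulate import (SimulationSpec, generate_reference,
                                     sample_reads)

        spec = SimulationSpec(reference_length=40_000, n_insertions=0,
                              coverage=10.0, error_rate=0.0, seed=9)
        ref = generate_reference(40_000, seed=9)
        reads = sample_reads(ref, spec)
        table = map_reads(build_reference_index(ref), reads.reads1,
                          reads.reads2, d=2)
        labels = classify_pairs(table, model)
        prof = compute_coverage(table, len(ref), seed=9)
        irs = build_irs(labels, prof, seed=9)
        assert not (irs.flags & (FLAG_OEA | FLAG_ORPHAN)).any()
        assert len(irs) <= table.n_pairs

    def test_insertion_reads_are_members(self, small_ds, small_pipeline):
        ds = small_ds
        irs = small_pipeline["irs"]
        flags = np.zeros(ds.reads.n_pairs, dtype=np.uint8)
        flags[irs.pair_indices] = irs.flags
        l = ds.reads.read_length
        for t in ds.truth:
            a, b = t.donor_locus, t.donor_locus + len(t.true_sequence)
            starts1 = ds.reads.frag_start
            starts2 = ds.reads.frag_start + ds.reads.frag_len - l
            in1 = (starts1 > a) & (starts1 + l < b)
            in2 = (starts2 > a) & (starts2 + l < b)
            inside = np.flatnonzero(in1 | in2)
            assert len(inside) > 0
            assert (flags[inside] > 0).all()

    def test_membership_is_deterministic(self, small_pipeline, model,
                                         small_ds):
        labels = small_pipeline["labels"]
        prof = small_pipeline["profile"]
        a = build_irs(labels, prof, seed=7)
        b = build_irs(labels, prof, seed=7)
        assert np.array_equal(a.pair_indices, b.pair_indices)
        assert np.array_equal(a.flags, b.flags)


class TestClusterOea:
    def test_empty_input(self, model):
        table = make_table([([F(100)], [R(264)])])
        labels = classify_pairs(table, model)
        assert cluster_oea(table, labels, model) == []

    def test_planted_insertions_are_localised(self, small_ds, small_pipeline,
                                              model):
        clusters = cluster_oea(small_pipeline["table"],
                               small_pipeline["labels"], model,
                               min_support=4)
        assert clusters, "expected OEA clusters at planted insertions"
        for t in small_ds.truth:
            assert any(s - 40 <= t.ref_locus <= e + 40
                       for s, e, _ in clusters), t.ref_locus

    def test_distant_insertions_make_disjoint_clusters(self, small_ds,
                                                       small_pipeline, model):
        clusters = cluster_oea(small_pipeline["table"],
                               small_pipeline["labels"], model,
                               min_support=4)
        # the two planted loci are far apart: at least two clusters
        assert len(clusters) >= 2
        spans = sorted((s, e) for s, e, _ in clusters)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
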