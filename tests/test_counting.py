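import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paracnv import (
    CountMatrix,
    GeneInterval,
    SampleMeta,
    count_overlaps,
    deduplicate,
    filter_genes,
    group_ratio_report,
    normalize,
)

from conftest import make_record


class TestDeduplicate:
    def test_highest_mapq_survives(self):
        recs = [
            make_record("r1", "chr1", 100, mapq=30),
            make_record("r2", "chr1", 100, mapq=42),
        ]
        out = list(deduplicate(recs))
        assert [r.read_id for r in out] == ["r2"]

    def test_different_positions_both_survive(self):
        recs = [make_record("r1", "chr1", 100), make_record("r2", "chr1", 101)]
        assert len(list(deduplicate(recs))) == 2

    def test_tie_keeps_first_in_input_order(self):
        recs = [
            make_record("r1", "chr1", 100, mapq=10),
            make_record("r2", "chr1", 100, mapq=10),
            make_record("r3", "chr1", 100, mapq=10),
        ]
        out = list(deduplicate(recs))
        assert [r.read_id for r in out] == ["r1"]

    def test_unsorted_input_rejected(self):
        recs = [make_record("r1", "chr1", 200), make_record("r2", "chr1", 100)]
        with pytest.raises(ValueError, match="r2"):
            list(deduplicate(recs))

    @given(
        st.lists(
            st.tuples(st.integers(0, 30), st.integers(0, 60)), max_size=40
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_idempotent(self, pos_mapq):
        recs = sorted(
            (make_record(f"r{i}", "chr1", p, mapq=q) for i, (p, q) in enumerate(pos_mapq)),
            key=lambda r: r.start,
        )
        once = list(deduplicate(recs))
        twice = list(deduplicate(once))
        assert once == twice
        assert len({r.start for r in once}) == len(once)


class TestCountOverlaps:
    GENES = [
        GeneInterval("g1", "chr1", 0, 200),
        GeneInterval("g2", "chr1", 200, 500),
        GeneInterval("g3", "chr2", 50, 300),
    ]

    def test_overlap_and_halfopen_boundary(self):
        inside = [make_record("r1", "chr1", 100)]  # [100,136) within g1
        counts, total = count_overlaps(inside, self.GENES)
        assert counts.tolist() == [1, 0, 0] and total == 1
        boundary = [make_record("r2", "chr1", 200)]  # [200,236): g2 only
        counts, _ = count_overlaps(boundary, self.GENES)
        assert counts.tolist() == [0, 1, 0]

    def test_hand_placed_reads_match_brute_force(self):
        starts = [(("chr1", s)) for s in (0, 150, 180, 199, 250, 490)] + [("chr2", 40)]
        reads = [make_record(f"r{i}", c, s) for i, (c, s) in enumerate(starts)]
        counts, total = count_overlaps(reads, self.GENES)
        brute = [
            sum(
                1
                for r in reads
                if r.chrom == g.chrom and r.start < g.end and r.end > g.start
            )
            for g in self.GENES
        ]
        assert counts.tolist() == brute
        assert total == len(reads)
        # the read at chr1:180 spans the g1/g2 boundary and counts toward both
        assert brute[0] >= 4 and brute[1] >= 3

    @given(
        st.lists(st.integers(0, 600), max_size=50),
        st.lists(st.tuples(st.integers(0, 550), st.integers(1, 80)), min_size=1, max_size=8),
    )
    @settings(deadline=None, max_examples=50)
    def test_random_reads_match_brute_force(self, read_starts, gene_spans):
        genes = [
            GeneInterval(f"g{i}", "chr1", s, s + l)
            for i, (s, l) in enumerate(gene_spans)
        ]
        reads = [make_record(f"r{i}", "chr1", s) for i, s in enumerate(read_starts)]
        counts, _ = count_overlaps(reads, genes)
        brute = [
            sum(1 for r in reads if r.start < g.end and r.end > g.start)
            for g in genes
        ]
        assert counts.tolist() == brute


class TestFilterGenes:
    def test_toy_matrix_matches_hand_computation(self, toy_filter_matrix):
        matrix, expected = toy_filter_matrix
        kept, log = filter_genes(matrix)
        assert kept.gene_ids == expected
        removed = dict(zip(log.gene_id, zip(log.low_median_per_100bp,
                                            log.zero_count_individual)))
        assert removed["g0"] == (True, False)   # median 0.8 per 100 bp
        assert removed["g2"] == (False, True)   # one zero individual
        assert removed["g7"] == (True, True)    # both rules
        assert removed["g9"] == (True, False)

    def test_equality_boundary_retained(self, toy_filter_matrix):
        # g1: median exactly 1.0 per 100 bp — "less than one" excludes equality
        matrix, _ = toy_filter_matrix
        kept, _ = filter_genes(matrix)
        assert "g1" in kept.gene_ids

    def test_never_retains_gene_with_a_zero_count(self):
        rng = np.random.default_rng(0)
        genes = [GeneInterval(f"g{i}", "c", i * 100, i * 100 + 50) for i in range(30)]
        counts = rng.integers(0, 5, (30, 6))
        samples = [SampleMeta(f"s{j}", "A" if j < 3 else "B", 10_000) for j in range(6)]
        kept, _ = filter_genes(CountMatrix(genes, samples, counts))
        assert (kept.counts > 0).all()


class TestNormalize:
    def _matrix(self, counts, totals):
        counts = np.asarray(counts)
        genes = [GeneInterval(f"g{i}", "c", i * 10, i * 10 + 5)
                 for i in range(counts.shape[0])]
        samples = [
            SampleMeta(f"s{j}", "A" if j % 2 == 0 else "B", t)
            for j, t in enumerate(totals)
        ]
        return CountMatrix(genes, samples, counts)

    def test_basic_division(self):
        m = normalize(self._matrix([[10]], [1_000_000]))
        assert m.normalized[0, 0] == pytest.approx(1e-5)
        assert m.counts[0, 0] == 10  # counts untouched

    def test_scale_invariance(self):
        m1 = normalize(self._matrix([[10, 7]], [1000, 500]))
        m2 = normalize(self._matrix([[20, 7]], [2000, 500]))
        np.testing.assert_allclose(m1.normalized, m2.normalized)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="s0"):
            normalize(self._matrix([[1]], [0]))


class TestGroupRatioReport:
    def _matrix(self):
        genes = [GeneInterval("g1", "c", 0, 100), GeneInterval("g2", "c", 200, 400)]
        samples = [SampleMeta(s, g, 1000) for s, g in
                   [("a1", "A"), ("a2", "A"), ("b1", "B"), ("b2", "B")]]
        counts = np.array([[4, 4, 2, 2], [3, 3, 3, 3]])
        return normalize(CountMatrix(genes, samples, counts))

    def test_ratios(self):
        rep = group_ratio_report(self._matrix(), "A", "B")
        assert rep.ratio.tolist() == [2.0, 1.0]

    def test_pair_sd_hand_computed(self):
        genes = [GeneInterval("g1", "c", 0, 100)]
        samples = [SampleMeta(s, g, 1000) for s, g in
                   [("a1", "A"), ("a2", "A"), ("a3", "A"),
                    ("b1", "B"), ("b2", "B"), ("b3", "B")]]
        counts = np.array([[10, 20, 30, 10, 10, 10]])
        m = normalize(CountMatrix(genes, samples, counts))
        rep = group_ratio_report(
            m, "A", "B", pairing=[("a1", "b1"), ("a2", "b2"), ("a3", "b3")]
        )
        # pair ratios {1, 2, 3} -> sample sd exactly 1
        assert rep.ratio_sd[0] == pytest.approx(1.0)

    def test_zero_denominator_flagged_not_raised(self):
        genes = [GeneInterval("g1", "c", 0, 100)]
        samples = [SampleMeta(s, g, 1000) for s, g in
                   [("a1", "A"), ("b1", "B"), ("b2", "B")]]
        m = normalize(CountMatrix(genes, samples, np.array([[5, 0, 0]])))
        rep = group_ratio_report(m, "A", "B")
        assert bool(rep.undefined[0]) and np.isnan(rep.ratio[0])

    def test_region_restriction(self):
        rep = group_ratio_report(self._matrix(), "A", "B", region=["g2"])
        assert rep.gene_id.tolist() == ["g2"]


def test_count_matrix_tsv_round_trip(tmp_path, toy_filter_matrix):
    matrix, _ = toy_filter_matrix
    p = tmp_path / "counts.tsv"
    matrix.to_tsv(p)
    back = CountMatrix.from_tsv(p)
    assert back.gene_ids == matrix.gene_ids
    assert back.groups == matrix.groups
    np.testing.assert_array_equal(back.counts, matrix.counts)
    np.testing.assert_array_equal(back.totals, matrix.totals)
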