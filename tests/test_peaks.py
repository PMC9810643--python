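import math

import numpy as np
import pytest
from intervaltree import IntervalTree

from longatac import peaks as pk
from longatac.io import fragments_to_ends
from longatac.model import InsertionEnd, Peak


def _ends(positions, chrom="chr1", cell="c"):
    return [InsertionEnd(cell, chrom, int(p), "left") for p in positions]


def _poisson_tail(k, lam):
    """Independent upper-tail oracle: P(X >= k) by direct summation."""
    term = math.exp(-lam)
    cdf = 0.0
    for i in range(k):
        cdf += term
        term *= lam / (i + 1)
    return 1.0 - cdf


class TestCallPeaks:
    def test_spike_called_with_closed_form_p(self):
        # uniform background at 1 end/kb; one window holds 20 extra ends
        chrom_lengths = {"chr1": 1_000_000}
        rng = np.random.default_rng(0)
        background = rng.integers(0, 1_000_000, 1000)
        spike = 500_000 + rng.integers(0, 500, 20)
        ends = _ends(np.concatenate([background, spike]))
        params = pk.PeakCallParams()
        called = pk.call_peaks(ends, chrom_lengths, params)
        assert any(p.start <= 500_250 < p.end for p in called)
        windows = pk.scan_windows(ends, chrom_lengths, params)
        (w,) = [w for w in windows if w[1] == 500_000]
        k = w[3]
        # local rate window (10 kb) holds nearly all spike ends, so the
        # local lambda exceeds the genome-wide one
        local = sum(1 for e in ends if abs(e.pos - 500_250) <= 5000)
        lam = max(1020 / 1_000_000, local / 10_000) * 500
        assert w[4] == pytest.approx(_poisson_tail(k, lam), rel=1e-6)

    def test_empty_input_empty_output(self):
        assert pk.call_peaks([], {"chr1": 10_000}) == []

    def test_sparse_background_no_peaks(self):
        ends = _ends(range(0, 100_000, 5000))
        assert pk.call_peaks(ends, {"chr1": 100_000}) == []

    def test_nearby_windows_merge(self):
        # two dense clusters 550 bp apart: windows overlap/abut within merge gap
        ends = _ends([1000 + i for i in range(30)] + [1550 + i for i in range(30)])
        called = pk.call_peaks(ends, {"chr1": 100_000})
        assert len(called) == 1
        assert called[0].start <= 1000 and called[0].end >= 1580

    def test_relaxing_threshold_only_grows_peaks(self, small_experiment):
        cfg, fragments, _, _ = small_experiment
        ends = fragments_to_ends(fragments)
        strict = pk.call_peaks(ends, cfg.chrom_lengths, pk.PeakCallParams(p_threshold=1e-8))
        loose = pk.call_peaks(ends, cfg.chrom_lengths, pk.PeakCallParams(p_threshold=1e-4))
        for s in strict:
            assert any(
                l.chrom == s.chrom and l.start <= s.start and s.end <= l.end
                for l in loose
            )

    def test_deterministic_and_disjoint(self, small_experiment):
        cfg, fragments, _, _ = small_experiment
        ends = fragments_to_ends(fragments)
        a = pk.call_peaks(ends, cfg.chrom_lengths)
        b = pk.call_peaks(ends, cfg.chrom_lengths)
        assert [(p.chrom, p.start, p.end) for p in a] == [(p.chrom, p.start, p.end) for p in b]
        for p1, p2 in zip(a[:-1], a[1:]):
            if p1.chrom == p2.chrom:
                assert p1.end <= p2.start

    def test_planted_peaks_recovered(self, small_experiment):
        cfg, fragments, _, truth = small_experiment
        ends = fragments_to_ends(fragments)
        called = pk.call_peaks(ends, cfg.chrom_lengths)
        _, recall = pk.benchmark_peaks(called, truth.peaks)
        assert recall >= 0.9


class TestPeakOverlap:
    def test_trivial_cases(self):
        a, b = [Peak("chr1", 0, 10)], [Peak("chr1", 5, 15)]
        assert pk.peak_overlap(a, b) == (1, 1.0, 1, 1.0)
        c = [Peak("chr2", 0, 10)]
        assert pk.peak_overlap(a, c) == (0, 0.0, 0, 0.0)

    def test_min_bp_requirement(self):
        a, b = [Peak("chr1", 0, 10)], [Peak("chr1", 9, 20)]
        assert pk.peak_overlap(a, b, min_bp=1)[0] == 1
        assert pk.peak_overlap(a, b, min_bp=2)[0] == 0

    def test_matches_intervaltree_oracle(self):
        rng = np.random.default_rng(5)
        def random_set(n):
            starts = np.sort(rng.choice(10_000, n, replace=False)) * 10
            return [Peak("chr1", int(s), int(s) + int(rng.integers(5, 80))) for s in starts]
        a, b = random_set(300), random_set(300)
        tree = IntervalTree()
        for p in b:
            tree[p.start:p.end] = None
        expect_a = sum(1 for p in a if tree.overlap(p.start, p.end))
        na, _, _, _ = pk.peak_overlap(a, b)
        assert na == expect_a


class TestBenchmark:
    def test_perfect_and_toy_counts(self):
        a = [Peak("chr1", 0, 10), Peak("chr1", 100, 110), Peak("chr1", 200, 210)]
        ref_same = [Peak("chr1", 0, 10), Peak("chr1", 100, 110), Peak("chr1", 300, 310)]
        assert pk.benchmark_peaks(a, a) == (1.0, 1.0)
        precision, recall = pk.benchmark_peaks(a, ref_same)
        assert precision == pytest.approx(2 / 3) and recall == pytest.approx(2 / 3)

    def test_empty_reference_fatal(self):
        with pytest.raises(ValueError):
            pk.benchmark_peaks([Peak("chr1", 0, 10)], [])


class TestAnnotate:
    def test_single_category(self):
        called = [Peak("chr1", 0, 10), Peak("chr1", 50, 60)]
        counts, fracs = pk.annotate_peaks(called, {"PLS": [Peak("chr1", 0, 100)]})
        assert counts["PLS"] == 2 and fracs["PLS"] == 1.0

    def test_priority_breaks_multi_category_ties(self):
        called = [Peak("chr1", 10, 20)]
        cats = {"dELS": [Peak("chr1", 0, 100)], "PLS": [Peak("chr1", 0, 100)]}
        counts, _ = pk.annotate_peaks(called, cats)
        assert counts["PLS"] == 1 and counts["dELS"] == 0

    def test_fractions_sum_to_one_and_unannotated(self):
        called = [Peak("chr1", 0, 10), Peak("chr1", 500, 510)]
        counts, fracs = pk.annotate_peaks(called, {"CTCF-only": [Peak("chr1", 0, 100)]})
        assert counts["unannotated"] == 1
        assert sum(fracs.values()) == pytest.approx(1.0)


class TestMatrices:
    def test_single_entry(self):
        mat, cells, names = pk.peak_cell_matrix(
            _ends([5], cell="cellA"), [Peak("chr1", 0, 10, name="p0")]
        )
        assert mat.toarray().tolist() == [[1.0]]
        assert cells == ["cellA"] and names == ["p0"]

    def test_column_sums_equal_frip_numerators(self, small_experiment):
        from longatac import qc

        cfg, fragments, _, truth = small_experiment
        ends = fragments_to_ends(fragments)
        mat, _, _ = pk.peak_cell_matrix(ends, truth.peaks)
        total_in_peaks = qc.frip(ends, truth.peaks) * len(ends)
        assert mat.sum() == pytest.approx(total_in_peaks)

    def test_gene_score_strand_aware_upstream(self):
        genes = [("gA", "chr1", 5000, 6000, "+"), ("gB", "chr1", 5000, 6000, "-")]
        # end at 4500 is upstream of gA (plus strand) only;
        # end at 6500 is upstream of gB (minus strand) only
        mat, cells, names = pk.gene_score(
            _ends([4500, 6500], cell="c"), genes, upstream_bp=2000
        )
        arr = mat.toarray()
        assert names == ["gA", "gB"]
        assert arr.tolist() == [[1.0, 1.0]]
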