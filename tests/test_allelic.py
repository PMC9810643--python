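import numpy as np
import pytest

from longatac import allelic
from longatac.model import Fragment, Peak, PhasedVariant


def _variant(pos, chrom="chr1", h1="A", h2="G"):
    return PhasedVariant(chrom, pos, "A", "G", h1, h2, phase_set="ps", phased=True)


def _read(rid, alleles, start=0, end=10_000, cell="c"):
    return Fragment(cell, "chr1", start, end, alleles=alleles, read_id=rid)


class TestHaplotypeReads:
    def test_unanimous_assignment(self):
        variants = [_variant(p) for p in (100, 200, 300)]
        read = _read("r1", {100: "A", 200: "A", 300: "A"})
        (h,) = allelic.haplotype_reads([read], variants).values()
        assert h.assigned == "hap1" and h.n_hap1_support == 3

    def test_tie_is_ambiguous(self):
        variants = [_variant(p) for p in (100, 200, 300, 400)]
        read = _read("r1", {100: "A", 200: "A", 300: "G", 400: "G"})
        (h,) = allelic.haplotype_reads([read], variants).values()
        assert h.assigned == "ambiguous"

    def test_consistency_threshold(self):
        variants = [_variant(p) for p in (1, 2, 3, 4, 5)]
        # 3 vs 2: margin 1 but max fraction 0.6 < 0.67
        read = _read("r1", {1: "A", 2: "A", 3: "A", 4: "G", 5: "G"})
        (h,) = allelic.haplotype_reads([read], variants).values()
        assert h.assigned == "ambiguous"
        # 2 vs 1: fraction 0.67 passes
        read2 = _read("r2", {1: "A", 2: "A", 3: "G"})
        (h2,) = allelic.haplotype_reads([read2], variants).values()
        assert h2.assigned == "hap1"

    def test_read_without_snps_is_ambiguous(self):
        (h,) = allelic.haplotype_reads([_read("r1", {})], [_variant(100)]).values()
        assert h.assigned == "ambiguous"

    def test_simulated_assignments_are_accurate(self, small_experiment):
        _, fragments, variants, truth = small_experiment
        haps = allelic.haplotype_reads(fragments, variants)
        informative = [
            (rid, h) for rid, h in haps.items()
            if h.assigned != "ambiguous" and h.n_hap1_support + h.n_hap2_support >= 3
        ]
        correct = sum(truth.read_haplotypes[rid] == h.assigned for rid, h in informative)
        assert len(informative) > 1000
        assert correct / len(informative) >= 0.95

    def test_swapping_haplotypes_swaps_directions(self):
        variants = [_variant(p) for p in (100, 200)]
        swapped = [_variant(p, h1="G", h2="A") for p in (100, 200)]
        peak = Peak("chr1", 4000, 4500, name="pk")
        reads = [
            _read(f"r{i}", {100: "A", 200: "A"}, start=50, end=4400) for i in range(20)
        ]
        for vs, expected in ((variants, "maternal"), (swapped, "paternal")):
            haps = allelic.haplotype_reads(reads, vs)
            counts = allelic.peak_haplotype_counts(reads, [peak], haps)
            (res,) = allelic.call_asp(counts, [peak], min_total=10)
            assert res.direction == expected


class TestCallAsp:
    def test_one_sided_extreme_counts(self):
        peak = Peak("chr1", 0, 100, name="pk")
        (res,) = allelic.call_asp({"pk": (10, 0)}, [peak], min_total=10)
        # exact two-sided binomial: 2 * 0.5^10
        assert res.p_value == pytest.approx(2 * 0.5**10)
        assert res.direction == "maternal"

    def test_balanced_counts_not_significant(self):
        peak = Peak("chr1", 0, 100, name="pk")
        (res,) = allelic.call_asp({"pk": (7, 7)}, [peak], min_total=10)
        assert res.p_value == 1.0 and res.direction == "none"

    def test_min_total_filter_and_empty_warning(self):
        peak = Peak("chr1", 0, 100, name="pk")
        with pytest.warns(UserWarning, match="minimum haplotyped-read count"):
            assert allelic.call_asp({"pk": (3, 2)}, [peak], min_total=10) == []

    def test_direction_iff_q_below_fdr(self):
        peaks = [Peak("chr1", i * 1000, i * 1000 + 100, name=f"p{i}") for i in range(20)]
        rng = np.random.default_rng(2)
        counts = {f"p{i}": (int(rng.integers(0, 30)), int(rng.integers(0, 30))) for i in range(20)}
        counts["p0"] = (40, 0)
        results = allelic.call_asp(counts, peaks, min_total=10, fdr=0.05)
        for r in results:
            assert (r.direction != "none") == (r.q_value <= 0.05 and r.n_maternal != r.n_paternal)

    def test_flanking_snps_count_reads_for_snp_free_peak(self):
        # no het SNP inside the peak; the only SNP sits 3 kb away but
        # within the read span, so peak-supporting reads still haplotype
        peak = Peak("chr1", 5000, 5500, name="pk")
        variants = [_variant(1000)]
        reads = [
            _read(f"r{i}", {1000: "A"}, start=900, end=5200 + i) for i in range(15)
        ]
        haps = allelic.haplotype_reads(reads, variants)
        counts = allelic.peak_haplotype_counts(reads, [peak], haps)
        assert counts["pk"] == (15, 0)
        (res,) = allelic.call_asp(counts, [peak], min_total=10)
        assert res.direction == "maternal"


class TestPhaseVariants:
    def _reads_cis(self, n, a1="A", a2="C"):
        # SNP1 at 100 (A/G), SNP2 at 600 (C/T)
        return [
            Fragment("c", "chr1", 0, 1000, alleles={100: a1, 600: a2}, read_id=f"r{i}")
            for i in range(n)
        ]

    def _variants(self):
        return [
            PhasedVariant("chr1", 100, "A", "G", phased=False),
            PhasedVariant("chr1", 600, "C", "T", phased=False),
        ]

    def test_unanimous_cis_pair(self):
        reads = self._reads_cis(3) + [
            Fragment("c", "chr1", 0, 1000, alleles={100: "G", 600: "T"}, read_id="x")
        ]
        (block,) = allelic.phase_variants(reads, self._variants())
        assert block.positions == [100, 600]
        assert block.phase_bits[0] == block.phase_bits[1]  # cis

    def test_unanimous_trans_pair(self):
        reads = [
            Fragment("c", "chr1", 0, 1000, alleles={100: "A", 600: "T"}, read_id=f"r{i}")
            for i in range(4)
        ]
        (block,) = allelic.phase_variants(reads, self._variants())
        assert block.phase_bits[0] != block.phase_bits[1]

    def test_balanced_evidence_leaves_snps_unphased(self):
        reads = self._reads_cis(3)
        reads += [
            Fragment("c", "chr1", 0, 1000, alleles={100: "A", 600: "T"}, read_id=f"t{i}")
            for i in range(3)
        ]
        assert allelic.phase_variants(reads, self._variants()) == []

    def test_blocks_to_variants_round_trip(self):
        reads = self._reads_cis(5)
        blocks = allelic.phase_variants(reads, self._variants())
        phased = allelic.blocks_to_variants(blocks, self._variants())
        assert all(v.phased for v in phased)
        assert phased[0].phase_set == phased[1].phase_set


class TestSwitchError:
    def _phased(self, orientations, chrom="chr1", ps="b1"):
        out = []
        for i, o in enumerate(orientations):
            h1, h2 = ("A", "G") if o == 0 else ("G", "A")
            out.append(
                PhasedVariant(chrom, 100 * (i + 1), "A", "G", h1, h2, phase_set=ps, phased=True)
            )
        return out

    def test_identical_phasing_zero_error(self):
        truth = self._phased([0, 1, 0, 1, 0])
        assert allelic.switch_error_rate(truth, truth) == ({"chr1": 0.0}, 0.0)

    def test_one_internal_flip_breaks_two_adjacent_pairs(self):
        truth = self._phased([0, 0, 0, 0, 0])
        called = self._phased([0, 0, 1, 0, 0])
        rates, median = allelic.switch_error_rate(called, truth)
        assert rates["chr1"] == pytest.approx(2 / 4) and median == pytest.approx(0.5)

    def test_whole_block_flip_invariance(self):
        truth = self._phased([0, 1, 1, 0])
        called = self._phased([1, 0, 0, 1])
        rates, _ = allelic.switch_error_rate(called, truth)
        assert rates["chr1"] == 0.0

    def test_sparse_chromosome_skipped(self):
        truth = self._phased([0])
        rates, median = allelic.switch_error_rate(truth, truth)
        assert rates == {} and np.isnan(median)
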