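import numpy as np
import pytest

from longatac import qc
from longatac.io import fragments_to_ends
from longatac.model import Fragment, InsertionEnd, Peak


def _uniform_ends(n, lo=0, hi=100_000, chrom="chr1", seed=0):
    rng = np.random.default_rng(seed)
    return [InsertionEnd("c", chrom, int(p), "left") for p in rng.integers(lo, hi, n)]


class TestTssEnrichment:
    def test_flat_background_scores_near_one(self):
        ends = _uniform_ends(200_000)
        _, score = qc.tss_enrichment_profile(ends, [("chr1", 50_000, "+")])
        assert 0.7 < score < 1.3

    def test_all_signal_at_tss_gives_inf(self):
        ends = [InsertionEnd("c", "chr1", 50_000, "left") for _ in range(10)]
        profile, score = qc.tss_enrichment_profile(ends, [("chr1", 50_000, "+")])
        assert score == float("inf")
        assert profile.sum() == 10

    def test_no_ends_in_flanks_warns_nan(self):
        ends = [InsertionEnd("c", "chr1", 900_000, "left")]
        with pytest.warns(UserWarning, match="score undefined"):
            _, score = qc.tss_enrichment_profile(ends, [("chr1", 50_000, "+")])
        assert np.isnan(score)

    def test_profile_conserves_flank_ends(self):
        ends = _uniform_ends(50_000)
        flank = 2000
        profile, _ = qc.tss_enrichment_profile(ends, [("chr1", 50_000, "+")], flank_bp=flank)
        n_in = sum(1 for e in ends if 50_000 - flank <= e.pos < 50_000 + flank)
        assert profile.sum() == n_in

    def test_minus_strand_orientation_flips_profile(self):
        # signal only downstream of the site in genome coordinates
        ends = [InsertionEnd("c", "chr1", 50_000 + 500 + i, "left") for i in range(50)]
        prof_plus, _ = qc.tss_enrichment_profile(ends, [("chr1", 50_000, "+")])
        prof_minus, _ = qc.tss_enrichment_profile(ends, [("chr1", 50_000, "-")])
        n = len(prof_plus)
        assert prof_plus[n // 2 :].sum() == 50 and prof_plus[: n // 2].sum() == 0
        assert prof_minus[: n // 2].sum() == 50 and prof_minus[n // 2 :].sum() == 0

    def test_simulated_central_enrichment_recovered(self):
        rng = np.random.default_rng(42)
        tss = [("chr1", p, "+") for p in range(100_000, 1_000_000, 100_000)]
        # background of 2 ends per 10 bp bin per site, plus 4x extra
        # signal in the central bin -> true enrichment 5x
        ends = _uniform_ends(200_000, 0, 1_000_000, seed=1)
        for chrom, p, _ in tss:
            for _ in range(8):
                ends.append(InsertionEnd("c", chrom, p + int(rng.integers(0, 10)), "left"))
        _, score = qc.tss_enrichment_profile(ends, tss)
        assert 4.0 <= score <= 6.0


class TestFootprint:
    def test_uniform_is_flat(self):
        ends = _uniform_ends(500_000)
        prof = qc.footprint_profile(ends, [("chr1", 50_000)], flank_bp=200, bin_bp=10)
        assert prof.min() > 0.5 * prof.mean()

    def test_central_depletion_localized(self):
        rng = np.random.default_rng(3)
        sites = [("chr1", p) for p in range(10_000, 90_000, 10_000)]
        ends = []
        for _ in range(100_000):
            pos = int(rng.integers(0, 100_000))
            if any(abs(pos - s) <= 25 for _, s in sites) and rng.random() < 0.9:
                continue  # Tn5 excluded from the bound footprint
            ends.append(InsertionEnd("c", "chr1", pos, "left"))
        prof = qc.footprint_profile(ends, sites, flank_bp=200, bin_bp=10)
        center = len(prof) // 2
        assert abs(int(np.argmin(prof)) - center) <= 3
        assert prof[center] < 0.5 * np.mean([prof[0], prof[-1]])

    def test_single_end_at_single_site_is_delta(self):
        prof = qc.footprint_profile(
            [InsertionEnd("c", "chr1", 1000, "left")], [("chr1", 1000)], 200, 10
        )
        assert prof.sum() == 1 and prof[len(prof) // 2] == 1


class TestFrip:
    def test_definition(self):
        peaks = [Peak("chr1", 0, 80)]
        ends = [InsertionEnd("c", "chr1", i, "left") for i in range(200)]
        assert qc.frip(ends, peaks) == pytest.approx(80 / 200)

    def test_whole_genome_peak_gives_one(self):
        ends = _uniform_ends(1000)
        assert qc.frip(ends, [Peak("chr1", 0, 10**9)]) == 1.0

    def test_no_ends_nan(self):
        assert np.isnan(qc.frip([], [Peak("chr1", 0, 10)]))

    def test_permutation_invariance_and_union_monotonicity(self):
        ends = _uniform_ends(5000)
        a = [Peak("chr1", 0, 10_000), Peak("chr1", 40_000, 45_000)]
        b = [Peak("chr1", 70_000, 90_000)]
        assert qc.frip(ends, a) == qc.frip(ends, a[::-1])
        assert qc.frip(ends, a + b) >= qc.frip(ends, a)

    def test_simulated_frip_matches_mixture_expectation(self, small_experiment):
        cfg, fragments, _, truth = small_experiment
        ends = fragments_to_ends(fragments, shift_plus=0, shift_minus=0)
        observed = qc.frip(ends, truth.peaks)
        rho = sum(p.width for p in truth.peaks) / sum(cfg.chrom_lengths.values())
        # one end of a peak-anchored read is inside a peak; every other
        # end lands in a peak with probability ~ peak genome fraction
        expected = cfg.peak_end_weight * (1 + rho) / 2 + (1 - cfg.peak_end_weight) * rho
        assert observed == pytest.approx(expected, abs=0.02)


class TestDoublets:
    def _cell(self, cid, n_a, n_b):
        frags = []
        for i in range(n_a):
            frags.append(Fragment(cid, "chr1", i, i + 100, species="human"))
        for i in range(n_b):
            frags.append(Fragment(cid, "chr1", i, i + 100, species="mouse"))
        return frags

    def test_threshold_rule(self):
        frags = self._cell("mix", 55, 45) + self._cell("pure", 98, 2)
        out = {c.cell_id: c for c in qc.classify_doublets(frags)}
        assert out["mix"].is_doublet and not out["pure"].is_doublet
        assert out["mix"].species_fractions["human"] == pytest.approx(0.55)

    def test_species_fractions_sum_to_one(self):
        out = qc.classify_doublets(self._cell("x", 30, 70))
        assert sum(out[0].species_fractions.values()) == pytest.approx(1.0)

    def test_threshold_monotone(self):
        rng = np.random.default_rng(0)
        frags = []
        for i in range(50):
            n_a = int(rng.integers(0, 101))
            frags += self._cell(f"c{i}", n_a, 100 - n_a)
        counts = [
            sum(c.is_doublet for c in qc.classify_doublets(frags, t))
            for t in (0.05, 0.1, 0.2, 0.4)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_unlabelled_cell_excluded_with_warning(self):
        frags = [Fragment("nolabel", "chr1", 0, 100)]
        with pytest.warns(UserWarning, match="nolabel"):
            out = qc.classify_doublets(frags)
        assert out == []

    def test_planted_doublet_rate_recovered(self):
        from longatac.validation import doublet_recovery

        r = doublet_recovery(seed=1)
        # binomial 95% CI for 10/500 at p=0.02 is ~[0.008, 0.036]
        assert 0.008 <= r["called_rate"] <= 0.036
        assert r["n_correct"] == r["n_called"]
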