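"""Planted-truth recovery experiments.

Each function simulates an experiment whose ground truth is known,
runs the corresponding pipeline stage, and scores recovery. They are
the package's calibration suite: the ASP caller's power and realized
FDR, the flanking-SNP haplotyping claim, phasing switch error, SV
recall/precision under the distinct-cell support rule, integer-CNV bin
accuracy, co-accessibility null calibration and power, and the peak
caller's false-positive rate on a uniform background.

All randomness flows from the ``seed`` argument; runtimes are kept to
seconds-to-minutes by simulating genomes of a few tens of megabases.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import allelic, cnv, coaccess, peaks, qc, simulate, sv
from .io import fragments_to_ends
from .model import SVCall


def _asp_sim(seed: int, n_peaks: int = 1000, snp_free_frac: float = 0.0) -> simulate.SimConfig:
    """~50 haplotyped reads per peak across ``n_peaks`` peaks."""
    return simulate.SimConfig(
        seed=seed,
        n_cells=100,
        reads_per_cell=650,
        chrom_lengths={"chr1": 12_500_000, "chr2": 12_500_000},
        n_peaks=n_peaks,
        frac_asp=0.02,
        asp_skew=0.9,
        asp_internal_snp_free_frac=snp_free_frac,
        peak_end_weight=0.85,
        base_error=0.02,
    )


def _run_asp(cfg: simulate.SimConfig):
    fragments, variants, truth = simulate.simulate_experiment(cfg)
    haps = allelic.haplotype_reads(fragments, variants)
    counts = allelic.peak_haplotype_counts(fragments, truth.peaks, haps)
    results = allelic.call_asp(counts, truth.peaks, min_total=10, fdr=0.05)
    sig = {r.peak.name for r in results if r.direction != "none"}
    return sig, truth


def asp_recovery(seed: int, n_reps: int = 10) -> dict[str, float]:
    """Power and realized FDR of ASP calling at planted skew 0.9.

    1000 peaks per replicate, 2% allele-specific at P(maternal) 0.9 or
    0.1, ~50 haplotyped reads per peak, exact binomial test at FDR 0.05.
    """
    tp = fp = n_planted = 0
    for rep in range(n_reps):
        sig, truth = _run_asp(_asp_sim(seed + rep))
        planted = set(truth.asp_skews)
        tp += len(sig & planted)
        fp += len(sig - planted)
        n_planted += len(planted)
    power = tp / n_planted if n_planted else float("nan")
    fdr = fp / (tp + fp) if tp + fp else 0.0
    return {"power": power, "realized_fdr": fdr, "n_planted": n_planted}


def flanking_snp_asp(seed: int) -> dict[str, float]:
    """ASPs with no het SNP inside the peak, haplotyped by flanking SNPs.

    Half the planted ASPs have every internal het SNP removed; long
    reads anchored in the peak still span flanking SNPs within a read
    length, so both classes should be recovered with the same power.
    """
    cfg = _asp_sim(seed, n_peaks=500, snp_free_frac=0.5)
    cfg.frac_asp = 0.08  # 40 ASPs so both classes are well populated
    sig, truth = _run_asp(cfg)
    free = truth.asp_internal_snp_free
    with_snp = set(truth.asp_skews) - free
    return {
        "power_snp_free": len(sig & free) / len(free),
        "power_with_snp": len(sig & with_snp) / len(with_snp),
        "n_snp_free": len(free),
        "n_with_snp": len(with_snp),
    }


def phasing_switch_error(seed: int, n_chroms: int = 4) -> dict[str, float]:
    """Read-backed phasing scored by per-chromosome switch error.

    ~100 het SNPs per chromosome, 20x read coverage, 5% base error.
    Returns the median per-chromosome switch error (percent).
    """
    chrom_len = 300_000
    cfg = simulate.SimConfig(
        seed=seed,
        n_cells=10,
        reads_per_cell=int(20 * chrom_len * n_chroms / 4500 / 10),
        chrom_lengths={f"chr{i + 1}": chrom_len for i in range(n_chroms)},
        n_peaks=n_chroms,
        frac_asp=0.0,
        peak_end_weight=0.0,
        het_snp_density=100 / chrom_len,
        base_error=0.05,
    )
    fragments, variants, truth_variants = simulate.simulate_experiment(cfg)
    blocks = allelic.phase_variants(fragments, variants)
    called = allelic.blocks_to_variants(blocks, variants)
    rates, median = allelic.switch_error_rate(called, truth_variants.variants)
    return {
        "median_switch_error_pct": 100.0 * median,
        "n_chromosomes_scored": len(rates),
    }


def sv_recovery(seed: int) -> dict[str, object]:
    """Recall/precision of multi-cell SV calling on planted INS and DEL.

    50 deletions and 50 insertions, each carried by half of 100 cells,
    called at the >= 5 distinct-cell support threshold, with a
    min-cells sweep 1..10 for the monotonicity of recall.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = {"chr1": 10_000_000, "chr2": 10_000_000}
    planted = []
    lengths = rng.integers(100, 1000, size=100)
    for k in range(100):
        chrom = "chr1" if k % 2 == 0 else "chr2"
        pos = 150_000 + (k // 2) * 190_000
        sv_type = "DEL" if k < 50 else "INS"
        planted.append(
            simulate.PlantedSV(sv_type, chrom, int(pos), int(lengths[k]), 0.5)
        )
    cfg = simulate.SimConfig(
        seed=seed,
        n_cells=100,
        reads_per_cell=1600,
        chrom_lengths=chrom_lengths,
        n_peaks=100,
        frac_asp=0.0,
        peak_end_weight=0.2,
        het_snp_density=1e-5,  # SNPs are irrelevant here; keep generation lean
        planted_svs=planted,
        sv_noise_rate=0.005,
    )
    fragments, _, truth = simulate.simulate_experiment(cfg)
    evidence = sv.extract_candidates(fragments)
    clusters = sv.cluster_candidates(evidence)
    truth_calls = [
        SVCall(s.sv_type, s.chrom, s.pos, s.length, s.chrom2, s.pos2, {"t"}, 1)
        for s in truth.sv_events
    ]
    sweep = list(range(1, 11))
    bench = sv.benchmark_svs(clusters, truth_calls, min_cells_sweep=sweep)
    per_type = {t: bench[t][5] for t in bench}
    n_truth = {t: sum(1 for s in truth.sv_events if s.sv_type == t) for t in bench}
    pooled_recall = sum(per_type[t][1] * n_truth[t] for t in bench) / sum(n_truth.values())
    n_called = {
        t: sum(1 for c in clusters if c.sv_type == t and c.n_cells >= 5) for t in bench
    }
    pooled_precision = (
        sum(per_type[t][0] * n_called[t] for t in bench if n_called[t])
        / max(1, sum(n_called.values()))
    )
    recall_sweep = {
        k: sum(bench[t][k][1] * n_truth[t] for t in bench) / sum(n_truth.values())
        for k in sweep
    }
    monotone = all(
        recall_sweep[a] >= recall_sweep[b] - 1e-12
        for a, b in zip(sweep[:-1], sweep[1:])
    )
    return {
        "recall": pooled_recall,
        "precision": pooled_precision,
        "recall_sweep": recall_sweep,
        "recall_monotone_nonincreasing": monotone,
    }


def cnv_recovery(seed: int) -> dict[str, float]:
    """Per-cell integer-CN recovery of planted segments.

    A CN-3 gain on the first half of chr1 and chrX at CN 1, every cell
    a carrier, ~200 expected fragments per 500 kb bin per cell. Scores
    the fraction of (cell, bin) entries whose rounded CN is exact.
    """
    chrom_lengths = {"chr1": 5_000_000, "chr2": 5_000_000, "chrX": 3_000_000}
    bin_bp = 500_000
    n_bins = sum(-(-L // bin_bp) for L in chrom_lengths.values())
    cfg = simulate.SimConfig(
        seed=seed,
        n_cells=12,
        reads_per_cell=200 * n_bins,
        chrom_lengths=chrom_lengths,
        n_peaks=50,
        frac_asp=0.0,
        peak_end_weight=0.0,
        het_snp_density=1e-5,
        planted_cnvs=[
            simulate.PlantedCNV("chr1", 0, 2_500_000, 3, cell_fraction=1.0),
            simulate.PlantedCNV("chrX", 0, 3_000_000, 1, cell_fraction=1.0),
        ],
    )
    fragments, _, _ = simulate.simulate_experiment(cfg)
    raw, bins = cnv.bin_counts(fragments, chrom_lengths, bin_bp)
    profiles = cnv.normalize_profile(raw, bins)
    expected = np.array(
        [
            3 if (c == "chr1" and s < 2_500_000) else (1 if c == "chrX" else 2)
            for c, s, _ in bins
        ]
    )
    hits = total = 0
    for p in profiles:
        called = np.array([b[5] for b in p.bins])
        hits += int((called == expected).sum())
        total += len(expected)
    return {"bin_accuracy": hits / total, "n_cells": len(profiles), "n_bins": len(bins)}


def _coaccess_sim(seed: int, read_frac: float) -> simulate.SimConfig:
    return simulate.SimConfig(
        seed=seed,
        n_cells=50,
        reads_per_cell=600,
        chrom_lengths={"chr1": 10_000_000, "chr2": 10_000_000},
        n_peaks=150,
        frac_asp=0.0,
        peak_end_weight=0.5,
        het_snp_density=1e-5,
        coaccess_pairs=50,
        coaccess_distance_range=(2_000, 15_000),
        coaccess_read_frac=read_frac,
    )


def coaccess_calibration(seed: int, n_reps: int = 3) -> dict[str, float]:
    """Null calibration, power and distance-length concordance.

    Null: the same peak geometry with fully independent read ends — the
    q <= 0.05 discovery fraction stays low. Power: planted spanning
    molecules several-fold above the length-distribution expectation.
    Among discovered pairs, supporting-read length tracks peak distance
    (Spearman rho), since a spanning molecule must be at least as long
    as the gap it bridges.
    """
    null_disc = null_cand = 0
    tp = n_planted = 0
    rhos = []
    enrich = []
    for rep in range(n_reps):
        # independent-ends null
        frags, _, truth = simulate.simulate_experiment(_coaccess_sim(seed + rep, 0.0))
        res = coaccess.find_coaccessible(truth.peaks, frags)
        null_cand += len(res)
        null_disc += sum(r.q_value <= 0.05 for r in res)
        # planted spanning molecules
        frags, _, truth = simulate.simulate_experiment(_coaccess_sim(seed + rep, 0.02))
        res = coaccess.find_coaccessible(truth.peaks, frags)
        planted = {frozenset(p) for p in truth.coaccess_pairs}
        # pairs planted beyond 2x the local median read length are outside
        # the method's stated scope and never become candidates; power is
        # scored over the testable planted pairs
        testable = {
            frozenset((r.peak_a.name, r.peak_b.name)) for r in res
        } & planted
        disc = [r for r in res if r.q_value <= 0.05]
        disc_names = {frozenset((r.peak_a.name, r.peak_b.name)) for r in disc}
        tp += len(disc_names & testable)
        n_planted += len(testable)
        for r in res:
            if frozenset((r.peak_a.name, r.peak_b.name)) in planted and r.expected_spanning > 0:
                enrich.append(r.observed_spanning / r.expected_spanning)
        if len(disc) >= 5:
            rho = stats.spearmanr(
                [r.distance for r in disc], [r.support_length_mean for r in disc]
            ).statistic
            rhos.append(float(rho))
    return {
        "null_discovery_fraction": null_disc / null_cand if null_cand else 0.0,
        "power": tp / n_planted if n_planted else float("nan"),
        "spearman_rho": float(np.mean(rhos)) if rhos else float("nan"),
        "median_enrichment": float(np.median(enrich)) if enrich else float("nan"),
    }


def peak_null_calibration(seed: int) -> dict[str, float]:
    """False-positive windows of the Poisson caller on uniform background."""
    chrom_lengths = {"chr1": 10_000_000}
    cfg = simulate.SimConfig(
        seed=seed,
        n_cells=40,
        reads_per_cell=500,
        chrom_lengths=chrom_lengths,
        n_peaks=1,
        frac_asp=0.0,
        peak_end_weight=0.0,
        het_snp_density=1e-5,
    )
    fragments, _, _ = simulate.simulate_experiment(cfg)
    ends = fragments_to_ends(fragments)
    params = peaks.PeakCallParams()
    windows = peaks.scan_windows(ends, chrom_lengths, params)
    n_windows = sum(
        len(range(0, max(1, L - params.window_bp + 1), params.step_bp))
        for L in chrom_lengths.values()
    )
    n_fp = sum(1 for w in windows if w[4] <= params.p_threshold)
    return {
        "n_false_positive_windows": n_fp,
        "n_windows": n_windows,
        "bound": 3 * params.p_threshold * n_windows,
    }


def doublet_recovery(seed: int) -> dict[str, float]:
    """Species-mixing doublet detection at a planted 2% doublet rate."""
    cfg = simulate.SimConfig(
        seed=seed,
        n_cells=500,
        reads_per_cell=120,
        chrom_lengths={"chr1": 2_000_000},
        n_peaks=20,
        frac_asp=0.0,
        het_snp_density=1e-5,
        doublet_fraction=0.02,
        species=("human", "mouse"),
    )
    fragments, _, truth = simulate.simulate_experiment(cfg)
    flags = qc.classify_doublets(fragments, min_minor_fraction=0.1)
    called = {c.cell_id for c in flags if c.is_doublet}
    return {
        "called_rate": len(called) / cfg.n_cells,
        "planted_rate": len(truth.doublet_cells) / cfg.n_cells,
        "n_correct": len(called & truth.doublet_cells),
        "n_called": len(called),
        "n_planted": len(truth.doublet_cells),
    }
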