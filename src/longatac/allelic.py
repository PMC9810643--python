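"""Allele-specific accessibility and read-backed phasing.

Long fragments are assigned to parental haplotypes from the phased
heterozygous SNP alleles they carry — crucially, SNPs *flanking* a peak
can haplotype a read whose insertion end falls inside the peak, so
allele-specific peaks (ASPs) are testable even when the peak itself
contains no heterozygous site. ASPs are called with a two-sided exact
binomial test against a 50:50 maternal:paternal null and
Benjamini–Hochberg FDR control. Unphased het SNPs can themselves be
phased from read co-occurrence, scored by the switch error rate.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import fragment_to_ends
from .model import AspResult, Fragment, Peak, PhaseBlock, PhasedVariant, ReadHaplotype


def haplotype_reads(
    fragments: Sequence[Fragment],
    variants: Sequence[PhasedVariant],
    min_snps: int = 1,
    min_margin: int = 1,
    min_consistency: float = 2 / 3,
) -> dict[str, ReadHaplotype]:
    """Assign each read to hap1/hap2 from its observed SNP alleles.

    Per read, alleles at covered phased het SNPs are matched against the
    hap1 and hap2 alleles; the majority haplotype is assigned iff the
    read covers at least ``min_snps`` informative sites, wins by at
    least ``min_margin`` votes and the winning fraction reaches
    ``min_consistency``. Everything else (including reads covering no
    het SNP) is ambiguous. Keys are read ids.
    """
    lookup: dict[tuple[str, int], tuple[str, str]] = {}
    for v in variants:
        if v.phased:
            lookup[(v.chrom, v.pos)] = (v.hap1_allele, v.hap2_allele)
    out: dict[str, ReadHaplotype] = {}
    for i, f in enumerate(fragments):
        rid = f.read_id or f"frag{i}"
        n1 = n2 = 0
        for pos, base in f.alleles.items():
            hp = lookup.get((f.chrom, pos))
            if hp is None:
                continue
            if base == hp[0]:
                n1 += 1
            elif base == hp[1]:
                n2 += 1
        assigned = "ambiguous"
        total = n1 + n2
        if total >= min_snps and abs(n1 - n2) >= min_margin:
            if max(n1, n2) / total >= min_consistency:
                assigned = "hap1" if n1 > n2 else "hap2"
        out[rid] = ReadHaplotype(rid, n1, n2, assigned)
    return out


def peak_haplotype_counts(
    fragments: Sequence[Fragment],
    peaks: Sequence[Peak],
    haplotypes: dict[str, ReadHaplotype],
    shift_plus: int = 4,
    shift_minus: int = 5,
) -> dict[str, tuple[int, int]]:
    """Per-peak (n_hap1, n_hap2) counts of haplotyped reads.

    A read supports a peak when either of its Tn5 insertion ends falls
    inside the peak (the same end-membership convention as FRIP); a read
    with both ends in one peak counts once.
    """
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in {p.chrom for p in peaks}:
        ps = sorted(
            ((p.start, p.end, p.name) for p in peaks if p.chrom == chrom)
        )
        by_chrom[chrom] = (
            np.array([s for s, _, _ in ps], dtype=np.int64),
            np.array([e for _, e, _ in ps], dtype=np.int64),
            [n for _, _, n in ps],
        )
    counts: dict[str, list[int]] = {p.name: [0, 0] for p in peaks}
    for i, f in enumerate(fragments):
        rid = f.read_id or f"frag{i}"
        hap = haplotypes.get(rid)
        if hap is None or hap.assigned == "ambiguous":
            continue
        if f.chrom not in by_chrom:
            continue
        starts, ends, names = by_chrom[f.chrom]
        hit: set[str] = set()
        for end in fragment_to_ends(f, shift_plus, shift_minus):
            j = int(np.searchsorted(starts, end.pos, side="right")) - 1
            if j >= 0 and end.pos < ends[j]:
                hit.add(names[j])
        for name in hit:
            counts[name][0 if hap.assigned == "hap1" else 1] += 1
    return {k: (v[0], v[1]) for k, v in counts.items()}


def call_asp(
    peak_counts: dict[str, tuple[int, int]],
    peaks: Sequence[Peak],
    min_total: int = 10,
    fdr: float = 0.05,
    null_p: float = 0.5,
) -> list[AspResult]:
    """Call allele-specific peaks from per-peak haplotyped read counts.

    Each peak with ``n_maternal + n_paternal >= min_total`` gets a
    two-sided exact binomial test against ``null_p`` (default: the
    symmetric 50:50 null); q-values are Benjamini–Hochberg across all
    tested peaks jointly. ``direction`` is the majority haplotype
    (hap1 = maternal) for peaks passing the FDR, else "none".
    """
    peak_by_name = {p.name: p for p in peaks}
    tested: list[AspResult] = []
    for name, (n1, n2) in peak_counts.items():
        if n1 + n2 < min_total or name not in peak_by_name:
            continue
        p = float(stats.binomtest(n1, n1 + n2, null_p).pvalue)
        tested.append(AspResult(peak_by_name[name], n1, n2, p))
    if not tested:
        warnings.warn("no peak reaches the minimum haplotyped-read count", stacklevel=2)
        return []
    _, qvals, _, _ = multipletests([r.p_value for r in tested], method="fdr_bh")
    for r, q in zip(tested, qvals):
        r.q_value = float(q)
        if q <= fdr and r.n_maternal != r.n_paternal:
            r.direction = "maternal" if r.n_maternal > r.n_paternal else "paternal"
    return tested


# ---------------------------------------------------------------------------
# read-backed phasing


def phase_variants(
    fragments: Sequence[Fragment],
    variants: Sequence[PhasedVariant],
) -> list[PhaseBlock]:
    """Phase het SNPs from co-occurrence of their alleles on single reads.

    SNP pairs co-covered by a read gain an edge weighted
    ``(#cis reads) − (#trans reads)``, where cis means both observed
    alleles are ref or both alt. Each connected component (zero-weight
    edges dropped) is phased by propagating orientations along its
    maximum-|weight| spanning tree; the sign of each tree edge decides
    the relative phase. Singleton SNPs stay unphased; deterministic.
    """
    ref = {(v.chrom, v.pos): v.ref_allele for v in variants}
    alt = {(v.chrom, v.pos): v.alt_allele for v in variants}
    weights: dict[tuple, int] = {}
    for f in fragments:
        seen = []
        for pos in sorted(f.alleles):
            key = (f.chrom, pos)
            if key not in ref:
                continue
            base = f.alleles[pos]
            if base == ref[key]:
                seen.append((key, 0))
            elif base == alt[key]:
                seen.append((key, 1))
        for (k1, a1), (k2, a2) in zip(seen[:-1], seen[1:]):
            e = (k1, k2)
            weights[e] = weights.get(e, 0) + (1 if a1 == a2 else -1)
    g = nx.Graph()
    for (k1, k2), w in weights.items():
        if w != 0:
            g.add_edge(k1, k2, weight=abs(w), sign=1 if w > 0 else -1)
    blocks: list[PhaseBlock] = []
    bid = 0
    for comp in sorted(nx.connected_components(g), key=lambda c: min(c)):
        sub = g.subgraph(comp)
        tree = nx.maximum_spanning_tree(sub, weight="weight")
        root = min(comp)
        phase = {root: 0}
        for parent, child in nx.bfs_edges(tree, root):
            sign = tree[parent][child]["sign"]
            phase[child] = phase[parent] if sign > 0 else 1 - phase[parent]
        ordered = sorted(comp)
        chrom = ordered[0][0]
        blocks.append(
            PhaseBlock(
                chrom=chrom,
                positions=[pos for _, pos in ordered],
                phase_bits=[phase[k] for k in ordered],
                block_id=f"PB{bid:04d}",
            )
        )
        bid += 1
    return blocks


def blocks_to_variants(
    blocks: Sequence[PhaseBlock], variants: Sequence[PhasedVariant]
) -> list[PhasedVariant]:
    """Stamp phase-block orientations back onto variant records.

    phase bit 0 puts the reference allele on hap1. Variants outside any
    block are returned unphased.
    """
    bit: dict[tuple[str, int], tuple[int, str]] = {}
    for b in blocks:
        for pos, ph in zip(b.positions, b.phase_bits):
            bit[(b.chrom, pos)] = (ph, b.block_id)
    out = []
    for v in variants:
        entry = bit.get((v.chrom, v.pos))
        if entry is None:
            out.append(
                PhasedVariant(v.chrom, v.pos, v.ref_allele, v.alt_allele, phased=False)
            )
        else:
            ph, block_id = entry
            out.append(
                PhasedVariant(
                    v.chrom, v.pos, v.ref_allele, v.alt_allele,
                    hap1_allele=v.ref_allele if ph == 0 else v.alt_allele,
                    hap2_allele=v.alt_allele if ph == 0 else v.ref_allele,
                    phase_set=block_id, phased=True,
                )
            )
    return out


def _orientation(v: PhasedVariant) -> int:
    """0 when hap1 carries the reference allele."""
    return 0 if v.hap1_allele == v.ref_allele else 1


def switch_error_rate(
    called: Sequence[PhasedVariant],
    truth: Sequence[PhasedVariant],
) -> tuple[dict[str, float], float]:
    """Switch error of a called phasing against truth, per chromosome.

    Over consecutive pairs of SNPs phased in both sets (ordered by
    position, within one called phase set), the fraction whose relative
    phase disagrees between call and truth. Invariant to flipping a
    whole block. Chromosomes with fewer than 2 shared phased SNPs are
    skipped. Returns (per-chromosome rates, median rate).
    """
    truth_or = {
        (v.chrom, v.pos): _orientation(v) for v in truth if v.phased
    }
    shared: dict[str, list[tuple[int, int, int, Optional[str]]]] = {}
    for v in called:
        if not v.phased:
            continue
        key = (v.chrom, v.pos)
        if key in truth_or:
            shared.setdefault(v.chrom, []).append(
                (v.pos, _orientation(v), truth_or[key], v.phase_set)
            )
    rates: dict[str, float] = {}
    for chrom, rows in shared.items():
        rows.sort()
        n_pairs = n_switch = 0
        for (p1, c1, t1, ps1), (p2, c2, t2, ps2) in zip(rows[:-1], rows[1:]):
            if ps1 != ps2:  # relative phase undefined across blocks
                continue
            n_pairs += 1
            if (c1 ^ c2) != (t1 ^ t2):
                n_switch += 1
        if n_pairs >= 1:
            rates[chrom] = n_switch / n_pairs
    median = float(np.median(list(rates.values()))) if rates else float("nan")
    return rates, median
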