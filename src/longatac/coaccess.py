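"""Single-molecule co-accessibility of neighboring peak pairs.

Two peaks on one chromosome are co-accessible when single long
fragments repeatedly place one Tn5 end in each peak — both sites open
on the same allele of the same cell at the same time. Candidate pairs
are limited to center distances within twice the *local* median read
length (farther pairs cannot be bridged by single molecules anyway);
the number of spanning molecules is then tested against the expectation
under the genome-wide fragment-length distribution with a Poisson upper
tail, and q-values are Benjamini–Hochberg across all candidate pairs.
"""

from __future__ import annotations

import sys
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CoaccessPair, Fragment, Peak


class EmpiricalLengthCDF:
    """Empirical CDF of fragment lengths, F(x) = P(length <= x)."""

    def __init__(self, lengths: Sequence[int]) -> None:
        if len(lengths) == 0:
            raise ValueError("need at least one fragment length")
        self._sorted = np.sort(np.asarray(lengths, dtype=np.int64))

    def __call__(self, x) -> np.ndarray:
        return np.searchsorted(self._sorted, x, side="right") / len(self._sorted)

    @property
    def median(self) -> float:
        return float(np.median(self._sorted))


def local_median_read_length(
    fragments: Sequence[Fragment],
    chrom: str,
    locus: int,
    window_bp: int = 100_000,
    min_fragments: int = 20,
) -> float:
    """Median length of fragments whose midpoint lies within the window.

    Falls back to the global median when fewer than ``min_fragments``
    fragments are local — co-accessibility must stay testable in
    sparse regions.
    """
    lo, hi = locus - window_bp // 2, locus + window_bp // 2
    local = [f.length for f in fragments if f.chrom == chrom and lo <= f.midpoint < hi]
    if len(local) >= min_fragments:
        return float(np.median(local))
    return float(np.median([f.length for f in fragments]))


def candidate_pairs(
    peaks: Sequence[Peak],
    fragments: Sequence[Fragment],
    window_bp: int = 100_000,
) -> list[tuple[Peak, Peak, int, float]]:
    """Same-chromosome peak pairs within 2x the local median read length.

    Returns ``(peak_a, peak_b, center distance, local median)`` with
    peak_a left of peak_b; overlapping or identical peaks (d = 0) are
    excluded since a single molecule trivially covers them.
    """
    out = []
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    # precompute per-chromosome midpoint/length arrays for local medians
    frag_mid: dict[str, np.ndarray] = {}
    frag_len: dict[str, np.ndarray] = {}
    for chrom in by_chrom:
        rows = [(f.midpoint, f.length) for f in fragments if f.chrom == chrom]
        rows.sort()
        frag_mid[chrom] = np.array([m for m, _ in rows], dtype=np.int64)
        frag_len[chrom] = np.array([l for _, l in rows], dtype=np.int64)
    global_median = float(np.median([f.length for f in fragments]))
    for chrom, plist in by_chrom.items():
        plist = sorted(plist, key=lambda p: p.start)
        mids, lens = frag_mid[chrom], frag_len[chrom]
        for i, pa in enumerate(plist):
            for pb in plist[i + 1 :]:
                d = pb.center - pa.center
                if d <= 0 or pa.end > pb.start:
                    continue
                locus = (pa.center + pb.center) // 2
                lo = np.searchsorted(mids, locus - window_bp // 2)
                hi = np.searchsorted(mids, locus + window_bp // 2)
                if hi - lo >= 20:
                    med = float(np.median(lens[lo:hi]))
                else:
                    med = global_median
                if d > 2 * med:
                    # peaks are distance-sorted: no later pb qualifies
                    # only if the local median were constant; keep scanning
                    # within a hard cap of 4x the global median
                    if d > 4 * global_median:
                        break
                    continue
                out.append((pa, pb, d, med))
    return out


def test_pair(
    pair: tuple[Peak, Peak, int, float],
    fragments: Sequence[Fragment],
    length_cdf: EmpiricalLengthCDF,
    pad_bp: int = 0,
) -> CoaccessPair:
    """Poisson spanning-molecule test for one candidate peak pair.

    Observed: fragments whose left end falls in peak A (± pad) and
    right end in peak B (± pad). Expected: for each A-anchored
    fragment, the background probability that a fragment of random
    length starting at that end reaches into B, summed via the
    empirical length CDF: λ = Σ_left∈A [F(B.end − e_left) −
    F(B.start − e_left)]. p = P(X ≥ observed; λ). A λ of zero with
    spanning molecules observed gets the smallest positive p.
    """
    pa, pb, d, med = pair
    obs = 0
    lam = 0.0
    lengths = []
    a_lo, a_hi = pa.start - pad_bp, pa.end + pad_bp
    b_lo, b_hi = pb.start - pad_bp, pb.end + pad_bp
    for f in fragments:
        if f.chrom != pa.chrom:
            continue
        e_left, e_right = f.start, f.end - 1
        if a_lo <= e_left < a_hi:
            lam += float(length_cdf(b_hi - e_left) - length_cdf(b_lo - e_left))
            if b_lo <= e_right < b_hi:
                obs += 1
                lengths.append(f.length)
    if lam == 0.0:
        p = sys.float_info.min if obs > 0 else 1.0
    else:
        p = float(stats.poisson.sf(obs - 1, lam)) if obs > 0 else 1.0
    return CoaccessPair(
        peak_a=pa, peak_b=pb, distance=d,
        observed_spanning=obs, expected_spanning=lam, p_value=p,
        support_length_mean=float(np.mean(lengths)) if lengths else float("nan"),
    )


def find_coaccessible(
    peaks: Sequence[Peak],
    fragments: Sequence[Fragment],
    fdr: float = 0.05,
    pad_bp: int = 0,
    window_bp: int = 100_000,
    length_cdf: Optional[EmpiricalLengthCDF] = None,
) -> list[CoaccessPair]:
    """Test all candidate pairs and BH-correct across them.

    Returns every candidate pair with p and q values; callers filter by
    ``q <= fdr`` for the discovery set. Fragments are pre-indexed per
    chromosome so the pair scan stays linear in local fragment count.
    """
    if length_cdf is None:
        length_cdf = EmpiricalLengthCDF([f.length for f in fragments])
    cands = candidate_pairs(peaks, fragments, window_bp=window_bp)
    if not cands:
        return []
    by_chrom: dict[str, list[Fragment]] = {}
    for f in fragments:
        by_chrom.setdefault(f.chrom, []).append(f)
    # sort by left end for windowed slicing
    starts: dict[str, np.ndarray] = {}
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda f: f.start)
        starts[chrom] = np.array([f.start for f in by_chrom[chrom]], dtype=np.int64)
    results = []
    for pair in cands:
        pa, pb = pair[0], pair[1]
        frags = by_chrom.get(pa.chrom, [])
        arr = starts.get(pa.chrom)
        lo = int(np.searchsorted(arr, pa.start - pad_bp)) if arr is not None else 0
        hi = int(np.searchsorted(arr, pa.end + pad_bp)) if arr is not None else 0
        results.append(test_pair(pair, frags[lo:hi], length_cdf, pad_bp=pad_bp))
    _, qvals, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    return results
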