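"""Peak calling from Tn5 insertion-end density, plus peak-set comparison,
benchmarking against reference elements, category annotation, and per-cell
count matrices.

The caller scores sliding windows by a Poisson upper tail against the
larger of the genome-wide and a local background rate (a MACS-style
local-lambda model), then merges significant windows into peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse, stats

from .model import Fragment, InsertionEnd, Peak


@dataclass
class PeakCallParams:
    """Tunable parameters of the sliding-window Poisson caller."""

    window_bp: int = 500
    step_bp: int = 100
    local_bg_bp: int = 10_000
    min_ends: int = 5
    p_threshold: float = 1e-5
    merge_gap_bp: int = 100

    def validate(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")
        if self.local_bg_bp <= self.window_bp:
            raise ValueError("local_bg_bp must exceed window_bp")


def _ends_by_chrom(ends: Iterable[InsertionEnd]) -> dict[str, np.ndarray]:
    acc: dict[str, list[int]] = {}
    for e in ends:
        acc.setdefault(e.chrom, []).append(e.pos)
    return {c: np.sort(np.array(v, dtype=np.int64)) for c, v in acc.items()}


def scan_windows(
    ends: Sequence[InsertionEnd],
    chrom_lengths: dict[str, int],
    params: Optional[PeakCallParams] = None,
) -> list[tuple[str, int, int, int, float]]:
    """Score every sliding window; return (chrom, start, end, count, p).

    λ for a window is ``max(genome rate, local rate) × window_bp`` where
    the local rate is measured over ``local_bg_bp`` centered on the
    window, and p is the Poisson upper tail P(X ≥ count).
    """
    params = params or PeakCallParams()
    params.validate()
    pos = _ends_by_chrom(ends)
    genome_bp = sum(chrom_lengths.values())
    n_total = sum(len(v) for v in pos.values())
    if genome_bp <= 0:
        raise ValueError("chrom_lengths must be positive")
    global_rate = n_total / genome_bp
    out = []
    for chrom, L in chrom_lengths.items():
        arr = pos.get(chrom)
        if arr is None or len(arr) == 0:
            continue
        w, step, bg = params.window_bp, params.step_bp, params.local_bg_bp
        starts = np.arange(0, max(1, L - w + 1), step, dtype=np.int64)
        k = np.searchsorted(arr, starts + w) - np.searchsorted(arr, starts)
        cand = np.nonzero(k >= params.min_ends)[0]
        for i in cand:
            s = int(starts[i])
            center = s + w // 2
            lo = max(0, center - bg // 2)
            hi = min(L, center + bg // 2)
            local_n = int(np.searchsorted(arr, hi) - np.searchsorted(arr, lo))
            local_rate = local_n / (hi - lo)
            lam = max(global_rate, local_rate) * w
            p = float(stats.poisson.sf(int(k[i]) - 1, lam))
            out.append((chrom, s, s + w, int(k[i]), p))
    return out


def call_peaks(
    ends: Sequence[InsertionEnd],
    chrom_lengths: dict[str, int],
    params: Optional[PeakCallParams] = None,
) -> list[Peak]:
    """Call peaks: significant windows merged within ``merge_gap_bp``.

    A window is significant when it holds at least ``min_ends`` ends and
    its Poisson tail p-value is at most ``p_threshold``. Merged peaks
    carry the best window's −log10 p as score. Deterministic; returns
    disjoint, coordinate-sorted peaks.
    """
    params = params or PeakCallParams()
    windows = scan_windows(ends, chrom_lengths, params)
    sig = [wdw for wdw in windows if wdw[4] <= params.p_threshold]
    sig.sort(key=lambda t: (t[0], t[1]))
    peaks: list[Peak] = []
    n = 0
    for chrom, s, e, _, p in sig:
        score = float(-np.log10(max(p, 1e-300)))
        if peaks and peaks[-1].chrom == chrom and s - peaks[-1].end <= params.merge_gap_bp:
            peaks[-1].end = max(peaks[-1].end, e)
            peaks[-1].score = max(peaks[-1].score, score)
        else:
            peaks.append(Peak(chrom, s, e, score=score, name=f"peak{n:05d}"))
            n += 1
    return peaks


# ---------------------------------------------------------------------------
# peak-set comparison


def _overlap_flags(a: Sequence[Peak], b: Sequence[Peak], min_bp: int) -> np.ndarray:
    """For each peak of ``a``, whether it intersects any peak of ``b`` by >= min_bp."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in b}:
        iv = sorted((p.start, p.end) for p in b if p.chrom == chrom)
        by_chrom[chrom] = (
            np.array([s for s, _ in iv], dtype=np.int64),
            np.array([e for _, e in iv], dtype=np.int64),
        )
    flags = np.zeros(len(a), dtype=bool)
    for i, p in enumerate(a):
        if p.chrom not in by_chrom:
            continue
        bs, be = by_chrom[p.chrom]
        lo = int(np.searchsorted(be, p.start + min_bp, side="left"))
        hi = int(np.searchsorted(bs, p.end - min_bp, side="right"))
        for j in range(lo, hi):
            if min(p.end, be[j]) - max(p.start, bs[j]) >= min_bp:
                flags[i] = True
                break
    return flags


def peak_overlap(
    a: Sequence[Peak], b: Sequence[Peak], min_bp: int = 1
) -> tuple[int, float, int, float]:
    """Reciprocal overlap counts between two merged peak sets.

    Returns ``(n_overlap_a, frac_a, n_overlap_b, frac_b)``: how many
    peaks of each set intersect the other by at least ``min_bp``, and
    those counts as fractions of each set's size. The two directions are
    asymmetric because peak widths differ between assays.
    """
    fa = _overlap_flags(a, b, min_bp)
    fb = _overlap_flags(b, a, min_bp)
    na, nb = int(fa.sum()), int(fb.sum())
    return (
        na,
        na / len(a) if a else 0.0,
        nb,
        nb / len(b) if b else 0.0,
    )


def benchmark_peaks(
    called: Sequence[Peak], reference: Sequence[Peak], min_bp: int = 1
) -> tuple[float, float]:
    """Precision/recall of a called peak set against reference elements.

    Precision: fraction of called peaks touching ≥1 reference element;
    recall: fraction of reference elements touched by ≥1 called peak.
    """
    if not reference:
        raise ValueError("reference element set is empty")
    if not called:
        return 0.0, 0.0
    precision = float(_overlap_flags(called, reference, min_bp).mean())
    recall = float(_overlap_flags(reference, called, min_bp).mean())
    return precision, recall


def annotate_peaks(
    called: Sequence[Peak],
    categorized: dict[str, Sequence[Peak]],
    priority: Optional[Sequence[str]] = None,
) -> tuple[dict[str, int], dict[str, float]]:
    """Assign each peak its first overlapping category by priority.

    ``categorized`` maps category name to intervals; ``priority``
    defaults to the regulatory-element convention
    PLS > pELS > dELS > CTCF-only > DNase-H3K4me3, then any remaining
    categories in dict order; unmatched peaks count as "unannotated".
    Returns (counts, fractions); fractions sum to 1 over called peaks.
    """
    default = ["PLS", "pELS", "dELS", "CTCF-only", "DNase-H3K4me3"]
    if priority is None:
        priority = [c for c in default if c in categorized] + [
            c for c in categorized if c not in default
        ]
    counts = {c: 0 for c in priority}
    counts["unannotated"] = 0
    flag_sets = {c: _overlap_flags(called, categorized[c], 1) for c in priority}
    for i in range(len(called)):
        for c in priority:
            if flag_sets[c][i]:
                counts[c] += 1
                break
        else:
            counts["unannotated"] += 1
    total = max(1, len(called))
    fractions = {c: n / total for c, n in counts.items()}
    return counts, fractions


# ---------------------------------------------------------------------------
# count matrices


def peak_cell_matrix(
    ends: Sequence[InsertionEnd], peaks: Sequence[Peak]
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Sparse cells × peaks matrix of insertion-end counts.

    Returns (matrix, cell ids, peak names); column sums over all cells
    equal the per-peak FRIP numerators by construction.
    """
    cells = sorted({e.cell_id for e in ends})
    cell_idx = {c: i for i, c in enumerate(cells)}
    order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].start))
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        ids = [i for i in order if peaks[i].chrom == chrom]
        by_chrom[chrom] = (
            np.array([peaks[i].start for i in ids], dtype=np.int64),
            np.array([peaks[i].end for i in ids], dtype=np.int64),
            np.array(ids, dtype=np.int64),
        )
    rows, cols = [], []
    for e in ends:
        if e.chrom not in by_chrom:
            continue
        ps, pe, ids = by_chrom[e.chrom]
        j = int(np.searchsorted(ps, e.pos, side="right")) - 1
        if j >= 0 and e.pos < pe[j]:
            rows.append(cell_idx[e.cell_id])
            cols.append(int(ids[j]))
    mat = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(cells), len(peaks))
    ).tocsr()
    return mat, cells, [p.name for p in peaks]


def gene_score(
    ends: Sequence[InsertionEnd],
    genes: Sequence[tuple[str, str, int, int, str]],
    upstream_bp: int = 2000,
) -> tuple[sparse.csr_matrix, list[str], list[str]]:
    """Cells × genes insertion-end counts over gene body + upstream window.

    ``genes`` rows are ``(name, chrom, start, end, strand)``; the
    upstream extension follows the strand. A simple accessibility score
    proxy for marker-gene activity.
    """
    regions = []
    for name, chrom, start, end, strand in genes:
        if strand == "-":
            regions.append(Peak(chrom, start, end + upstream_bp, name=name))
        else:
            regions.append(Peak(chrom, max(0, start - upstream_bp), end, name=name))
    # genes may overlap; count each end in every gene region it hits
    cells = sorted({e.cell_id for e in ends})
    cell_idx = {c: i for i, c in enumerate(cells)}
    rows, cols = [], []
    for j, r in enumerate(regions):
        for i, e in enumerate(ends):
            if e.chrom == r.chrom and r.start <= e.pos < r.end:
                rows.append(cell_idx[e.cell_id])
                cols.append(j)
    mat = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(cells), len(regions))
    ).tocsr()
    return mat, cells, [r.name for r in regions]
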