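"""Quality control for long-read scATAC data.

Per-cell and aggregate metrics: TSS enrichment of Tn5 insertion ends,
fraction of read ends in peaks (FRIP), fragment counts, footprint
profiles around bound sites and species-mixing doublet classification.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import CellQc, Fragment, InsertionEnd, Peak


def _end_positions(ends: Sequence[InsertionEnd], chrom: Optional[str] = None) -> np.ndarray:
    if chrom is None:
        return np.array([e.pos for e in ends], dtype=np.int64)
    return np.array([e.pos for e in ends if e.chrom == chrom], dtype=np.int64)


def _profile(
    offsets: np.ndarray, flank_bp: int, bin_bp: int
) -> np.ndarray:
    """Histogram signed offsets in [-flank, flank) into fixed-width bins."""
    n_bins = 2 * flank_bp // bin_bp
    keep = (offsets >= -flank_bp) & (offsets < flank_bp)
    idx = (offsets[keep] + flank_bp) // bin_bp
    return np.bincount(idx.astype(np.int64), minlength=n_bins).astype(float)


def tss_enrichment_profile(
    ends: Sequence[InsertionEnd],
    tss_sites: Sequence[tuple[str, int, str]],
    flank_bp: int = 2000,
    bin_bp: int = 10,
) -> tuple[np.ndarray, float]:
    """Aggregate insertion-end profile around TSS and a scalar enrichment score.

    ``tss_sites`` are ``(chrom, pos, strand)``; minus-strand sites are
    flipped so the profile is transcription-oriented. The score is the
    center-bin count divided by the mean of the outermost 10% of bins on
    each side (ENCODE-style background normalization): ~1 for a flat
    library, NaN with a warning when no ends fall in the flanks, +inf
    when all signal is central and the outer flanks are empty.
    """
    if not tss_sites:
        raise ValueError("need at least one TSS")
    if flank_bp % bin_bp:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    profile = np.zeros(n_bins)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in {c for c, _, _ in tss_sites}:
        by_chrom[chrom] = np.sort(_end_positions(ends, chrom))
    for chrom, pos, strand in tss_sites:
        arr = by_chrom[chrom]
        lo = np.searchsorted(arr, pos - flank_bp)
        hi = np.searchsorted(arr, pos + flank_bp)
        offs = arr[lo:hi] - pos
        if strand == "-":
            offs = -offs - 1
        profile += _profile(offs, flank_bp, bin_bp)
    if profile.sum() == 0:
        warnings.warn("no insertion ends within TSS flanks; score undefined", stacklevel=2)
        return profile, float("nan")
    n_outer = max(1, n_bins // 2 // 10)
    outer = np.concatenate([profile[:n_outer], profile[-n_outer:]])
    center = profile[n_bins // 2]
    if outer.mean() == 0:
        return profile, float("inf")
    return profile, float(center / outer.mean())


def footprint_profile(
    ends: Sequence[InsertionEnd],
    site_centers: Sequence[tuple[str, int]],
    flank_bp: int = 200,
    bin_bp: int = 5,
) -> np.ndarray:
    """Unstranded aggregate end profile around bound-site centers.

    A protein bound at the centers excludes Tn5 locally, so an occupied
    factor shows as a central dip against the accessible flanks.
    """
    if not site_centers:
        raise ValueError("need at least one site")
    if flank_bp % bin_bp:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    profile = np.zeros(2 * flank_bp // bin_bp)
    by_chrom = {c: np.sort(_end_positions(ends, c)) for c in {c for c, _ in site_centers}}
    for chrom, pos in site_centers:
        arr = by_chrom[chrom]
        lo = np.searchsorted(arr, pos - flank_bp)
        hi = np.searchsorted(arr, pos + flank_bp)
        profile += _profile(arr[lo:hi] - pos, flank_bp, bin_bp)
    return profile


def frip(ends: Sequence[InsertionEnd], peaks: Sequence[Peak]) -> float:
    """Fraction of insertion ends falling inside any peak.

    Assumes a merged (non-overlapping) peak set; returns NaN for an
    empty end set.
    """
    if not ends:
        return float("nan")
    n_in = 0
    starts: dict[str, np.ndarray] = {}
    ends_arr: dict[str, np.ndarray] = {}
    for chrom in {p.chrom for p in peaks}:
        ps = sorted((p.start, p.end) for p in peaks if p.chrom == chrom)
        starts[chrom] = np.array([s for s, _ in ps], dtype=np.int64)
        ends_arr[chrom] = np.array([e for _, e in ps], dtype=np.int64)
    for e in ends:
        if e.chrom not in starts:
            continue
        i = np.searchsorted(starts[e.chrom], e.pos, side="right") - 1
        if i >= 0 and e.pos < ends_arr[e.chrom][i]:
            n_in += 1
    return n_in / len(ends)


def classify_doublets(
    fragments: Iterable[Fragment],
    min_minor_fraction: float = 0.1,
) -> list[CellQc]:
    """Flag species-mixing doublets from per-fragment genome labels.

    A cell is a doublet when its minor-species read fraction exceeds
    ``min_minor_fraction``. Cells with zero fragments are excluded with
    a warning; fragments without a species label are ignored.
    """
    counts: dict[str, dict[str, int]] = {}
    totals: dict[str, int] = {}
    for f in fragments:
        totals[f.cell_id] = totals.get(f.cell_id, 0) + 1
        if f.species is not None:
            counts.setdefault(f.cell_id, {}).setdefault(f.species, 0)
            counts[f.cell_id][f.species] += 1
    out = []
    for cid, total in sorted(totals.items()):
        sp = counts.get(cid, {})
        labelled = sum(sp.values())
        if labelled == 0:
            warnings.warn(f"cell {cid} has no species-labelled fragments; skipped", stacklevel=2)
            continue
        fracs = {k: v / labelled for k, v in sp.items()}
        minor = 1.0 - max(fracs.values())
        out.append(
            CellQc(
                cell_id=cid,
                n_fragments=total,
                species_fractions=fracs,
                is_doublet=minor > min_minor_fraction,
            )
        )
    return out


def cell_qc(
    fragments: Sequence[Fragment],
    ends: Sequence[InsertionEnd],
    peaks: Sequence[Peak],
    tss_sites: Sequence[tuple[str, int, str]],
    flank_bp: int = 2000,
    bin_bp: int = 10,
) -> list[CellQc]:
    """Per-cell fragment count, FRIP and TSS enrichment."""
    by_cell_frag: dict[str, int] = {}
    for f in fragments:
        by_cell_frag[f.cell_id] = by_cell_frag.get(f.cell_id, 0) + 1
    by_cell_ends: dict[str, list[InsertionEnd]] = {}
    for e in ends:
        by_cell_ends.setdefault(e.cell_id, []).append(e)
    out = []
    for cid in sorted(by_cell_frag):
        cell_ends = by_cell_ends.get(cid, [])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, score = tss_enrichment_profile(cell_ends, tss_sites, flank_bp, bin_bp) if cell_ends else (None, float("nan"))
        out.append(
            CellQc(
                cell_id=cid,
                n_fragments=by_cell_frag[cid],
                frip=frip(cell_ends, peaks),
                tss_enrichment=score,
            )
        )
    return out
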