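"""Per-cell copy-number profiles from binned fragment depth.

Fragments are assigned to genome-tiling bins by midpoint, depth is
normalized per cell (library size) and per bin (median across cells, or
an external reference), and rescaled so the autosomal median equals the
assumed ploidy before rounding to integer copy number. Large-scale
events only — no segmentation, no GC/mappability correction (a
user-supplied per-bin covariate can be folded into the reference).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .model import CnvProfile, Fragment


def genome_bins(
    chrom_lengths: dict[str, int], bin_bp: int = 1_000_000
) -> list[tuple[str, int, int]]:
    """Genome-tiling bins; the last bin of each chromosome is truncated."""
    bins = []
    for chrom, L in chrom_lengths.items():
        for s in range(0, L, bin_bp):
            bins.append((chrom, s, min(s + bin_bp, L)))
    return bins


def bin_counts(
    fragments: Sequence[Fragment],
    chrom_lengths: dict[str, int],
    bin_bp: int = 1_000_000,
) -> tuple[dict[str, np.ndarray], list[tuple[str, int, int]]]:
    """Raw per-cell bin counts; each fragment goes to its midpoint's bin.

    Midpoint assignment counts every fragment exactly once, however many
    bin boundaries a long fragment spans. Returns (counts per cell id,
    bin list).
    """
    bins = genome_bins(chrom_lengths, bin_bp)
    offsets: dict[str, int] = {}
    off = 0
    for chrom, L in chrom_lengths.items():
        offsets[chrom] = off
        off += -(-L // bin_bp)
    counts: dict[str, np.ndarray] = {}
    n_bins = len(bins)
    for f in fragments:
        if f.chrom not in offsets:
            continue
        b = offsets[f.chrom] + f.midpoint // bin_bp
        if f.cell_id not in counts:
            counts[f.cell_id] = np.zeros(n_bins, dtype=np.int64)
        counts[f.cell_id][b] += 1
    return counts, bins


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def normalize_profile(
    raw: dict[str, np.ndarray],
    bins: Sequence[tuple[str, int, int]],
    ploidy: int = 2,
    bin_reference: str | np.ndarray = "uniform",
    autosomes: Optional[Sequence[str]] = None,
) -> list[CnvProfile]:
    """Normalize raw bin counts into per-cell copy-number profiles.

    depth = raw / cell total / reference; each cell is then rescaled so
    its autosomal median depth equals ``ploidy`` and rounded (half away
    from zero) to integer CN. The reference per bin is one of

    * ``"uniform"`` (default): the bin's width fraction of the genome —
      absolute copy number, including events shared by every cell;
    * ``"median"``: per-bin median of library-size-normalized counts
      across cells (needs >= 10 cells) — cancels shared coverage biases
      but therefore only resolves CNVs *relative* to the cell majority
      (subclones);
    * an explicit per-bin array (e.g. from a diploid control sample).

    Bins with zero reference are masked (NaN depth, CN -1).
    """
    cells = sorted(raw)
    mat = np.array([raw[c] for c in cells], dtype=float)
    cell_tot = mat.sum(axis=1, keepdims=True)
    cell_tot[cell_tot == 0] = 1.0
    rel = mat / cell_tot
    if isinstance(bin_reference, str):
        if bin_reference == "uniform":
            widths = np.array([e - s for _, s, e in bins], dtype=float)
            bin_reference = widths / widths.sum()
        elif bin_reference == "median":
            if len(cells) < 10:
                raise ValueError("need >=10 cells for a median reference")
            bin_reference = np.median(rel, axis=0)
        else:
            raise ValueError(f"unknown reference mode {bin_reference!r}")
    ref = np.asarray(bin_reference, dtype=float)
    masked = ref <= 0
    chroms = np.array([b[0] for b in bins])
    if autosomes is None:
        auto = ~np.isin(chroms, ["chrX", "chrY", "X", "Y"])
    else:
        auto = np.isin(chroms, list(autosomes))
    auto_ok = auto & ~masked
    profiles = []
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = rel / ref
    depth[:, masked] = np.nan
    for i, cid in enumerate(cells):
        d = depth[i]
        med = np.nanmedian(d[auto_ok]) if auto_ok.any() else np.nanmedian(d)
        scaled = d * (ploidy / med) if med and med > 0 else d
        cn = np.full(len(bins), -1, dtype=int)
        ok = ~np.isnan(scaled)
        cn[ok] = _round_half_away(scaled[ok]).astype(int)
        cn[ok] = np.maximum(cn[ok], 0)
        profiles.append(
            CnvProfile(
                cell_id=cid,
                bins=[
                    (b[0], b[1], b[2], int(raw[cid][j]),
                     float(scaled[j]) if ok[j] else float("nan"), int(cn[j]))
                    for j, b in enumerate(bins)
                ],
            )
        )
    return profiles


def aggregate_profiles(
    profiles: Sequence[CnvProfile],
    groups: dict[str, Sequence[str]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group mean normalized depth and consensus integer CN.

    ``groups`` maps group name to cell ids (a partition of the cells);
    empty groups are skipped. Consensus is the rounded group mean depth;
    masked bins stay NaN / -1.
    """
    by_cell = {p.cell_id: p for p in profiles}
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, cells in groups.items():
        members = [by_cell[c] for c in cells if c in by_cell]
        if not members:
            continue
        depth = np.array([[b[4] for b in p.bins] for p in members], dtype=float)
        mean = np.nanmean(depth, axis=0) if len(members) else depth
        consensus = np.full(mean.shape, -1, dtype=int)
        ok = ~np.isnan(mean)
        consensus[ok] = _round_half_away(mean[ok]).astype(int)
        out[name] = (mean, consensus)
    return out
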