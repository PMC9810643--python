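"""Synthetic long-read single-cell ATAC experiments with planted truth.

The generator emulates the data properties the pipeline consumes:

* long fragments with a log-normal length distribution (median in the
  4-5 kb range, matching plate-based nanopore scATAC libraries);
* Tn5 insertion-end enrichment at planted accessible peaks;
* a diploid genome with phased heterozygous SNPs, read alleles drawn
  from the read's haplotype with a configurable base-error rate;
* allele-specific peaks (ASPs) whose supporting reads are skewed toward
  one haplotype, optionally with every het SNP *inside* the peak removed
  so that only flanking SNPs can haplotype the reads;
* structural variants (insertions, deletions, translocations) planted
  in a fraction of cells, expressed as CIGAR events / split anchors on
  spanning reads;
* integer copy-number segments that scale per-cell sampling intensity;
* single molecules spanning planted co-accessible peak pairs;
* cross-species doublet cells in species-mixing designs.

Everything planted is recorded in a :class:`SimTruth` ledger keyed by
peak name, read id and cell id, so downstream modules can be scored
against ground truth. Output is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import Fragment, Peak, PhasedVariant

_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class PlantedSV:
    """A structural variant planted in a fraction of cells."""

    sv_type: str  # INS | DEL | TRA
    chrom: str
    pos: int
    length: int = 0
    cell_fraction: float = 1.0
    chrom2: Optional[str] = None
    pos2: Optional[int] = None


@dataclass(frozen=True)
class PlantedCNV:
    """An integer copy-number segment carried by a subset of cells."""

    chrom: str
    start: int
    end: int
    copy_number: int
    cell_fraction: float = 1.0
    cell_ids: Optional[tuple[str, ...]] = None


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment.

    Defaults describe a small but realistic plate-based long-read
    scATAC run: a few hundred cells, ~4.5 kb median fragments, about
    half of all insertion ends falling in accessible peaks, and one het
    SNP per ~1.5 kb (human-like heterozygosity).
    """

    n_cells: int = 100
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_peaks: int = 200
    peak_width_bp: int = 500
    frac_asp: float = 0.02
    asp_skew: float = 0.9  # P(maternal) for maternal-skewed ASPs
    asp_internal_snp_free_frac: float = 0.0
    fragment_median_bp: float = 4500.0
    fragment_sigma: float = 0.35
    min_fragment_bp: int = 200
    reads_per_cell: int = 500
    peak_end_weight: float = 0.5  # fraction of reads anchored in a peak
    het_snp_density: float = 1 / 1500
    base_error: float = 0.02
    ploidy: int = 2
    planted_svs: list[PlantedSV] = field(default_factory=list)
    planted_cnvs: list[PlantedCNV] = field(default_factory=list)
    sv_noise_rate: float = 0.0
    coaccess_pairs: int = 0
    coaccess_distance_range: tuple[int, int] = (2_000, 15_000)
    coaccess_read_frac: float = 0.0
    doublet_fraction: float = 0.0
    species: tuple[str, ...] = ("human",)
    species_contam: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for frac in (
            self.frac_asp, self.asp_skew, self.peak_end_weight, self.base_error,
            self.doublet_fraction, self.coaccess_read_frac, self.species_contam,
            self.asp_internal_snp_free_frac,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.fragment_median_bp <= 0:
            raise ValueError("fragment_median_bp must be positive")
        for chrom, L in self.chrom_lengths.items():
            if self.peak_width_bp > L:
                raise ValueError(f"peak width exceeds length of {chrom}")


@dataclass
class SimTruth:
    """Complete planted ground truth of one simulated experiment."""

    peaks: list[Peak]
    asp_skews: dict[str, float]  # peak name -> P(hap1) for planted ASPs
    asp_internal_snp_free: set[str]
    variants: list[PhasedVariant]
    sv_events: list[PlantedSV]
    sv_carriers: dict[int, set[str]]  # index into sv_events -> carrier cells
    cnv_segments: list[PlantedCNV]
    cnv_carriers: dict[int, set[str]]
    coaccess_pairs: list[tuple[str, str]]  # (peak_a name, peak_b name)
    doublet_cells: set[str]
    cell_species: dict[str, tuple[str, ...]]
    read_haplotypes: dict[str, str]  # read id -> hap1 | hap2

    @property
    def asp_peaks(self) -> list[Peak]:
        return [p for p in self.peaks if p.name in self.asp_skews]


class _WeightedPositions:
    """Piecewise-uniform sampler over a genome with per-segment weights."""

    def __init__(
        self,
        chrom_lengths: dict[str, int],
        overrides: Sequence[tuple[str, int, int, float]] = (),
    ) -> None:
        self.chroms = list(chrom_lengths)
        segs: list[tuple[int, int, int, float]] = []  # (chrom_idx, start, end, w)
        for ci, (chrom, L) in enumerate(chrom_lengths.items()):
            cuts = {0, L}
            for c, s, e, _ in overrides:
                if c == chrom:
                    cuts.add(max(0, min(s, L)))
                    cuts.add(max(0, min(e, L)))
            bounds = sorted(cuts)
            for s, e in zip(bounds[:-1], bounds[1:]):
                w = 1.0
                for c, os, oe, ow in overrides:
                    if c == chrom and os <= s and e <= oe:
                        w = ow
                segs.append((ci, s, e, w))
        self._chrom = np.array([c for c, _, _, _ in segs], dtype=np.int64)
        self._start = np.array([s for _, s, _, _ in segs], dtype=np.int64)
        self._span = np.array([e - s for _, s, e, _ in segs], dtype=np.int64)
        self._mass = np.array([(e - s) * w for _, s, e, w in segs], dtype=float)
        self._cum = np.cumsum(self._mass)
        self.total = float(self._cum[-1])

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (chrom_index, position) arrays for ``n`` draws."""
        u = rng.random(n) * self.total
        idx = np.minimum(np.searchsorted(self._cum, u, side="right"), len(self._cum) - 1)
        lo = self._cum[idx] - self._mass[idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(self._mass[idx] > 0, (u - lo) / self._mass[idx], 0.0)
        pos = self._start[idx] + (frac * self._span[idx]).astype(np.int64)
        return self._chrom[idx], pos


def _place_peaks(cfg: SimConfig, rng: np.random.Generator) -> tuple[list[Peak], list[tuple[int, int]]]:
    """Evenly spaced jittered peaks plus planted co-accessible partners.

    Returns the peak list and index pairs (a, b) of planted co-accessible
    pairs. Even spacing guarantees non-overlap and leaves room for a
    partner peak within the co-accessibility distance range.
    """
    chroms = list(cfg.chrom_lengths)
    total = sum(cfg.chrom_lengths.values())
    peaks: list[Peak] = []
    per_chrom = {
        c: max(1, round(cfg.n_peaks * L / total)) for c, L in cfg.chrom_lengths.items()
    }
    w = cfg.peak_width_bp
    for chrom in chroms:
        L = cfg.chrom_lengths[chrom]
        n_c = per_chrom[chrom]
        spacing = L / n_c
        jitter_amp = max(0.0, spacing / 8 - w)
        for i in range(n_c):
            center = (i + 0.5) * spacing + rng.uniform(-jitter_amp, jitter_amp)
            start = int(np.clip(center - w / 2, 0, L - w))
            peaks.append(Peak(chrom, start, start + w, name=f"peak{len(peaks):05d}"))
    pair_idx: list[tuple[int, int]] = []
    if cfg.coaccess_pairs:
        lo, hi = cfg.coaccess_distance_range
        anchors = rng.choice(len(peaks), size=cfg.coaccess_pairs, replace=False)
        for a in sorted(int(x) for x in anchors):
            pa = peaks[a]
            d = int(rng.integers(lo, hi + 1))
            L = cfg.chrom_lengths[pa.chrom]
            start = pa.center + d - w // 2
            if start + w > L:
                start = pa.center - d - w // 2
            start = int(np.clip(start, 0, L - w))
            peaks.append(Peak(pa.chrom, start, start + w, name=f"peak{len(peaks):05d}"))
            pair_idx.append((a, len(peaks) - 1))
    return peaks, pair_idx


def _plant_variants(cfg: SimConfig, rng: np.random.Generator) -> list[PhasedVariant]:
    variants: list[PhasedVariant] = []
    for chrom, L in cfg.chrom_lengths.items():
        n = rng.poisson(cfg.het_snp_density * L)
        pos = np.sort(rng.choice(L, size=min(n, L), replace=False))
        ref_i = rng.integers(0, 4, size=len(pos))
        alt_i = (ref_i + rng.integers(1, 4, size=len(pos))) % 4
        hap1_is_ref = rng.random(len(pos)) < 0.5
        for p, ri, ai, h1r in zip(pos, ref_i, alt_i, hap1_is_ref):
            ref, alt = _BASES[ri], _BASES[ai]
            variants.append(
                PhasedVariant(
                    chrom=chrom, pos=int(p), ref_allele=ref, alt_allele=alt,
                    hap1_allele=ref if h1r else alt,
                    hap2_allele=alt if h1r else ref,
                    phase_set=chrom, phased=True,
                )
            )
    return variants


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[list[Fragment], list[PhasedVariant], SimTruth]:
    """Generate fragments, het SNPs and the planted-truth ledger.

    Per cell, each read is either a co-accessibility molecule (both ends
    in the two peaks of a planted pair), a peak-anchored read (one end
    uniform inside a copy-number-weighted random peak) or background
    (uniform over the copy-number-weighted genome). Read haplotypes are
    Bernoulli(0.5) except in ASPs, where peak-anchored reads follow the
    planted skew; every read reports the haplotype's allele at each
    covered het SNP, miscalled with probability ``base_error``.
    """
    cfg.validate()
    rng0 = np.random.default_rng(cfg.seed)
    chroms = list(cfg.chrom_lengths)
    chrom_len = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=np.int64)

    peaks, pair_idx = _place_peaks(cfg, rng0)
    variants = _plant_variants(cfg, rng0)

    # ASP assignment (pair members excluded so the two analyses stay orthogonal)
    paired = {i for ab in pair_idx for i in ab}
    eligible = [i for i in range(len(peaks)) if i not in paired]
    n_asp = round(cfg.frac_asp * len(peaks))
    asp_indices = sorted(int(i) for i in rng0.choice(eligible, size=min(n_asp, len(eligible)), replace=False))
    asp_skews: dict[str, float] = {}
    peak_skew = np.full(len(peaks), 0.5)
    for i in asp_indices:
        skew = cfg.asp_skew if rng0.random() < 0.5 else 1.0 - cfg.asp_skew
        asp_skews[peaks[i].name] = skew
        peak_skew[i] = skew

    # optionally strip het SNPs from inside a fraction of ASPs
    snp_free: set[str] = set()
    if cfg.asp_internal_snp_free_frac > 0 and asp_indices:
        k = round(cfg.asp_internal_snp_free_frac * len(asp_indices))
        chosen = sorted(int(i) for i in rng0.choice(asp_indices, size=k, replace=False))
        drop_zones = [(peaks[i].chrom, peaks[i].start, peaks[i].end) for i in chosen]
        snp_free = {peaks[i].name for i in chosen}
        variants = [
            v for v in variants
            if not any(c == v.chrom and s <= v.pos < e for c, s, e in drop_zones)
        ]

    # per-chromosome SNP lookup arrays
    snp_pos = {c: np.array([v.pos for v in variants if v.chrom == c], dtype=np.int64) for c in chroms}
    snp_h1 = {c: np.array([v.hap1_allele for v in variants if v.chrom == c]) for c in chroms}
    snp_h2 = {c: np.array([v.hap2_allele for v in variants if v.chrom == c]) for c in chroms}

    # cells, species, doublets
    cell_ids = [f"cell{i:04d}" for i in range(cfg.n_cells)]
    n_doublet = round(cfg.doublet_fraction * cfg.n_cells)
    doublet_set = set(
        cell_ids[int(i)] for i in rng0.choice(cfg.n_cells, size=n_doublet, replace=False)
    )
    cell_species: dict[str, tuple[str, ...]] = {}
    for i, cid in enumerate(cell_ids):
        base = cfg.species[i % len(cfg.species)]
        if cid in doublet_set and len(cfg.species) > 1:
            other = cfg.species[(i + 1) % len(cfg.species)]
            cell_species[cid] = (base, other)
        else:
            cell_species[cid] = (base,)

    # SV / CNV carriers
    sv_carriers: dict[int, set[str]] = {}
    for k, sv in enumerate(cfg.planted_svs):
        n_car = round(sv.cell_fraction * cfg.n_cells)
        sv_carriers[k] = set(
            cell_ids[int(i)] for i in rng0.choice(cfg.n_cells, size=n_car, replace=False)
        )
    cnv_carriers: dict[int, set[str]] = {}
    for k, cnv in enumerate(cfg.planted_cnvs):
        if cnv.cell_ids is not None:
            cnv_carriers[k] = set(cnv.cell_ids)
        else:
            n_car = round(cnv.cell_fraction * cfg.n_cells)
            cnv_carriers[k] = set(
                cell_ids[int(i)]
                for i in rng0.choice(cfg.n_cells, size=n_car, replace=False)
            )

    # cache position samplers / peak weights per CNV genotype class
    peak_chrom_idx = np.array([chroms.index(p.chrom) for p in peaks])
    peak_centers = np.array([p.center for p in peaks], dtype=np.int64)
    samplers: dict[tuple[int, ...], tuple[_WeightedPositions, np.ndarray]] = {}

    def _class_sampler(carried: tuple[int, ...]):
        if carried not in samplers:
            overrides = [
                (cfg.planted_cnvs[k].chrom, cfg.planted_cnvs[k].start,
                 cfg.planted_cnvs[k].end, cfg.planted_cnvs[k].copy_number / cfg.ploidy)
                for k in carried
            ]
            ws = _WeightedPositions(cfg.chrom_lengths, overrides)
            pw = np.ones(len(peaks))
            for c, s, e, w in overrides:
                ci = chroms.index(c)
                in_seg = (peak_chrom_idx == ci) & (peak_centers >= s) & (peak_centers < e)
                pw[in_seg] = w
            samplers[carried] = (ws, pw / pw.sum())
        return samplers[carried]

    # planted SVs indexed per chromosome for fast spanning checks
    svs_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    for k, sv in enumerate(cfg.planted_svs):
        svs_by_chrom[sv.chrom].append(k)

    pair_arr = np.array(pair_idx, dtype=np.int64) if pair_idx else None
    margin = 200  # bp a read must extend past a breakpoint to report it

    fragments: list[Fragment] = []
    read_haplotypes: dict[str, str] = {}

    for ci_cell, cid in enumerate(cell_ids):
        rng = np.random.default_rng([cfg.seed, ci_cell])
        carried = tuple(k for k, cells in cnv_carriers.items() if cid in cells)
        sampler, peak_w = _class_sampler(carried)
        n = cfg.reads_per_cell

        u = rng.random(n)
        p_ca = cfg.coaccess_read_frac if pair_arr is not None else 0.0
        p_pk = (1.0 - p_ca) * cfg.peak_end_weight
        cat = np.where(u < p_ca, 0, np.where(u < p_ca + p_pk, 1, 2))

        lengths = np.maximum(
            cfg.min_fragment_bp,
            np.round(cfg.fragment_median_bp * np.exp(cfg.fragment_sigma * rng.standard_normal(n))),
        ).astype(np.int64)
        chrom_i = np.zeros(n, dtype=np.int64)
        starts = np.zeros(n, dtype=np.int64)
        p_h1 = np.full(n, 0.5)

        bg = cat == 2
        if bg.any():
            chrom_i[bg], starts[bg] = sampler.sample(rng, int(bg.sum()))

        pk = cat == 1
        if pk.any():
            m = int(pk.sum())
            pidx = rng.choice(len(peaks), size=m, p=peak_w)
            offset = rng.integers(0, cfg.peak_width_bp, size=m)
            anchor = np.array([peaks[i].start for i in pidx]) + offset
            side = rng.integers(0, 2, size=m)  # 0: anchor is left end
            s = np.where(side == 0, anchor, anchor - (lengths[pk] - 1))
            chrom_i[pk] = peak_chrom_idx[pidx]
            starts[pk] = s
            p_h1[pk] = peak_skew[pidx]

        ca = cat == 0
        if ca.any():
            m = int(ca.sum())
            which = rng.integers(0, len(pair_arr), size=m)
            ea = np.empty(m, dtype=np.int64)
            eb = np.empty(m, dtype=np.int64)
            for j, wi in enumerate(which):
                a, b = pair_arr[wi]
                ea[j] = rng.integers(peaks[a].start, peaks[a].end)
                eb[j] = rng.integers(peaks[b].start, peaks[b].end)
            left = np.minimum(ea, eb)
            right = np.maximum(ea, eb)
            chrom_i[ca] = peak_chrom_idx[pair_arr[which, 0]]
            starts[ca] = left
            lengths[ca] = right - left + 1

        # clip to chromosome bounds
        L_arr = chrom_len[chrom_i]
        lengths = np.minimum(lengths, L_arr - 1)
        starts = np.clip(starts, 0, L_arr - lengths)
        ends = starts + lengths

        hap1 = rng.random(n) < p_h1

        # species labels (only meaningful for mixing designs)
        sp_list = cell_species[cid]
        if len(sp_list) == 2:
            pick = rng.random(n) < 0.5
            sp = np.where(pick, sp_list[0], sp_list[1])
        else:
            sp = np.full(n, sp_list[0], dtype=object)
        if cfg.species_contam > 0 and len(cfg.species) > 1:
            flip = rng.random(n) < cfg.species_contam
            others = [s for s in cfg.species if s != sp_list[0]]
            if flip.any() and others:
                repl = rng.choice(others, size=int(flip.sum()))
                sp = np.asarray(sp, dtype=object)
                sp[flip] = repl

        noise = rng.random(n) < cfg.sv_noise_rate

        for i in range(n):
            chrom = chroms[chrom_i[i]]
            s, e = int(starts[i]), int(ends[i])
            rid = f"{cid}:r{i}"
            hap = "hap1" if hap1[i] else "hap2"
            read_haplotypes[rid] = hap

            cigar: list[tuple[str, int]] = []
            supp: list[tuple[str, int, str]] = []
            for k in svs_by_chrom[chrom]:
                if cid not in sv_carriers[k]:
                    continue
                sv = cfg.planted_svs[k]
                if sv.sv_type == "DEL":
                    if s + margin <= sv.pos and sv.pos + sv.length + margin <= e:
                        cigar = [("M", sv.pos - s), ("D", sv.length), ("M", e - sv.pos - sv.length)]
                        break
                elif sv.sv_type == "INS":
                    if s + margin <= sv.pos <= e - margin:
                        cigar = [("M", sv.pos - s), ("I", sv.length), ("M", e - sv.pos)]
                        break
                elif sv.sv_type == "TRA":
                    # the primary alignment truncates at the junction; the
                    # remainder maps to the partner locus as a split anchor
                    if s + margin <= sv.pos <= e - margin:
                        e = sv.pos
                        supp = [(sv.chrom2 or chrom, int(sv.pos2 or 0), "+")]
                        break
            if noise[i] and not cigar and not supp:
                op = "I" if rng.random() < 0.5 else "D"
                ln = int(rng.integers(50, 501))
                bp = int(rng.integers(s + margin, max(s + margin + 1, e - margin)))
                if op == "D" and bp + ln + margin < e:
                    cigar = [("M", bp - s), ("D", ln), ("M", e - bp - ln)]
                elif op == "I":
                    cigar = [("M", bp - s), ("I", ln), ("M", e - bp)]

            pos_arr = snp_pos[chrom]
            a = int(np.searchsorted(pos_arr, s))
            b = int(np.searchsorted(pos_arr, e))
            alleles: dict[int, str] = {}
            if b > a:
                true_bases = (snp_h1 if hap1[i] else snp_h2)[chrom][a:b]
                err = rng.random(b - a) < cfg.base_error
                for j, (p, base) in enumerate(zip(pos_arr[a:b], true_bases)):
                    if err[j]:
                        other = snp_h2[chrom][a + j] if hap1[i] else snp_h1[chrom][a + j]
                        alleles[int(p)] = str(other)
                    else:
                        alleles[int(p)] = str(base)

            fragments.append(
                Fragment(
                    cell_id=cid, chrom=chrom, start=s, end=e, mapq=60,
                    cigar_events=cigar, supplementary=supp, alleles=alleles,
                    species=str(sp[i]) if len(cfg.species) > 1 else None,
                    read_id=rid,
                )
            )

    truth = SimTruth(
        peaks=peaks,
        asp_skews=asp_skews,
        asp_internal_snp_free=snp_free,
        variants=variants,
        sv_events=list(cfg.planted_svs),
        sv_carriers=sv_carriers,
        cnv_segments=list(cfg.planted_cnvs),
        cnv_carriers=cnv_carriers,
        coaccess_pairs=[(peaks[a].name, peaks[b].name) for a, b in pair_idx],
        doublet_cells=doublet_set,
        cell_species=cell_species,
        read_haplotypes=read_haplotypes,
    )
    return fragments, variants, truth


def downsample_pseudobulk(
    fragments: Sequence[Fragment],
    per_cell_reads: int,
    n_cells: Optional[int] = None,
    seed: int = 0,
) -> list[Fragment]:
    """Partition a pseudo-bulk read pool into synthetic cells.

    Samples without replacement: each of ``n_cells`` synthetic cells
    receives exactly ``per_cell_reads`` fragments, relabelled
    ``pseudo0000``.... With the default ``n_cells`` the pool is carved
    into as many full cells as it supports.
    """
    pool = len(fragments)
    if n_cells is None:
        n_cells = pool // per_cell_reads
    need = per_cell_reads * n_cells
    if need > pool or n_cells == 0:
        raise ValueError(
            f"pool of {pool} reads cannot supply {n_cells} cells x {per_cell_reads} reads"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(pool)[:need]
    out: list[Fragment] = []
    for ci in range(n_cells):
        cid = f"pseudo{ci:04d}"
        for k in order[ci * per_cell_reads : (ci + 1) * per_cell_reads]:
            f = fragments[k]
            out.append(
                Fragment(
                    cell_id=cid, chrom=f.chrom, start=f.start, end=f.end,
                    mapq=f.mapq, cigar_events=list(f.cigar_events),
                    supplementary=list(f.supplementary), alleles=dict(f.alleles),
                    species=f.species, read_id=f.read_id,
                )
            )
    return out
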