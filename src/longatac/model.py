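"""Core domain types for long-read single-cell ATAC analysis.

All genomic coordinates are 0-based half-open throughout the package;
conversions to 1-based formats (VCF) happen only at format boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

CIGAR_OPS = frozenset("MIDSH")


@dataclass(slots=True)
class Fragment:
    """One aligned long-read fragment of one cell.

    The atomic evidence unit of the pipeline: its two ends are Tn5
    insertion sites (accessibility), its sequence carries SNP alleles
    (haplotype), its CIGAR and split alignments carry SV evidence and
    its genomic position contributes to copy-number depth.

    Parameters
    ----------
    cell_id : str
        Opaque cell identity (barcode or well).
    chrom, start, end : str, int, int
        0-based half-open reference interval; ``start < end``.
    mapq : int
        Mapping quality, 0-60.
    cigar_events : list of (str, int)
        Ordered CIGAR operations ``(op, length)`` with op in M/I/D/S/H.
        Empty list means "fully matched" (simulated or table input).
    supplementary : list of (str, int, str)
        Split-alignment anchors ``(chrom, pos, strand)`` attached to this
        primary alignment; evidence for translocations.
    alleles : dict mapping int -> str
        Observed base at covered heterozygous SNP positions (0-based).
    species : str or None
        Genome-of-alignment label for species-mixing designs.
    read_id : str or None
        Unique read identifier (join key against simulation truth).
    """

    cell_id: str
    chrom: str
    start: int
    end: int
    mapq: int = 60
    cigar_events: list[tuple[str, int]] = field(default_factory=list)
    supplementary: list[tuple[str, int, str]] = field(default_factory=list)
    alleles: dict[int, str] = field(default_factory=dict)
    species: Optional[str] = None
    read_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("Fragment.chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"Fragment requires start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(slots=True)
class InsertionEnd:
    """A single Tn5 insertion site; each fragment yields exactly two."""

    cell_id: str
    chrom: str
    pos: int
    side: str  # "left" | "right"


@dataclass(slots=True, order=True)
class Peak:
    """Accessible-chromatin interval with a score (-log10 p or arbitrary)."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"Peak requires start < end, got [{self.start}, {self.end})")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(slots=True)
class PhasedVariant:
    """Heterozygous SNP, optionally phased into hap1/hap2 alleles.

    When ``phased`` is true, ``{hap1_allele, hap2_allele}`` equals
    ``{ref_allele, alt_allele}``. Positions are 0-based internally
    (shifted by one relative to VCF).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    hap1_allele: Optional[str] = None
    hap2_allele: Optional[str] = None
    phase_set: Optional[str] = None
    phased: bool = False

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.phased:
            if {self.hap1_allele, self.hap2_allele} != {self.ref_allele, self.alt_allele}:
                raise ValueError(
                    "phased variant requires {hap1, hap2} == {ref, alt} "
                    f"at {self.chrom}:{self.pos}"
                )


@dataclass(slots=True)
class SVCall:
    """Clustered structural-variant event with its distinct supporting cells."""

    sv_type: str  # INS | DEL | TRA
    chrom: str
    pos: int
    length: int
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    supporting_cells: set[str] = field(default_factory=set)
    supporting_reads: int = 0

    def __post_init__(self) -> None:
        if self.sv_type not in ("INS", "DEL", "TRA"):
            raise ValueError(f"unknown SV type {self.sv_type!r}")

    @property
    def n_cells(self) -> int:
        return len(self.supporting_cells)


@dataclass(slots=True)
class AspResult:
    """Allele-specific test result for one peak.

    ``n_maternal``/``n_paternal`` are haplotyped read counts whose
    insertion end falls in the peak; direction is the majority haplotype
    when the BH-adjusted q-value passes the FDR, else "none".
    """

    peak: Peak
    n_maternal: int
    n_paternal: int
    p_value: float
    q_value: float = float("nan")
    direction: str = "none"  # maternal | paternal | none


@dataclass(slots=True)
class CoaccessPair:
    """Single-molecule co-accessibility evidence for a neighboring peak pair."""

    peak_a: Peak
    peak_b: Peak
    distance: int
    observed_spanning: int
    expected_spanning: float
    p_value: float
    q_value: float = float("nan")
    support_length_mean: float = float("nan")


@dataclass(slots=True)
class CnvProfile:
    """Per-cell copy-number profile over genome-tiling bins.

    ``bins`` is an ordered list of
    ``(chrom, start, end, raw_count, normalized_depth, integer_cn)``.
    Masked bins (zero reference) carry NaN depth and -1 integer CN.
    """

    cell_id: str
    bins: list[tuple[str, int, int, int, float, int]]


@dataclass(slots=True)
class CellQc:
    """Per-cell quality metrics."""

    cell_id: str
    n_fragments: int
    frip: float = float("nan")
    tss_enrichment: float = float("nan")
    species_fractions: dict[str, float] = field(default_factory=dict)
    is_doublet: bool = False


@dataclass(slots=True)
class ReadHaplotype:
    """Haplotype assignment of one read from its phased-SNP alleles."""

    read_id: str
    n_hap1_support: int
    n_hap2_support: int
    assigned: str  # hap1 | hap2 | ambiguous


@dataclass(slots=True)
class PhaseBlock:
    """A set of het SNPs phased relative to one another by overlapping reads.

    ``phase_bits[i] = 0`` means hap1 carries the reference allele at
    ``positions[i]`` under the block's (arbitrary) global orientation.
    """

    chrom: str
    positions: list[int]
    phase_bits: list[int]
    block_id: str = "."

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.phase_bits):
            raise ValueError("positions and phase_bits length mismatch")
        if len(self.positions) < 2:
            raise ValueError("a phase block needs at least 2 SNPs")
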