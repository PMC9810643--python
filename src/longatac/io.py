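"""Readers and writers for the standard formats the pipeline touches.

Supported inputs: coordinate-sorted SAM/BAM with a cell-identity tag,
a plain-text fragment table (TSV), BED3/BED5 intervals and VCF 4.x
heterozygous SNVs. Outputs: fragment table, BED, phased VCF and a
tab-separated SV call table.

Internal coordinates are 0-based half-open everywhere; VCF positions are
shifted by one on read and write.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .model import Fragment, InsertionEnd, Peak, PhasedVariant, SVCall

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

#: fragment-table columns beyond the 5 mandatory ones
_OPTIONAL_COLUMNS = ("read_id", "cigar", "supp", "alleles", "species")


class FormatError(ValueError):
    """Raised on a malformed record, with the offending line number."""


# ---------------------------------------------------------------------------
# fragments


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string into ``(op, length)`` events (M/I/D/S/H kept)."""
    if not cigar or cigar == "*" or cigar == ".":
        return []
    events = []
    for length, op in _CIGAR_RE.findall(cigar):
        if op in "=X":
            op = "M"
        if op in "MIDSH":
            events.append((op, int(length)))
    return events


def format_cigar(events: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in events) if events else "."


def _parse_supp(s: str) -> list[tuple[str, int, str]]:
    if not s or s == ".":
        return []
    anchors = []
    for token in s.split(";"):
        chrom, pos, strand = token.rsplit(":", 2)
        anchors.append((chrom, int(pos), strand))
    return anchors


def _format_supp(anchors: list[tuple[str, int, str]]) -> str:
    return ";".join(f"{c}:{p}:{s}" for c, p, s in anchors) if anchors else "."


def _parse_alleles(s: str) -> dict[int, str]:
    if not s or s == ".":
        return {}
    out = {}
    for token in s.split(";"):
        pos, base = token.split(":")
        out[int(pos)] = base
    return out


def _format_alleles(alleles: dict[int, str]) -> str:
    if not alleles:
        return "."
    return ";".join(f"{p}:{b}" for p, b in sorted(alleles.items()))


def read_fragment_table(path: str | Path, min_mapq: int = 30) -> Iterator[Fragment]:
    """Yield fragments from a 5+-column TSV.

    Columns: chrom, start, end, cell_id, mapq, then optionally read_id,
    cigar, supp, alleles, species ("." for missing). Records below
    ``min_mapq`` or with start >= end are skipped (the latter with a
    warning).
    """
    n_bad = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 columns, got {len(fields)}")
            try:
                chrom, start, end, cell_id, mapq = (
                    fields[0], int(fields[1]), int(fields[2]), fields[3], int(fields[4]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                n_bad += 1
                continue
            if mapq < min_mapq:
                continue
            opt = dict(zip(_OPTIONAL_COLUMNS, fields[5:]))
            yield Fragment(
                cell_id=cell_id,
                chrom=chrom,
                start=start,
                end=end,
                mapq=mapq,
                cigar_events=parse_cigar(opt.get("cigar", ".")),
                supplementary=_parse_supp(opt.get("supp", ".")),
                alleles=_parse_alleles(opt.get("alleles", ".")),
                species=None if opt.get("species", ".") in (".", "") else opt["species"],
                read_id=None if opt.get("read_id", ".") in (".", "") else opt["read_id"],
            )
    if n_bad:
        warnings.warn(f"{path}: skipped {n_bad} records with start >= end", stacklevel=2)


def write_fragment_table(fragments: Iterable[Fragment], path: str | Path) -> None:
    """Write fragments as the 10-column TSV dialect of this package."""
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(
                "\t".join(
                    (
                        f.chrom,
                        str(f.start),
                        str(f.end),
                        f.cell_id,
                        str(f.mapq),
                        f.read_id or ".",
                        format_cigar(f.cigar_events),
                        _format_supp(f.supplementary),
                        _format_alleles(f.alleles),
                        f.species or ".",
                    )
                )
                + "\n"
            )


def read_alignments(
    path: str | Path,
    min_mapq: int = 30,
    cell_tag: str = "CB",
) -> Iterator[Fragment]:
    """Yield fragments from a SAM/BAM file with a cell-identity tag.

    Secondary alignments are dropped; supplementary alignments are
    attached to their primary (matched by query name) as split anchors.
    Cell identity is read from ``cell_tag`` (falling back to the read
    group when absent).
    """
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    primaries: dict[str, Fragment] = {}
    pending: dict[str, list[tuple[str, int, str]]] = {}
    n_bad = 0
    with pysam.AlignmentFile(str(path), mode) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary:
                continue
            if rec.is_supplementary:
                strand = "-" if rec.is_reverse else "+"
                anchor = (rec.reference_name, rec.reference_start, strand)
                if rec.query_name in primaries:
                    primaries[rec.query_name].supplementary.append(anchor)
                else:
                    pending.setdefault(rec.query_name, []).append(anchor)
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.reference_start >= rec.reference_end:
                n_bad += 1
                continue
            if rec.has_tag(cell_tag):
                cell = str(rec.get_tag(cell_tag))
            elif rec.has_tag("RG"):
                cell = str(rec.get_tag("RG"))
            else:
                cell = "unknown"
            events = []
            for op_code, length in rec.cigartuples or []:
                op = "MIDNSHP=X"[op_code]
                if op in "=X":
                    op = "M"
                if op in "MIDSH":
                    events.append((op, length))
            frag = Fragment(
                cell_id=cell,
                chrom=rec.reference_name,
                start=rec.reference_start,
                end=rec.reference_end,
                mapq=rec.mapping_quality,
                cigar_events=events,
                read_id=rec.query_name,
            )
            frag.supplementary.extend(pending.pop(rec.query_name, []))
            primaries[rec.query_name] = frag
    if n_bad:
        warnings.warn(f"{path}: skipped {n_bad} zero-length alignments", stacklevel=2)
    yield from primaries.values()


def read_fragments(
    path: str | Path, min_mapq: int = 30, cell_tag: str = "CB"
) -> Iterator[Fragment]:
    """Read fragments from a SAM/BAM (.sam/.bam suffix) or a fragment table."""
    p = str(path)
    if p.endswith((".sam", ".bam")):
        return read_alignments(path, min_mapq=min_mapq, cell_tag=cell_tag)
    return read_fragment_table(path, min_mapq=min_mapq)


def fragment_to_ends(
    f: Fragment,
    shift_plus: int = 4,
    shift_minus: int = 5,
    chrom_length: Optional[int] = None,
) -> tuple[InsertionEnd, InsertionEnd]:
    """Derive the two Tn5 insertion sites of a fragment.

    The left end sits at ``start + shift_plus`` and the right end at
    ``end - 1 - shift_minus`` (the standard ATAC +4/-5 offset by
    default), both clipped to the chromosome and ordered left <= right.
    """
    left = f.start + shift_plus
    right = f.end - 1 - shift_minus
    hi = (chrom_length - 1) if chrom_length else max(f.end - 1, left, right)
    left = min(max(left, 0), hi)
    right = min(max(right, 0), hi)
    if left > right:
        left = right = min(max((f.start + f.end) // 2, 0), hi)
    return (
        InsertionEnd(f.cell_id, f.chrom, left, "left"),
        InsertionEnd(f.cell_id, f.chrom, right, "right"),
    )


def fragments_to_ends(
    fragments: Iterable[Fragment], shift_plus: int = 4, shift_minus: int = 5
) -> list[InsertionEnd]:
    """All insertion ends of a fragment collection (2 per fragment)."""
    out: list[InsertionEnd] = []
    for f in fragments:
        out.extend(fragment_to_ends(f, shift_plus, shift_minus))
    return out


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Peak]:
    """Read BED3/BED5 intervals (0-based half-open) as peaks."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                peaks.append(
                    Peak(
                        chrom=fields[0],
                        start=int(fields[1]),
                        end=int(fields[2]),
                        name=fields[3] if len(fields) > 3 else ".",
                        score=float(fields[4]) if len(fields) > 4 else 0.0,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path, bed3: bool = False) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            if bed3:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
            else:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\n")


# ---------------------------------------------------------------------------
# VCF (SNVs only)


def read_vcf_hets(path: str | Path) -> list[PhasedVariant]:
    """Read heterozygous SNVs from a VCF.

    Genotype ``a|b`` in the first sample sets hap1/hap2 alleles and
    ``phased=True``; ``a/b`` leaves the variant unphased. Positions are
    converted to 0-based. Non-SNV and homozygous records are skipped.
    """
    variants = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 10:
                raise FormatError(f"{path}:{lineno}: VCF record needs >=10 columns")
            chrom, pos, _, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if len(ref) != 1 or len(alt) != 1 or "," in alt:
                continue
            fmt = fields[8].split(":")
            sample = fields[9].split(":")
            rec = dict(zip(fmt, sample))
            gt = rec.get("GT", "./.")
            phased = "|" in gt
            sep = "|" if phased else "/"
            try:
                a, b = gt.split(sep)
                ia, ib = int(a), int(b)
            except ValueError:
                continue
            if ia == ib:
                continue
            alleles = {0: ref, 1: alt}
            try:
                v = PhasedVariant(
                    chrom=chrom,
                    pos=int(pos) - 1,
                    ref_allele=ref,
                    alt_allele=alt,
                    hap1_allele=alleles[ia] if phased else None,
                    hap2_allele=alleles[ib] if phased else None,
                    phase_set=rec.get("PS") if phased else None,
                    phased=phased,
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            variants.append(v)
    return variants


def write_vcf_hets(variants: Iterable[PhasedVariant], path: str | Path) -> None:
    """Write het SNVs as a minimal single-sample VCF with PS tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=String,Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in variants:
            if v.phased:
                gt = "0|1" if v.hap1_allele == v.ref_allele else "1|0"
                fmt, sample = "GT:PS", f"{gt}:{v.phase_set or '.'}"
            else:
                fmt, sample = "GT", "0/1"
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\t{fmt}\t{sample}\n"
            )


# ---------------------------------------------------------------------------
# SV table


SV_TABLE_HEADER = ("type", "chrom", "pos", "length", "chrom2", "pos2", "n_cells", "n_reads")


def write_sv_table(calls: Iterable[SVCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SV_TABLE_HEADER) + "\n")
        for c in calls:
            fh.write(
                "\t".join(
                    (
                        c.sv_type,
                        c.chrom,
                        str(c.pos),
                        str(c.length),
                        c.chrom2 or ".",
                        "." if c.pos2 is None else str(c.pos2),
                        str(c.n_cells),
                        str(c.supporting_reads),
                    )
                )
                + "\n"
            )


def read_sv_table(path: str | Path) -> list[SVCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SV_TABLE_HEADER:
            raise FormatError(f"{path}:1: unexpected SV table header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                calls.append(
                    SVCall(
                        sv_type=f[0],
                        chrom=f[1],
                        pos=int(f[2]),
                        length=int(f[3]),
                        chrom2=None if f[4] == "." else f[4],
                        pos2=None if f[5] == "." else int(f[5]),
                        supporting_cells={f"cell{i}" for i in range(int(f[6]))},
                        supporting_reads=int(f[7]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return calls
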