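"""Structural variants from long-read fragments.

Candidates come from large CIGAR insertions/deletions and cross-
chromosome split alignments; they are clustered across cells by
single-linkage on breakpoint proximity (and size similarity for
INS/DEL), and an SV is called when enough *distinct cells* contribute
evidence — a single cell's reads, however many, cannot make a call.
Somatic events are case calls with no match in a germline control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .model import Fragment, SVCall


@dataclass(frozen=True)
class SVEvidence:
    """One read's evidence for one candidate SV."""

    sv_type: str
    chrom: str
    pos: int
    length: int
    cell_id: str
    chrom2: Optional[str] = None
    pos2: Optional[int] = None


def extract_candidates(
    fragments: Sequence[Fragment], min_sv_len: int = 50
) -> list[SVEvidence]:
    """Per-read SV evidence from CIGAR events and split anchors.

    A CIGAR I of at least ``min_sv_len`` yields an INS at the insertion
    point; a D yields a DEL spanning the deleted reference interval; a
    supplementary anchor on a different chromosome yields a TRA between
    the primary alignment's terminus (where the alignment breaks off to
    the partner locus) and the anchor.
    """
    out: list[SVEvidence] = []
    for f in fragments:
        ref_pos = f.start
        for op, length in f.cigar_events:
            if op == "M" or op == "D":
                if op == "D" and length >= min_sv_len:
                    out.append(
                        SVEvidence("DEL", f.chrom, ref_pos, length, f.cell_id)
                    )
                ref_pos += length
            elif op == "I" and length >= min_sv_len:
                out.append(SVEvidence("INS", f.chrom, ref_pos, length, f.cell_id))
            # S/H consume no reference
        for chrom2, pos2, _strand in f.supplementary:
            if chrom2 != f.chrom:
                out.append(
                    SVEvidence("TRA", f.chrom, f.end, 0, f.cell_id, chrom2, pos2)
                )
    return out


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _linked(a: SVEvidence, b: SVEvidence, pos_tol: int, min_size_ratio: float) -> bool:
    if a.sv_type != b.sv_type or a.chrom != b.chrom:
        return False
    if abs(a.pos - b.pos) > pos_tol:
        return False
    if a.sv_type == "TRA":
        return a.chrom2 == b.chrom2 and abs((a.pos2 or 0) - (b.pos2 or 0)) <= pos_tol
    lo, hi = sorted((a.length, b.length))
    return hi > 0 and lo / hi >= min_size_ratio


def cluster_candidates(
    evidence: Sequence[SVEvidence],
    pos_tol: int = 500,
    min_size_ratio: float = 0.7,
) -> list[SVCall]:
    """Single-linkage clustering of per-read evidence into SV calls.

    Two INS/DEL candidates link when their breakpoints are within
    ``pos_tol`` and the smaller length is at least ``min_size_ratio`` of
    the larger; TRAs link when both breakpoints agree within
    ``pos_tol``. A call's position and length are the medians of its
    members; supporting cells are the distinct contributing cell ids.
    Order-invariant: input is canonically sorted first.
    """
    ev = sorted(
        evidence,
        key=lambda x: (x.sv_type, x.chrom, x.pos, x.length, x.cell_id,
                       x.chrom2 or "", x.pos2 or 0),
    )
    uf = _UnionFind(len(ev))
    for i in range(len(ev)):
        for j in range(i + 1, len(ev)):
            if (ev[j].sv_type, ev[j].chrom) != (ev[i].sv_type, ev[i].chrom):
                break
            if ev[j].pos - ev[i].pos > pos_tol:
                break
            if _linked(ev[i], ev[j], pos_tol, min_size_ratio):
                uf.union(i, j)
    groups: dict[int, list[SVEvidence]] = {}
    for i, e in enumerate(ev):
        groups.setdefault(uf.find(i), []).append(e)
    calls = []
    for root in sorted(groups):
        members = groups[root]
        pos = int(np.median([m.pos for m in members]))
        length = int(np.median([m.length for m in members]))
        first = members[0]
        call = SVCall(
            sv_type=first.sv_type,
            chrom=first.chrom,
            pos=pos,
            length=length,
            supporting_cells={m.cell_id for m in members},
            supporting_reads=len(members),
        )
        if first.sv_type == "TRA":
            call.chrom2 = first.chrom2
            call.pos2 = int(np.median([m.pos2 or 0 for m in members]))
        calls.append(call)
    return calls


def call_svs(clusters: Sequence[SVCall], min_cells: int = 5) -> list[SVCall]:
    """Keep clusters supported by at least ``min_cells`` distinct cells."""
    return [c for c in clusters if c.n_cells >= min_cells]


def _match(
    called: Sequence[SVCall],
    truth: Sequence[SVCall],
    pos_tol: int,
    min_size_ratio: float,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching by breakpoint distance, each truth once."""
    candidates = []
    for i, c in enumerate(called):
        for j, t in enumerate(truth):
            if c.sv_type != t.sv_type or c.chrom != t.chrom:
                continue
            if abs(c.pos - t.pos) > pos_tol:
                continue
            if c.sv_type == "TRA":
                if c.chrom2 != t.chrom2 or abs((c.pos2 or 0) - (t.pos2 or 0)) > pos_tol:
                    continue
            else:
                lo, hi = sorted((c.length, t.length))
                if hi == 0 or lo / hi < min_size_ratio:
                    continue
            candidates.append((abs(c.pos - t.pos), i, j))
    candidates.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used_c or j in used_t:
            continue
        used_c.add(i)
        used_t.add(j)
        pairs.append((i, j))
    return pairs


def benchmark_svs(
    called: Sequence[SVCall],
    truth: Sequence[SVCall],
    pos_tol: int = 1000,
    min_size_ratio: float = 0.7,
    min_cells_sweep: Optional[Sequence[int]] = None,
) -> dict[str, dict[int, tuple[float, float]]]:
    """Precision/recall per SV type across a minimum-cell-support sweep.

    Returns ``{sv_type: {min_cells: (precision, recall)}}``. Precision
    is matched-called / called, recall matched-truth / truth, under
    greedy one-to-one matching by breakpoint proximity.
    """
    if not truth:
        raise ValueError("truth SV set is empty")
    sweep = list(min_cells_sweep) if min_cells_sweep is not None else [1]
    out: dict[str, dict[int, tuple[float, float]]] = {}
    for sv_type in sorted({t.sv_type for t in truth} | {c.sv_type for c in called}):
        t_sub = [t for t in truth if t.sv_type == sv_type]
        out[sv_type] = {}
        for k in sweep:
            c_sub = [c for c in called if c.sv_type == sv_type and c.n_cells >= k]
            pairs = _match(c_sub, t_sub, pos_tol, min_size_ratio)
            precision = len(pairs) / len(c_sub) if c_sub else float("nan")
            recall = len(pairs) / len(t_sub) if t_sub else float("nan")
            out[sv_type][k] = (precision, recall)
    return out


def somatic_filter(
    case_calls: Sequence[SVCall],
    control_calls: Sequence[SVCall],
    pos_tol: int = 1000,
    min_size_ratio: float = 0.7,
) -> list[SVCall]:
    """Case calls with no germline match in the control call set."""
    matched = {i for i, _ in _match(case_calls, control_calls, pos_tol, min_size_ratio)}
    return [c for i, c in enumerate(case_calls) if i not in matched]
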