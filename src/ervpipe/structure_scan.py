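"""Simplified proviral structure assessment.

Alignment-free heuristics over the internal region of a full-length
provirus: primer-binding-site (pbs) motif search just downstream of the 5'
LTR, polypurine-tract (PPT) search just upstream of the 3' LTR, an ORF scan
(maximal stop-free codon runs in all six frames), and a gag-state call —
intact, frameshifted (two sub-threshold ORFs in different frames jointly
covering the gag region), or absent.  These are heuristic surrogates for
full retroviral-motif chain reconstruction; every threshold is a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ervpipe.locus_builder import ERVLocus, internal_region, reverse_complement

STOP_CODONS = {"TAA", "TAG", "TGA"}
PURINES = frozenset("AG")

#: synthetic default pbs motif (tRNA databases are user-supplied inputs)
DEFAULT_PBS_MOTIFS = ("TGGCGCCCGAACAGGGAC",)


@dataclass(frozen=True)
class ORF:
    frame: int  # 0..2 forward, 3..5 reverse
    start: int  # nt offset in the internal region (forward coordinates)
    end: int
    length_codons: int


@dataclass(frozen=True)
class StructureReport:
    pbs_found: bool
    pbs_offset: int | None
    ppt_found: bool
    ppt_offset: int | None
    orfs: tuple[ORF, ...]
    gag_state: str  # intact | frameshifted | absent
    notes: str = ""


@dataclass(frozen=True)
class StructureParams:
    pbs_motifs: tuple[str, ...] = DEFAULT_PBS_MOTIFS
    pbs_search_bp: int = 30
    pbs_max_mismatch: int = 1
    ppt_search_bp: int = 30
    ppt_min_len: int = 10
    ppt_min_purine_frac: float = 0.9
    min_codons: int = 100
    gag_min_codons: int = 400
    frameshift_max_gap: int = 30


def find_orfs(seq: str, min_codons: int = 100) -> list[ORF]:
    """Maximal stop-free codon runs >= ``min_codons`` in all six frames.

    Reverse-frame ORFs are reported in forward coordinates of ``seq``.
    Runs are stop-free; no start codon is required (ancient proviruses
    rarely keep one).
    """
    seq = seq.upper()
    orfs: list[ORF] = []
    for strand, s in ((0, seq), (3, reverse_complement(seq))):
        n = len(s)
        for frame in range(3):
            run_start = frame
            pos = frame
            while pos + 3 <= n:
                if s[pos : pos + 3] in STOP_CODONS:
                    _append_orf(orfs, strand, frame, run_start, pos, n, min_codons)
                    run_start = pos + 3
                pos += 3
            _append_orf(orfs, strand, frame, run_start, pos, n, min_codons)
    return sorted(orfs, key=lambda o: (o.start, o.frame))


def _append_orf(
    orfs: list[ORF], strand: int, frame: int, start: int, end: int, n: int, min_codons: int
) -> None:
    codons = (end - start) // 3
    if codons < min_codons:
        return
    if strand == 0:
        orfs.append(ORF(frame, start, start + codons * 3, codons))
    else:
        # map reverse-strand run back to forward coordinates
        fwd_end = n - start
        orfs.append(ORF(strand + frame, fwd_end - codons * 3, fwd_end, codons))


def _find_pbs(
    internal: str, motifs: Sequence[str], search_bp: int, max_mismatch: int
) -> tuple[bool, int | None]:
    window = internal[: search_bp + max(len(m) for m in motifs)].upper()
    best: tuple[int, int] | None = None  # (mismatches, offset)
    for motif in motifs:
        motif = motif.upper()
        for off in range(0, min(search_bp, len(window) - len(motif)) + 1):
            mism = sum(a != b for a, b in zip(window[off : off + len(motif)], motif))
            if mism <= max_mismatch and (best is None or (mism, off) < best):
                best = (mism, off)
    if best is None:
        return False, None
    return True, best[1]


def _find_ppt(
    internal: str, search_bp: int, min_len: int, min_purine_frac: float
) -> tuple[bool, int | None]:
    tail = internal[-search_bp:].upper()
    n = len(tail)
    for length in range(n, min_len - 1, -1):
        for off in range(0, n - length + 1):
            window = tail[off : off + length]
            frac = sum(c in PURINES for c in window) / length
            if frac >= min_purine_frac:
                # offset of the window start upstream of the 3' LTR
                return True, n - off
    return False, None


def _gag_state(orfs: Sequence[ORF], internal_len: int, params: StructureParams) -> str:
    third = internal_len / 3.0
    forward = [o for o in orfs if o.frame < 3]
    for orf in forward:
        if orf.length_codons >= params.gag_min_codons and orf.start <= third:
            return "intact"
    # frameshift: two sub-threshold ORFs in different frames jointly covering gag
    for o1 in forward:
        if o1.start > third or o1.length_codons >= params.gag_min_codons:
            continue
        for o2 in forward:
            if o2 is o1 or o2.frame == o1.frame:
                continue
            gap = o2.start - o1.end
            if gap > params.frameshift_max_gap:
                continue
            if o2.end <= o1.end:
                continue
            span = o2.end - o1.start
            if span >= params.gag_min_codons * 3:
                return "frameshifted"
    return "absent"


def scan_structure(
    locus: ERVLocus,
    genome: Mapping[str, str],
    params: StructureParams | None = None,
) -> StructureReport:
    """Assess the proviral structure of a full-length locus.

    See module docstring; all thresholds come from ``StructureParams``.
    An internal region shorter than 300 nt is reported as-is with
    ``notes='internal too short'``.
    """
    if locus.classification != "full_length":
        raise ValueError("structure scan applies to full-length loci")
    params = params or StructureParams()
    internal = internal_region(locus, genome)
    if len(internal) < 300:
        return StructureReport(False, None, False, None, (), "absent", "internal too short")

    pbs_found, pbs_offset = _find_pbs(
        internal, params.pbs_motifs, params.pbs_search_bp, params.pbs_max_mismatch
    )
    ppt_found, ppt_offset = _find_ppt(
        internal, params.ppt_search_bp, params.ppt_min_len, params.ppt_min_purine_frac
    )
    orfs = tuple(find_orfs(internal, params.min_codons))
    gag = _gag_state(orfs, len(internal), params)
    return StructureReport(pbs_found, pbs_offset, ppt_found, ppt_offset, orfs, gag)
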