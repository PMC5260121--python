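"""Flanking-sequence features of ERV insertions.

Target-site duplications (TSDs) — short direct repeats of host sequence
created at integration — are the hallmark of a retrotransposition event;
the fixed LTR terminal motifs (TGTTG ... CAACA, mutual reverse complements)
mark intact LTR ends.  The genomic environment of each insertion is
summarised as flank GC content, flank gene density, and a genic-context
class (exonic > intronic > intergenic).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ervpipe.io_formats import GeneModel
from ervpipe.locus_builder import ERVLocus

TIR_5 = "TGTTG"
TIR_3 = "CAACA"


@dataclass(frozen=True)
class TSDReport:
    left_seq: str
    right_seq: str
    length: int
    is_match: bool
    mismatches: int
    edge: bool = False


@dataclass(frozen=True)
class GenomicContext:
    gc_pct: float | None
    gene_count_2mb: int
    genes_per_mb: float
    genic_class: str


def detect_tsd(
    locus: ERVLocus,
    genome: Mapping[str, str],
    kmin: int = 3,
    kmax: int = 8,
) -> TSDReport:
    """Find the longest exact target-site duplication flanking a locus.

    Compares the k-mer immediately 5' of the locus with the k-mer
    immediately 3' of it for k from ``kmax`` down to ``kmin``; the longest
    exact match wins.  If no k matches, the ``kmin``-mers are reported with
    their mismatch count.  A locus too close to a chromosome end for a
    ``kmax`` flank is reported unmatched and flagged ``edge``.
    """
    chrom_seq = genome[locus.chrom]
    if locus.start < kmax or locus.end + kmax > len(chrom_seq):
        k = min(kmin, locus.start, len(chrom_seq) - locus.end)
        left = chrom_seq[max(0, locus.start - k) : locus.start].upper()
        right = chrom_seq[locus.end : locus.end + k].upper()
        mism = sum(a != b for a, b in zip(left, right)) + abs(len(left) - len(right))
        return TSDReport(left, right, len(left), False, mism, edge=True)

    for k in range(kmax, kmin - 1, -1):
        left = chrom_seq[locus.start - k : locus.start].upper()
        right = chrom_seq[locus.end : locus.end + k].upper()
        if left == right and "N" not in left:
            return TSDReport(left, right, k, True, 0)
    left = chrom_seq[locus.start - kmin : locus.start].upper()
    right = chrom_seq[locus.end : locus.end + kmin].upper()
    mism = sum(a != b for a, b in zip(left, right))
    return TSDReport(left, right, kmin, False, mism)


def check_tir(ltr_seq: str) -> tuple[bool, bool]:
    """Test the LTR terminal motifs: starts with TGTTG, ends with CAACA."""
    if len(ltr_seq) < 10:
        raise ValueError("LTR sequence shorter than 10 nt")
    seq = ltr_seq.upper()
    return seq.startswith(TIR_5), seq.endswith(TIR_3)


def gc_window(
    locus: ERVLocus,
    genome: Mapping[str, str],
    window_bp: int = 20_000,
) -> float | None:
    """GC% of the two flanks around a locus, element itself excluded.

    ``window_bp/2`` is taken upstream and downstream; windows are clipped at
    chromosome ends and the actual length is used.  N bases are excluded
    from the denominator; an empty denominator yields ``None``.
    """
    if window_bp % 2:
        raise ValueError("window_bp must be even")
    half = window_bp // 2
    chrom_seq = genome[locus.chrom]
    flank = (
        chrom_seq[max(0, locus.start - half) : locus.start]
        + chrom_seq[locus.end : locus.end + half]
    ).upper()
    denom = len(flank) - flank.count("N")
    if denom == 0:
        return None
    gc = flank.count("G") + flank.count("C")
    return 100.0 * gc / denom


def gene_density(
    locus: ERVLocus,
    genes: Sequence[GeneModel],
    window_bp: int = 2_000_000,
) -> tuple[int, float]:
    """Count genes overlapping the flanking window; return (count, genes/Mb).

    The window spans ``window_bp/2`` on each side of the locus (element
    excluded); any overlap counts.  Density uses the nominal window size:
    ``genes_per_mb = count / (window_bp / 1e6)``.
    """
    half = window_bp // 2
    lo = locus.start - half
    hi = locus.end + half
    count = sum(
        1
        for g in genes
        if g.feature_kind == "gene"
        and g.chrom == locus.chrom
        and g.start < hi
        and g.end > lo
        and not (g.start >= locus.start and g.end <= locus.end)
    )
    return count, count / (window_bp / 1e6)


def genic_context(locus: ERVLocus, genes: Sequence[GeneModel]) -> str:
    """Classify a locus exonic, intronic or intergenic (in that precedence).

    Exonic if the locus overlaps any exon feature; otherwise intronic if it
    lies within any gene span; otherwise intergenic.  Order-independent.
    """
    overlaps_exon = any(
        g.feature_kind == "exon"
        and g.chrom == locus.chrom
        and g.start < locus.end
        and g.end > locus.start
        for g in genes
    )
    if overlaps_exon:
        return "exonic"
    in_gene = any(
        g.feature_kind == "gene"
        and g.chrom == locus.chrom
        and g.start < locus.end
        and g.end > locus.start
        for g in genes
    )
    return "intronic" if in_gene else "intergenic"
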