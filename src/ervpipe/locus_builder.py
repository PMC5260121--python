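"""Assemble repeat hits into ERV loci and classify them.

A provirus leaves two LTRs flanking an internal coding region; homologous
recombination between the LTRs collapses it to a solo-LTR; everything else
(missing LTRs, internal-only remnants) is truncated.  RepeatMasker reports
one row per fragment, linked by an ID column, so assembly is (1) group by
linkage id, (2) conservatively merge nearby same-strand fragments of the
same subfamily, (3) assign LTR5/INTERNAL/LTR3 roles along element
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from ervpipe.io_formats import RepeatHit

LTR_SUFFIX = "-LTR"
INT_SUFFIX = "-int"

#: fraction of N bases above which an extracted LTR is flagged low-quality
MAX_N_FRACTION = 0.20

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ERVLocus:
    """An assembled ERV locus with component hits and a class label.

    ``components`` is ordered along element orientation (5' to 3' of the
    element, i.e. reversed genomic order on the minus strand); each entry is
    ``(hit, role)`` with role in {LTR5, INTERNAL, LTR3, LTR_SOLO}.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    components: list[tuple[RepeatHit, str]]
    classification: str = "truncated"
    irregular: bool = False
    ltr5_seq: str | None = None
    ltr3_seq: str | None = None
    solo_seq: str | None = None
    ltr5_low_quality: bool = False
    ltr3_low_quality: bool = False
    tir_5: bool | None = None
    tir_3: bool | None = None

    @property
    def roles(self) -> list[str]:
        return [role for _, role in self.components]

    def subfamily_stem(self) -> str:
        """Repeat-name stem of the first component ('GGERV10B-LTR' -> 'GGERV10B')."""
        return _stem(self.components[0][0].repeat_name)


def _stem(repeat_name: str) -> str:
    for suffix in (LTR_SUFFIX, INT_SUFFIX):
        if repeat_name.endswith(suffix):
            return repeat_name[: -len(suffix)]
    return repeat_name


def _is_ltr(repeat_name: str) -> bool:
    return repeat_name.endswith(LTR_SUFFIX)


def assemble_loci(
    hits: Sequence[RepeatHit],
    max_gap_bp: int = 500,
    mean_internal_len: int | None = None,
) -> list[ERVLocus]:
    """Group repeat hits into ERV loci.

    Hits sharing a linkage id always form one locus.  Groups with distinct
    linkage ids are additionally merged when they lie on the same chromosome
    and strand, the gap between them is at most ``max_gap_bp``, and their
    repeat names share a subfamily stem — a conservative automation of
    joining fragments of one element split by the annotation.

    Every input hit ends up in exactly one locus; class counts do not depend
    on input row order.
    """
    if max_gap_bp < 0:
        raise ValueError("max_gap_bp must be >= 0")

    # group by (chrom, linkage_id); empty linkage ids stay singletons
    groups: dict[tuple, list[RepeatHit]] = {}
    for i, hit in enumerate(sorted(hits, key=lambda h: (h.chrom, h.start, h.end, h.repeat_name))):
        key = (hit.chrom, hit.linkage_id) if hit.linkage_id else (hit.chrom, f"_anon{i}")
        groups.setdefault(key, []).append(hit)

    # merge nearby same-stem, same-strand groups
    merged: list[list[RepeatHit]] = []
    for group in sorted(groups.values(), key=lambda g: (g[0].chrom, min(h.start for h in g))):
        group = sorted(group, key=lambda h: h.start)
        if merged:
            prev = merged[-1]
            gap = group[0].start - max(h.end for h in prev)
            if (
                prev[0].chrom == group[0].chrom
                and prev[0].strand == group[0].strand
                and gap <= max_gap_bp
                and _stem(prev[0].repeat_name) == _stem(group[0].repeat_name)
            ):
                prev.extend(group)
                continue
        merged.append(group)

    if mean_internal_len is None:
        internal_lens = [h.end - h.start for h in hits if not _is_ltr(h.repeat_name)]
        mean_internal_len = (
            int(sum(internal_lens) / len(internal_lens)) if internal_lens else 0
        )

    loci = []
    for idx, group in enumerate(merged):
        loci.append(_build_locus(f"locus_{idx:05d}", group, mean_internal_len))
    return loci


def _build_locus(locus_id: str, group: list[RepeatHit], mean_internal_len: int) -> ERVLocus:
    group = sorted(group, key=lambda h: h.start)
    chrom = group[0].chrom
    strand = group[0].strand
    start = min(h.start for h in group)
    end = max(h.end for h in group)

    # element orientation: minus-strand elements read right-to-left
    oriented = group if strand == "+" else list(reversed(group))
    kinds = ["LTR" if _is_ltr(h.repeat_name) else "INTERNAL" for h in oriented]

    irregular = False
    components: list[tuple[RepeatHit, str]] = []
    n_ltr = kinds.count("LTR")
    n_int = kinds.count("INTERNAL")

    if n_ltr == 1 and n_int == 0:
        components = [(oriented[0], "LTR_SOLO")]
    else:
        # an LTR strictly between two internals breaks proviral structure
        for i, kind in enumerate(kinds):
            if kind == "LTR" and 0 < i < len(kinds) - 1:
                if kinds[i - 1] == "INTERNAL" and kinds[i + 1] == "INTERNAL":
                    irregular = True
        seen_ltr5 = False
        for i, (hit, kind) in enumerate(zip(oriented, kinds)):
            if kind == "INTERNAL":
                components.append((hit, "INTERNAL"))
            elif i == 0 and not seen_ltr5:
                components.append((hit, "LTR5"))
                seen_ltr5 = True
            else:
                components.append((hit, "LTR3"))

    locus = ERVLocus(
        locus_id=locus_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        components=components,
        irregular=irregular,
    )
    locus.classification = classify_locus(locus, mean_internal_len)
    return locus


def classify_locus(locus: ERVLocus, mean_internal_len: int = 0) -> str:
    """Label a locus full_length, solo_ltr, or truncated.

    full_length requires LTR5 + at least one INTERNAL + LTR3; a lone
    LTR_SOLO is a solo-LTR; everything else — including the irregular case
    and the two-LTRs-no-internal case (internal region deleted, not two
    independent recombination remnants) — is truncated.  Truncated loci stay
    in the output but are excluded downstream from dating and from
    subfamily-consensus alignments.
    """
    roles = locus.roles
    if locus.irregular:
        return "truncated"
    if roles == ["LTR_SOLO"]:
        return "solo_ltr"
    if "LTR5" in roles and "LTR3" in roles and "INTERNAL" in roles:
        return "full_length"
    return "truncated"


def extract_ltrs(locus: ERVLocus, genome: Mapping[str, str]) -> ERVLocus:
    """Extract LTR sequences in element orientation; mutates and returns ``locus``.

    Minus-strand loci are reverse-complemented so the returned strings read
    5' to 3' of the element.  An LTR whose span is more than 20% N is still
    returned but flagged low-quality (excluded from alignments downstream).
    """
    chrom_seq = genome[locus.chrom]
    if locus.end > len(chrom_seq):
        raise ValueError(f"locus {locus.locus_id} extends past end of {locus.chrom}")

    def slice_hit(hit: RepeatHit) -> str:
        seq = chrom_seq[hit.start : hit.end].upper()
        return reverse_complement(seq) if locus.strand == "-" else seq

    for hit, role in locus.components:
        if role == "LTR5":
            locus.ltr5_seq = slice_hit(hit)
        elif role == "LTR3":
            locus.ltr3_seq = slice_hit(hit)
        elif role == "LTR_SOLO":
            locus.solo_seq = slice_hit(hit)

    if locus.ltr5_seq:
        locus.ltr5_low_quality = locus.ltr5_seq.count("N") > MAX_N_FRACTION * len(locus.ltr5_seq)
    if locus.ltr3_seq:
        locus.ltr3_low_quality = locus.ltr3_seq.count("N") > MAX_N_FRACTION * len(locus.ltr3_seq)
    return locus


def internal_region(locus: ERVLocus, genome: Mapping[str, str]) -> str:
    """Concatenated INTERNAL component sequence in element orientation."""
    chrom_seq = genome[locus.chrom]
    internals = sorted(
        (h for h, r in locus.components if r == "INTERNAL"), key=lambda h: h.start
    )
    seq = "".join(chrom_seq[h.start : h.end].upper() for h in internals)
    return reverse_complement(seq) if locus.strand == "-" else seq
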