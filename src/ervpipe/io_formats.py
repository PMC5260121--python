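"""Readers and writers for the standard formats the pipeline touches.

Internal convention: every coordinate held in memory is 0-based half-open.
Converters for 1-based formats (RepeatMasker ``.out``, GFF3) live only here,
in the readers and writers, so downstream modules never see mixed conventions.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

DEFAULT_NAME_PATTERN = "GGERV10"


@dataclass(frozen=True)
class RepeatHit:
    """One repeat-annotation row in 0-based half-open coordinates.

    ``linkage_id`` is the RepeatMasker ID column: fragments of a single
    interrupted element share one id, which is what lets the locus builder
    reassemble a provirus split by nested insertions.
    """

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str = "LTR/ERV"
    consensus_start: int = 0
    consensus_end: int = 0
    divergence_pct: float = 0.0
    linkage_id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"RepeatHit requires start < end, got [{self.start}, {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 <= self.divergence_pct <= 100.0:
            raise ValueError(f"divergence_pct outside [0, 100]: {self.divergence_pct}")


@dataclass(frozen=True)
class GeneModel:
    """A gene or exon feature in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"GeneModel requires start < end, got [{self.start}, {self.end})")
        if self.feature_kind not in {"gene", "exon"}:
            raise ValueError(f"feature_kind must be 'gene' or 'exon', got {self.feature_kind!r}")


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome into a chrom -> upper-case sequence mapping."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    return genome


def _strip_parens(tok: str) -> int:
    return int(tok.strip("()"))


def _parse_rm_out_line(tokens: list[str], lineno: int) -> tuple:
    # standard 15-column .out layout; trailing '*' overlap marker optional
    try:
        chrom = tokens[4]
        start = int(tokens[5]) - 1  # 1-based inclusive -> 0-based half-open
        end = int(tokens[6])
        strand = "-" if tokens[8] in {"C", "-"} else "+"
        repeat_name = tokens[9]
        repeat_class = tokens[10]
        if strand == "+":
            cons_start = _strip_parens(tokens[11]) - 1
            cons_end = _strip_parens(tokens[12])
        else:
            # minus strand prints (left) end begin
            cons_start = _strip_parens(tokens[13]) - 1
            cons_end = _strip_parens(tokens[12])
        divergence = float(tokens[1])
        linkage_id = tokens[14]
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed RepeatMasker .out row at line {lineno}: {exc}") from exc
    return chrom, start, end, strand, repeat_name, repeat_class, cons_start, cons_end, divergence, linkage_id


def _parse_ucsc_line(tokens: list[str], lineno: int) -> tuple:
    # UCSC rmsk table, with or without the leading bin column
    if len(tokens) == 17:
        tokens = tokens[1:]
    try:
        divergence = float(tokens[1]) / 10.0  # milliDiv
        chrom = tokens[4]
        start = int(tokens[5])  # genoStart is already 0-based
        end = int(tokens[6])
        strand = "-" if tokens[8] in {"C", "-"} else "+"
        repeat_name = tokens[9]
        repeat_class = tokens[10]
        cons_start = _strip_parens(tokens[12]) - 1
        cons_end = _strip_parens(tokens[13])
        linkage_id = tokens[15]
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed UCSC rmsk row at line {lineno}: {exc}") from exc
    return chrom, start, end, strand, repeat_name, repeat_class, cons_start, cons_end, divergence, linkage_id


def read_rmsk(
    path: str | Path,
    dialect: str = "rm_out",
    name_pattern: str = DEFAULT_NAME_PATTERN,
) -> list[RepeatHit]:
    """Read repeat annotation in RepeatMasker ``.out`` or UCSC rmsk dialect.

    Parameters
    ----------
    path
        Annotation file.
    dialect
        ``"rm_out"`` (native RepeatMasker output, 1-based inclusive) or
        ``"ucsc_rmsk"`` (Table Browser TSV, genoStart already 0-based).
    name_pattern
        Regular expression; rows whose repeat name does not match are
        dropped.  Pass ``""`` to keep every row.

    Returns
    -------
    list of RepeatHit with 0-based half-open coordinates.
    """
    if dialect not in {"rm_out", "ucsc_rmsk"}:
        raise ValueError(f"unknown rmsk dialect: {dialect!r}")
    pattern = re.compile(name_pattern) if name_pattern else None
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if dialect == "rm_out":
                # skip the two header lines RepeatMasker prints
                if tokens[0] in {"SW", "score"}:
                    continue
                parsed = _parse_rm_out_line(tokens, lineno)
            else:
                if not tokens[0].lstrip("-").isdigit():
                    continue  # header row
                parsed = _parse_ucsc_line(tokens, lineno)
            chrom, start, end, strand, name, rclass, cs, ce, div, lid = parsed
            if pattern is not None and not pattern.search(name):
                continue
            hits.append(
                RepeatHit(
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    repeat_name=name,
                    repeat_class=rclass,
                    consensus_start=cs,
                    consensus_end=ce,
                    divergence_pct=div,
                    linkage_id=lid,
                )
            )
    return hits


def read_gene_annotation(path: str | Path, format: str = "bed") -> list[GeneModel]:
    """Read gene annotation from BED4+ or GFF3 into 0-based half-open models.

    BED rows become ``gene`` features.  GFF3 ``gene`` and ``exon`` rows are
    kept (1-based starts converted); exon gene_id is taken from ``Parent``.
    Overlapping duplicates of the same gene_id trigger a warning but both
    rows are kept.
    """
    if format not in {"bed", "gff3"}:
        raise ValueError(f"unknown gene annotation format: {format!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            cols = stripped.split("\t")
            if len(cols) == 1:
                cols = stripped.split()
            if format == "bed":
                if len(cols) < 3:
                    raise ValueError(f"malformed BED row at line {lineno}")
                name = cols[3] if len(cols) > 3 else f"gene_{lineno}"
                strand = cols[5] if len(cols) > 5 and cols[5] in {"+", "-"} else "+"
                genes.append(GeneModel(cols[0], int(cols[1]), int(cols[2]), strand, name))
            else:
                if len(cols) < 9:
                    raise ValueError(f"malformed GFF3 row at line {lineno}")
                kind = cols[2].lower()
                if kind not in {"gene", "exon"}:
                    continue
                attrs = dict(
                    item.split("=", 1) for item in cols[8].split(";") if "=" in item
                )
                if kind == "gene":
                    gene_id = attrs.get("ID", attrs.get("gene_id", f"gene_{lineno}"))
                else:
                    gene_id = attrs.get("Parent", attrs.get("ID", f"exon_{lineno}"))
                strand = cols[6] if cols[6] in {"+", "-"} else "+"
                genes.append(
                    GeneModel(cols[0], int(cols[3]) - 1, int(cols[4]), strand, gene_id, kind)
                )
    _warn_duplicate_genes(genes)
    return genes


def _warn_duplicate_genes(genes: Sequence[GeneModel]) -> None:
    seen: dict[tuple[str, str], GeneModel] = {}
    for g in genes:
        if g.feature_kind != "gene":
            continue
        key = (g.chrom, g.gene_id)
        prev = seen.get(key)
        if prev is not None and g.start < prev.end and prev.start < g.end:
            warnings.warn(f"overlapping duplicate gene_id {g.gene_id!r} on {g.chrom}")
        seen[key] = g


RM_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def write_rmsk(hits: Iterable[RepeatHit], path: str | Path, dialect: str = "rm_out") -> None:
    """Write repeat hits in RepeatMasker ``.out`` or UCSC rmsk dialect.

    Inverse of :func:`read_rmsk`: a written file re-read with the same
    dialect reproduces identical 0-based half-open coordinates.
    """
    if dialect not in {"rm_out", "ucsc_rmsk"}:
        raise ValueError(f"unknown rmsk dialect: {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "rm_out":
            fh.write(RM_OUT_HEADER)
            for h in hits:
                strand = "+" if h.strand == "+" else "C"
                if h.strand == "+":
                    rep_pos = f"{h.consensus_start + 1} {h.consensus_end} (0)"
                else:
                    rep_pos = f"(0) {h.consensus_end} {h.consensus_start + 1}"
                fh.write(
                    f"{1000:>5} {h.divergence_pct:>5.1f}  0.0  0.0  {h.chrom} "
                    f"{h.start + 1} {h.end} (0) {strand} {h.repeat_name} "
                    f"{h.repeat_class} {rep_pos} {h.linkage_id}\n"
                )
        else:
            fh.write(
                "#bin\tswScore\tmilliDiv\tmilliDel\tmilliIns\tgenoName\tgenoStart\t"
                "genoEnd\tgenoLeft\tstrand\trepName\trepClass\trepFamily\trepStart\t"
                "repEnd\trepLeft\tid\n"
            )
            for h in hits:
                fh.write(
                    f"0\t1000\t{h.divergence_pct * 10:.0f}\t0\t0\t{h.chrom}\t{h.start}\t"
                    f"{h.end}\t0\t{h.strand}\t{h.repeat_name}\t{h.repeat_class}\t"
                    f"{h.repeat_class}\t{h.consensus_start + 1}\t{h.consensus_end}\t0\t"
                    f"{h.linkage_id}\n"
                )


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


REPORT_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "strand",
    "classification",
    "subfamily",
    "chimeric",
    "tsd_seq",
    "tsd_len",
    "tir_5",
    "tir_3",
    "k2p_d",
    "age_myr",
    "gc_pct",
    "genes_per_mb",
    "genic_class",
]


def write_locus_report(
    loci: Sequence,
    calls: Mapping[str, object],
    ages: Mapping[str, object],
    contexts: Mapping[str, object],
    path: str | Path,
    tsds: Mapping[str, object] | None = None,
    summary_path: str | Path | None = None,
) -> None:
    """Write the per-locus TSV report plus a JSON per-subfamily summary.

    ``calls``, ``ages``, ``contexts`` and ``tsds`` are keyed by locus id;
    a missing key yields NA fields for that locus (with a logged warning)
    rather than an error, so partial runs still produce a report.
    """
    tsds = tsds or {}
    path = Path(path)
    rows = []
    for locus in loci:
        lid = locus.locus_id
        call = calls.get(lid)
        age = ages.get(lid)
        ctx = contexts.get(lid)
        tsd = tsds.get(lid)
        for name, mapping in (("call", calls), ("age", ages), ("context", contexts)):
            if lid not in mapping and name != "age":
                logger.warning("locus %s missing %s; emitting NA fields", lid, name)
        row = {
            "locus_id": lid,
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
            "strand": locus.strand,
            "classification": locus.classification,
            "subfamily": getattr(call, "locus_subfamily", "NA") if call else "NA",
            "chimeric": getattr(call, "chimeric", "NA") if call else "NA",
            "tsd_seq": getattr(tsd, "left_seq", "NA") if tsd and getattr(tsd, "is_match", False) else "NA",
            "tsd_len": getattr(tsd, "length", "NA") if tsd and getattr(tsd, "is_match", False) else "NA",
            "tir_5": getattr(locus, "tir_5", "NA"),
            "tir_3": getattr(locus, "tir_3", "NA"),
            "k2p_d": f"{age.d:.6f}" if age is not None else "NA",
            "age_myr": f"{age.age_myr:.4f}" if age is not None else "NA",
            "gc_pct": f"{ctx.gc_pct:.2f}" if ctx is not None and ctx.gc_pct is not None else "NA",
            "genes_per_mb": f"{ctx.genes_per_mb:.2f}" if ctx is not None else "NA",
            "genic_class": ctx.genic_class if ctx is not None else "NA",
        }
        rows.append(row)

    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in REPORT_COLUMNS) + "\n")

    summary = _subfamily_summary(loci, calls)
    spath = Path(summary_path) if summary_path else path.with_suffix(".summary.json")
    with open(spath, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _subfamily_summary(loci: Sequence, calls: Mapping[str, object]) -> dict:
    """Per-subfamily copy / full-length / solo counts and mean LTR length."""
    per: dict[str, dict] = {}
    n_class = {"full_length": 0, "solo_ltr": 0, "truncated": 0}
    for locus in loci:
        n_class[locus.classification] = n_class.get(locus.classification, 0) + 1
        call = calls.get(locus.locus_id)
        if call is None or locus.classification == "truncated":
            continue
        name = getattr(call, "locus_subfamily", None)
        if name is None:
            continue
        entry = per.setdefault(
            name, {"copy_number": 0, "n_full_length": 0, "n_solo_ltr": 0, "_ltr_lens": []}
        )
        entry["copy_number"] += 1
        if locus.classification == "full_length":
            entry["n_full_length"] += 1
            for seq in (locus.ltr5_seq, locus.ltr3_seq):
                if seq:
                    entry["_ltr_lens"].append(len(seq))
        elif locus.classification == "solo_ltr":
            entry["n_solo_ltr"] += 1
            if locus.solo_seq:
                entry["_ltr_lens"].append(len(locus.solo_seq))
    for entry in per.values():
        lens = entry.pop("_ltr_lens")
        entry["mean_ltr_len"] = round(sum(lens) / len(lens), 1) if lens else None
    return {
        "total_loci": len(loci),
        "class_counts": n_class,
        "subfamilies": per,
    }
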