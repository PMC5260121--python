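"""End-to-end orchestration: ingest -> assemble -> classify -> flank features
-> subfamily/chimera -> dating -> phylogeny -> structure scan -> report.

Every stage logs its record counts (the exclusion steps — truncated loci,
low-quality LTRs, heavily deleted copies — are all auditable events), the
summary JSON echoes every parameter and seed, and a fixed config + seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from ervpipe import dating_phylo, flank_features, io_formats, locus_builder, structure_scan
from ervpipe.dating_phylo import AgeEstimate
from ervpipe.flank_features import GenomicContext
from ervpipe.subfamily import (
    SubfamilyCall,
    assign_subfamily,
    build_subfamily_msa,
    detect_chimera,
    read_consensus_fasta,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure, carrying the stage name and offending record."""


@dataclass
class PipelineConfig:
    genome_path: str
    rmsk_path: str
    consensus_path: str
    out_dir: str
    genes_path: str | None = None
    genes_format: str = "bed"
    rmsk_dialect: str = "rm_out"
    name_pattern: str = "GGERV10"
    max_gap_bp: int = 500
    tsd_kmin: int = 3
    tsd_kmax: int = 8
    gc_window_bp: int = 20_000
    gene_window_bp: int = 2_000_000
    margin_min: float = 0.02
    max_deletion: int = 50
    mu: float = 0.0019
    bootstrap_reps: int = 100
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for label, p in (
            ("genome", self.genome_path),
            ("rmsk", self.rmsk_path),
            ("consensuses", self.consensus_path),
        ):
            if not Path(p).exists():
                raise PipelineError(f"pre-flight: {label} file not found: {p}")
        if self.genes_path is not None and not Path(self.genes_path).exists():
            raise PipelineError(f"pre-flight: genes file not found: {self.genes_path}")
        if self.rmsk_dialect not in {"rm_out", "ucsc_rmsk"}:
            raise PipelineError(f"pre-flight: unknown rmsk dialect {self.rmsk_dialect!r}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report set; returns the summary dict."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- ingest
    genome = _ingest_genome(config)
    hits = _ingest_hits(config)
    genes = _ingest_genes(config)
    consensuses = read_consensus_fasta(config.consensus_path)
    logger.info("ingest: %d repeat hits, %d gene features", len(hits), len(genes))

    # --- assemble + classify + extract
    loci = _assemble(config, hits, genome)
    n_class = _count_classes(loci)
    logger.info("assemble: %d loci %s", len(loci), n_class)

    # --- flank features
    tsds, contexts = _flank(config, loci, genome, genes)

    # --- subfamily / chimera
    calls = _subfamily_calls(config, loci, consensuses)

    # --- dating
    ages = _dating(config, loci)

    # --- subfamily MSAs + per-subfamily age
    subfamily_ages, excluded_ltrs = _subfamily_ages(config, loci, calls, outdir)

    # --- phylogeny of full-length LTRs
    newick_path = _phylogeny(config, loci, outdir)

    # --- structure scan
    structures = _structures(config, loci, genome)

    # --- report
    report_path = outdir / "locus_report.tsv"
    io_formats.write_locus_report(
        loci, calls, ages, contexts, report_path, tsds, outdir / "summary_subfamilies.json"
    )
    summary = _summary(
        config, loci, calls, ages, tsds, contexts, structures, subfamily_ages, excluded_ltrs
    )
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


@_stage("ingest_genome")
def _ingest_genome(config):
    return io_formats.read_genome(config.genome_path)


@_stage("ingest_rmsk")
def _ingest_hits(config):
    return io_formats.read_rmsk(config.rmsk_path, config.rmsk_dialect, config.name_pattern)


@_stage("ingest_genes")
def _ingest_genes(config):
    if config.genes_path is None:
        return []
    return io_formats.read_gene_annotation(config.genes_path, config.genes_format)


@_stage("assemble")
def _assemble(config, hits, genome):
    loci = locus_builder.assemble_loci(hits, config.max_gap_bp)
    for locus in loci:
        locus_builder.extract_ltrs(locus, genome)
        seq5 = locus.ltr5_seq or locus.solo_seq
        seq3 = locus.ltr3_seq or locus.solo_seq
        if seq5 and len(seq5) >= 10:
            locus.tir_5 = flank_features.check_tir(seq5)[0]
        if seq3 and len(seq3) >= 10:
            locus.tir_3 = flank_features.check_tir(seq3)[1]
    return loci


@_stage("flank_features")
def _flank(config, loci, genome, genes):
    tsds, contexts = {}, {}
    for locus in loci:
        tsds[locus.locus_id] = flank_features.detect_tsd(
            locus, genome, config.tsd_kmin, config.tsd_kmax
        )
        count, per_mb = flank_features.gene_density(locus, genes, config.gene_window_bp)
        contexts[locus.locus_id] = GenomicContext(
            gc_pct=flank_features.gc_window(locus, genome, config.gc_window_bp),
            gene_count_2mb=count,
            genes_per_mb=per_mb,
            genic_class=flank_features.genic_context(locus, genes),
        )
    return tsds, contexts


@_stage("subfamily")
def _subfamily_calls(config, loci, consensuses):
    calls = {}
    for locus in loci:
        if locus.classification == "full_length":
            if locus.ltr5_low_quality or locus.ltr3_low_quality:
                continue
            calls[locus.locus_id] = detect_chimera(locus, consensuses, config.margin_min)
        elif locus.classification == "solo_ltr" and locus.solo_seq:
            call = assign_subfamily(locus.solo_seq, consensuses)
            calls[locus.locus_id] = SubfamilyCall(call, None, call.name, False)
    return calls


@_stage("dating")
def _dating(config, loci):
    ages = {}
    for locus in loci:
        if locus.classification != "full_length":
            continue
        if not locus.ltr5_seq or not locus.ltr3_seq:
            continue
        if locus.ltr5_low_quality or locus.ltr3_low_quality:
            continue
        try:
            s5, s3 = _pair_align(locus.ltr5_seq, locus.ltr3_seq)
            P, Q, d = dating_phylo.k2p_distance(s5, s3)
        except ValueError as exc:
            logger.warning("dating skipped for %s: %s", locus.locus_id, exc)
            continue
        ages[locus.locus_id] = AgeEstimate(P, Q, d, config.mu)
    return ages


def _pair_align(seq1: str, seq2: str) -> tuple[str, str]:
    if len(seq1) == len(seq2):
        return seq1, seq2
    from ervpipe.subfamily import _ALIGNER

    aln = _ALIGNER.align(seq1, seq2)[0]
    return str(aln[0]), str(aln[1])


@_stage("subfamily_ages")
def _subfamily_ages(config, loci, calls, outdir):
    groups: dict[str, dict[str, str]] = {}
    for locus in loci:
        call = calls.get(locus.locus_id)
        if call is None or call.chimeric:
            continue
        name = call.locus_subfamily
        if name == "unassigned":
            continue
        bucket = groups.setdefault(name, {})
        if locus.classification == "full_length":
            bucket[f"{locus.locus_id}_5"] = locus.ltr5_seq
            bucket[f"{locus.locus_id}_3"] = locus.ltr3_seq
        elif locus.solo_seq:
            bucket[locus.locus_id] = locus.solo_seq
    subfamily_ages = {}
    excluded: dict[str, list[str]] = {}
    for name, seqs in sorted(groups.items()):
        if len(seqs) < 3:
            continue
        msa, dropped = build_subfamily_msa(seqs, config.max_deletion)
        excluded[name] = dropped
        io_formats.write_fasta(msa, Path(outdir) / f"msa_{name}.afa")
        if len(msa) >= 3:
            subfamily_ages[name] = round(
                dating_phylo.subfamily_age(list(msa.values()), config.mu), 4
            )
    return subfamily_ages, excluded


@_stage("phylogeny")
def _phylogeny(config, loci, outdir):
    seqs = {}
    for locus in loci:
        if locus.classification != "full_length":
            continue
        if locus.ltr5_low_quality or locus.ltr3_low_quality:
            continue
        if locus.ltr5_seq:
            seqs[f"{locus.locus_id}_5"] = locus.ltr5_seq
        if locus.ltr3_seq:
            seqs[f"{locus.locus_id}_3"] = locus.ltr3_seq
    if len(seqs) < 3:
        return None
    msa, _ = build_subfamily_msa(seqs, max_deletion=10**9)  # keep all for the tree
    labels = list(msa)
    aligned = [msa[k] for k in labels]
    dm = dating_phylo.k2p_matrix(aligned)
    _write_matrix(labels, dm, Path(outdir) / "ltr_distances.tsv")
    tree, _ = dating_phylo.bootstrap_supports(
        labels, aligned, n_reps=config.bootstrap_reps, seed=config.seed
    )
    newick_path = Path(outdir) / "ltr_tree.nwk"
    tree.write(str(newick_path))
    return newick_path


def _write_matrix(labels, dm, path):
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lbl, row in zip(labels, dm):
            fh.write(lbl + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


@_stage("structure_scan")
def _structures(config, loci, genome):
    out = {}
    for locus in loci:
        if locus.classification != "full_length":
            continue
        out[locus.locus_id] = structure_scan.scan_structure(locus, genome)
    return out


def _count_classes(loci) -> dict:
    counts = {"full_length": 0, "solo_ltr": 0, "truncated": 0}
    for locus in loci:
        counts[locus.classification] += 1
    return counts


def _summary(config, loci, calls, ages, tsds, contexts, structures, subfamily_ages, excluded):
    n_class = _count_classes(loci)
    per_subfamily: dict[str, dict] = {}
    chimeric_loci = []
    for locus in loci:
        call = calls.get(locus.locus_id)
        if call is None:
            continue
        if call.chimeric:
            chimeric_loci.append(locus.locus_id)
            continue
        name = call.locus_subfamily
        entry = per_subfamily.setdefault(
            name, {"n_full_length": 0, "n_solo_ltr": 0, "_lens": []}
        )
        if locus.classification == "full_length":
            entry["n_full_length"] += 1
            entry["_lens"] += [len(s) for s in (locus.ltr5_seq, locus.ltr3_seq) if s]
        elif locus.classification == "solo_ltr":
            entry["n_solo_ltr"] += 1
            if locus.solo_seq:
                entry["_lens"].append(len(locus.solo_seq))
    for entry in per_subfamily.values():
        lens = entry.pop("_lens")
        entry["copy_number"] = entry["n_full_length"] + entry["n_solo_ltr"]
        entry["mean_ltr_len"] = round(float(np.mean(lens)), 1) if lens else None

    gcs = [c.gc_pct for c in contexts.values() if c.gc_pct is not None]
    densities = [c.genes_per_mb for c in contexts.values()]
    genic = {"intergenic": 0, "intronic": 0, "exonic": 0}
    for c in contexts.values():
        genic[c.genic_class] += 1
    n_ctx = max(len(contexts), 1)
    tsd_found = sum(1 for t in tsds.values() if t.is_match)
    gag_states = {"intact": 0, "frameshifted": 0, "absent": 0}
    for rep in structures.values():
        gag_states[rep.gag_state] += 1

    return {
        "total_loci": len(loci),
        "class_counts": n_class,
        "n_analyzed": n_class["full_length"] + n_class["solo_ltr"],
        "subfamilies": per_subfamily,
        "chimeric_loci": sorted(chimeric_loci),
        "subfamily_age_myr": subfamily_ages,
        "mean_insertion_age_myr": (
            round(float(np.mean([a.age_myr for a in ages.values()])), 4) if ages else None
        ),
        "mean_flank_gc_pct": round(float(np.mean(gcs)), 2) if gcs else None,
        "mean_genes_per_mb": round(float(np.mean(densities)), 2) if densities else None,
        "genic_class_pct": {k: round(100.0 * v / n_ctx, 1) for k, v in genic.items()},
        "tsd_detected": tsd_found,
        "gag_states": gag_states,
        "pbs_found": sum(1 for rep in structures.values() if rep.pbs_found),
        "ppt_found": sum(1 for rep in structures.values() if rep.ppt_found),
        "excluded_from_msa": {k: sorted(v) for k, v in excluded.items()},
        "parameters": dataclasses.asdict(config),
    }
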