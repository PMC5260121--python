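"""LTR subfamily assignment, chimera detection, and diagnostic segments.

Each LTR is assigned to the closest subfamily consensus by end-gap-free
global alignment identity.  A full-length provirus whose 5' and 3' LTRs
confidently match *different* consensuses is a chimeric recombinant — the
signature of template switching between co-packaged genomes.  Diagnostic
segments are runs of alignment columns whose per-subfamily majority states
split the subfamilies into groups, recovering insertion/deletion blocks
that are private to a subfamily or shared by a subset.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import Align, SeqIO

from ervpipe.locus_builder import ERVLocus

UNASSIGNED_THRESHOLD = 0.5
DEFAULT_MARGIN_MIN = 0.02


@dataclass(frozen=True)
class SubfamilyConsensus:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty consensus sequence for {self.name}")


@dataclass(frozen=True)
class LTRCall:
    """Best consensus for one LTR: name, identity distance, margin to runner-up."""

    name: str
    distance: float
    margin: float
    runner_up: str | None = None


@dataclass(frozen=True)
class SubfamilyCall:
    ltr5_best: LTRCall | None
    ltr3_best: LTRCall | None
    locus_subfamily: str
    chimeric: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class DiagnosticSegment:
    """A run of MSA columns partitioning the subfamilies.

    ``present_in`` is the (strict, non-empty) subset of subfamilies carrying
    the non-gap/derived state over columns [start, end).
    """

    msa_cols: tuple[int, int]
    present_in: frozenset
    segment_seq: str


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    # stiff gap costs: spurious gapped matches between unrelated sequences
    # would otherwise inflate identity well above the background 25%
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    # end gaps free: LTR edges are length-variable
    aligner.end_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def alignment_identity_distance(seq: str, consensus: str, min_span_frac: float = 0.5) -> float:
    """1 - identity over aligned columns, terminal end-gap columns excluded.

    Unrelated sequences under free end gaps optimize to a tiny high-identity
    overlap; an aligned span shorter than ``min_span_frac`` of the shorter
    sequence is therefore reported as maximally distant.
    """
    aln = _ALIGNER.align(seq.upper(), consensus.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    # score columns between the first and last position where both have residues
    first = next((k for k in range(len(s1)) if s1[k] != "-" and s2[k] != "-"), None)
    last = next((k for k in range(len(s1) - 1, -1, -1) if s1[k] != "-" and s2[k] != "-"), None)
    if first is None:
        return 1.0
    ncols = last + 1 - first
    if ncols < min_span_frac * min(len(seq), len(consensus)):
        return 1.0
    cols = range(first, last + 1)
    matches = sum(1 for k in cols if s1[k] == s2[k] and s1[k] != "-")
    return 1.0 - matches / ncols


def assign_subfamily(
    ltr_seq: str,
    consensuses: Sequence[SubfamilyConsensus],
    unassigned_threshold: float = UNASSIGNED_THRESHOLD,
) -> LTRCall:
    """Assign one LTR to its closest subfamily consensus.

    Distance is 1 - identity over aligned columns of an end-gap-free global
    alignment; the margin is the runner-up distance minus the best.  If
    every distance exceeds ``unassigned_threshold`` the call is
    ``unassigned``.
    """
    if len(consensuses) < 2:
        raise ValueError("need >= 2 consensuses for an informative assignment")
    dists = sorted(
        ((alignment_identity_distance(ltr_seq, c.sequence), c.name) for c in consensuses),
    )
    (best_d, best_name), (second_d, second_name) = dists[0], dists[1]
    if best_d > unassigned_threshold:
        return LTRCall("unassigned", best_d, 0.0, None)
    return LTRCall(best_name, best_d, second_d - best_d, second_name)


def detect_chimera(
    locus: ERVLocus,
    consensuses: Sequence[SubfamilyConsensus],
    margin_min: float = DEFAULT_MARGIN_MIN,
) -> SubfamilyCall:
    """Call the subfamily of a full-length locus and flag chimeric LTR pairs.

    Chimeric iff the two LTRs' best consensuses differ and each call's
    margin is at least ``margin_min``.  Discordant calls below the margin
    are resolved toward the 5' LTR and flagged; an unassigned LTR yields a
    non-chimeric call flagged ``partial``.
    """
    if locus.classification != "full_length":
        raise ValueError("chimera detection applies to full-length loci")
    if not locus.ltr5_seq or not locus.ltr3_seq:
        raise ValueError("locus LTR sequences not extracted")
    call5 = assign_subfamily(locus.ltr5_seq, consensuses)
    call3 = assign_subfamily(locus.ltr3_seq, consensuses)
    flags: list[str] = []
    if call5.name == "unassigned" or call3.name == "unassigned":
        assigned = call5 if call5.name != "unassigned" else call3
        return SubfamilyCall(call5, call3, assigned.name, False, ("partial",))
    if call5.name != call3.name:
        if call5.margin >= margin_min and call3.margin >= margin_min:
            return SubfamilyCall(call5, call3, "chimeric", True, ())
        flags.append("discordant_low_margin")
        return SubfamilyCall(call5, call3, call5.name, False, tuple(flags))
    return SubfamilyCall(call5, call3, call5.name, False, ())


def build_subfamily_msa(
    ltr_seqs: Mapping[str, str],
    max_deletion: int = 50,
    mafft_path: str | None = None,
) -> tuple[dict[str, str], list[str]]:
    """Progressively align LTR sequences; exclude heavily deleted copies.

    Sequences more than ``max_deletion`` bp shorter than the median length
    are excluded before alignment (they cannot be aligned reliably) and
    returned in the exclusion list.  Alignment is delegated to mafft
    (progressive, distance-based guide tree).  Requires >= 2 sequences
    after filtering.
    """
    if len(ltr_seqs) < 2:
        raise ValueError("insufficient sequences: need >= 2")
    lengths = sorted(len(s) for s in ltr_seqs.values())
    median = lengths[len(lengths) // 2]
    kept = {k: v for k, v in ltr_seqs.items() if len(v) >= median - max_deletion}
    excluded = [k for k in ltr_seqs if k not in kept]
    if len(kept) < 2:
        raise ValueError("insufficient sequences after deletion filter")

    exe = mafft_path or shutil.which("mafft")
    if exe is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fa"
        with open(fin, "w") as fh:
            for name, seq in kept.items():
                fh.write(f">{name}\n{seq}\n")
        result = subprocess.run(
            [exe, "--quiet", "--retree", "2", str(fin)],
            capture_output=True,
            text=True,
            check=True,
        )
        msa = {}
        name = None
        for line in result.stdout.splitlines():
            if line.startswith(">"):
                name = line[1:].split()[0]
                msa[name] = []
            elif name is not None:
                msa[name].append(line.strip())
    aligned = {k: "".join(v).upper() for k, v in msa.items()}
    # mafft preserves input order; re-key in original order for determinism
    return {k: aligned[k] for k in kept}, excluded


def find_diagnostic_segments(
    msa: Mapping[str, str],
    labels: Mapping[str, str],
    min_len: int = 10,
    min_agreement: float = 0.8,
) -> list[DiagnosticSegment]:
    """Find maximal runs of columns that partition the subfamilies.

    A column is informative when every subfamily's rows agree on a majority
    state (gap counts as a state) at >= ``min_agreement``, and those
    majority states split the subfamilies into >= 2 groups.  Maximal runs of
    >= ``min_len`` informative columns sharing the same partition become
    segments.  ``present_in`` is the union of non-gap groups when some
    group's state is a gap (an insertion private to those subfamilies),
    otherwise the smallest group (the derived state).

    Rows are de-duplicated within each subfamily first, so the result is
    invariant to row order and to duplicating any row.
    """
    subfams = sorted(set(labels.values()))
    if len(subfams) < 2:
        return []
    rows_by_subfam: dict[str, list[str]] = {}
    for row_name, seq in msa.items():
        sf = labels.get(row_name)
        if sf is None:
            continue
        bucket = rows_by_subfam.setdefault(sf, [])
        if seq not in bucket:  # duplicate rows carry no extra information
            bucket.append(seq)
    subfams = sorted(rows_by_subfam)
    ncols = len(next(iter(msa.values())))

    arrays = {sf: np.array([list(s.upper()) for s in rows]) for sf, rows in rows_by_subfam.items()}

    signatures: list[tuple | None] = []
    majorities: list[dict[str, str] | None] = []
    for j in range(ncols):
        maj: dict[str, str] = {}
        ok = True
        for sf in subfams:
            col = arrays[sf][:, j]
            vals, counts = np.unique(col, return_counts=True)
            order = np.lexsort((vals, -counts))
            top, top_count = vals[order[0]], counts[order[0]]
            if top_count / len(col) < min_agreement:
                ok = False
                break
            maj[sf] = str(top)
        if not ok:
            signatures.append(None)
            majorities.append(None)
            continue
        groups: dict[str, list[str]] = {}
        for sf in subfams:
            groups.setdefault(maj[sf], []).append(sf)
        if len(groups) < 2:
            signatures.append(None)
            majorities.append(None)
            continue
        partition = frozenset(frozenset(g) for g in groups.values())
        gap_groups = frozenset(frozenset(g) for state, g in groups.items() if state == "-")
        signatures.append((partition, gap_groups))
        majorities.append(maj)

    segments: list[DiagnosticSegment] = []
    j = 0
    while j < ncols:
        if signatures[j] is None:
            j += 1
            continue
        k = j
        while k < ncols and signatures[k] == signatures[j]:
            k += 1
        if k - j >= min_len:
            partition, gap_groups = signatures[j]
            non_gap = [g for g in partition if g not in gap_groups]
            if gap_groups and non_gap:
                present = frozenset().union(*non_gap)
            else:
                present = min(partition, key=lambda g: (len(g), tuple(sorted(g))))
            seq_chars = []
            for col in range(j, k):
                maj = majorities[col]
                states = [maj[sf] for sf in sorted(present)]
                state = max(sorted(set(states)), key=states.count)
                if state != "-":
                    seq_chars.append(state)
            segments.append(
                DiagnosticSegment((j, k), frozenset(present), "".join(seq_chars))
            )
        j = k
    return segments


def read_consensus_fasta(path) -> list[SubfamilyConsensus]:
    """Load subfamily LTR consensuses from FASTA."""
    return [
        SubfamilyConsensus(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]
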