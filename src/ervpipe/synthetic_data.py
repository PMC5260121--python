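"""Synthetic genomes with planted ERV loci and full ground truth.

The generator emulates the study system: a bird-sized genome background at
41% GC carrying five LTR-retrovirus subfamilies (consensus LTR lengths 295,
382, 329, 336 and 332 nt, all framed by the TGTTG...CAACA terminal motifs,
one carrying a private 24-nt tandem duplication), planted as full-length
proviruses, solo-LTRs (recombination remnants) and truncated copies, each
with a duplicated target site.  LTR pairs diverge by independent Poisson
substitution at a per-site rate mu per myr with a transition bias, so every
dating estimator can be validated against the planted ages.  Defaults mirror
the reference census: 49 full-length (two of them chimeric), 483 solo-LTRs,
61 truncated; gag/pbs structure states 31 intact, 15 frameshifted, 3
pbs-deficient.

Evolution is substitution-only by default (keeps the dating model exact);
an optional indel mode exercises the heavy-deletion exclusion filter.
Planted diagnostic features (pbs, PPT, reading-frame state) are protected
from mutation so the recorded truth stays valid at any age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ervpipe.io_formats import GeneModel, RepeatHit, write_fasta, write_rmsk
from ervpipe.locus_builder import reverse_complement
from ervpipe.structure_scan import (
    DEFAULT_PBS_MOTIFS,
    StructureParams,
    _gag_state,
    find_orfs,
)
from ervpipe.subfamily import SubfamilyConsensus

BASES = "ACGT"
SUBFAMILIES = ("GGERV10A", "GGERV10B", "GGERV10C1", "GGERV10C2", "GGERV10D")
LTR_LENGTHS = {
    "GGERV10A": 295,
    "GGERV10B": 382,
    "GGERV10C1": 329,
    "GGERV10C2": 336,
    "GGERV10D": 332,
}
#: the 24-nt block tandem-duplicated in the GGERV10A-like consensus
DUPLICATED_BLOCK = "GCGTAGCGAGGGAAACGAGGTGTG"

# reference census used for the default event mix
TABLE_FULL = {"GGERV10A": 7, "GGERV10B": 12, "GGERV10C1": 6, "GGERV10C2": 9, "GGERV10D": 13}
TABLE_SOLO = {"GGERV10A": 20, "GGERV10B": 12, "GGERV10C1": 111, "GGERV10C2": 241, "GGERV10D": 99}
TABLE_TRUNCATED = {"GGERV10A": 3, "GGERV10B": 3, "GGERV10C1": 13, "GGERV10C2": 29, "GGERV10D": 13}
CHIMERIC_PAIRS = (("GGERV10D", "GGERV10B"), ("GGERV10C2", "GGERV10C1"))
COPY_WEIGHTS = {"GGERV10A": 27, "GGERV10B": 25, "GGERV10C1": 117, "GGERV10C2": 251, "GGERV10D": 112}

INTERNAL_LEN = 3000
ORF_START = 240
ORF_CODONS = 450
PBS_OFFSET = 3
PPT_START_FROM_END = 22  # 13-purine tract planted at [-22, -9)
PPT_LEN = 13

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class SimConfig:
    """Generator configuration; the defaults are the study conditions."""

    n_chroms: int = 4
    chrom_len: int = 10_000_000
    background_gc: float = 0.41
    counts: dict = field(
        default_factory=lambda: {
            "full_length": sum(TABLE_FULL.values()),
            "solo_ltr": sum(TABLE_SOLO.values()),
            "truncated": sum(TABLE_TRUNCATED.values()),
            "chimeric": len(CHIMERIC_PAIRS),
        }
    )
    subfamily_weights: dict = field(default_factory=lambda: dict(COPY_WEIGHTS))
    subfamily_ages: dict = field(
        default_factory=lambda: {
            "GGERV10A": 6.0,
            "GGERV10B": 3.7,
            "GGERV10C1": 5.0,
            "GGERV10C2": 4.5,
            "GGERV10D": 5.5,
        }
    )
    age_spread: float = 0.5  # uniform +/- fraction around the subfamily mean
    mu: float = 0.0019
    ts_tv_ratio: float = 2.0
    tsd_len_range: tuple = (4, 6)
    gene_rate_per_mb: float = 3.8
    gene_len_range: tuple = (5_000, 30_000)
    structure_counts: dict = field(
        default_factory=lambda: {"intact": 31, "frameshifted": 15, "pbs_deficient": 3}
    )
    indel_rate: float = 0.0  # per-site indel probability (0 = substitution-only)
    min_gap_bp: int = 1_000
    edge_margin_bp: int | None = None  # None: min(1_001_000, chrom_len // 5)
    seed: int = 0

    def margin(self) -> int:
        if self.edge_margin_bp is not None:
            return self.edge_margin_bp
        return min(1_001_000, self.chrom_len // 5)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one planted event (final genome coordinates)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    event_type: str  # full_length | solo_ltr | truncated | chimeric
    subfamily_5: str
    subfamily_3: str
    true_age_myr: float
    tsd_seq: str
    gag_state: str  # intact | frameshifted | absent | NA
    pbs_present: bool

    @property
    def expected_class(self) -> str:
        if self.event_type in {"full_length", "chimeric"}:
            return "full_length"
        return self.event_type

    @property
    def subfamily(self) -> str:
        if self.subfamily_5 != self.subfamily_3:
            return f"{self.subfamily_5}/{self.subfamily_3}"
        return self.subfamily_5


@dataclass
class ConsensusSet:
    ltr_consensuses: list[SubfamilyConsensus]
    internal: str
    pbs_motif: str = DEFAULT_PBS_MOTIFS[0]

    def by_name(self) -> dict[str, str]:
        return {c.name: c.sequence for c in self.ltr_consensuses}


@dataclass
class SimResult:
    config: SimConfig
    genome: dict
    truths: list
    hits: list
    genes: list
    consensus_set: ConsensusSet


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    edges = np.cumsum(_base_probs(gc))[:3]
    codes = np.searchsorted(edges, rng.random(length)).astype(np.uint8)
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def _substitute_base(base: str, rng: np.random.Generator, ts_tv_ratio: float) -> str:
    code = BASES.index(base)
    if rng.random() < ts_tv_ratio / (ts_tv_ratio + 1.0):
        return BASES[code ^ 2]  # transition partner
    return BASES[code ^ (1 if rng.random() < 0.5 else 3)]


def mutate_sequence(
    seq: str,
    p_site: float,
    rng: np.random.Generator,
    ts_tv_ratio: float = 2.0,
    protected: Sequence[tuple[int, int]] = (),
    orf_interval: tuple[int, int] | None = None,
) -> tuple[str, int]:
    """Apply Poisson(p_site * len) substitutions; returns (seq, n_applied).

    Sites inside ``protected`` intervals are skipped.  Inside
    ``orf_interval`` (frame 0 relative to its start) substitutions that
    would create a stop codon are skipped, emulating the constraint that a
    planted intact reading frame stays open.
    """
    n = rng.poisson(p_site * len(seq))
    if n == 0:
        return seq, 0
    n = min(n, len(seq))
    sites = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    applied = 0
    for site in sites:
        if any(lo <= site < hi for lo, hi in protected):
            continue
        if chars[site] not in BASES:
            continue
        new = _substitute_base(chars[site], rng, ts_tv_ratio)
        if orf_interval is not None:
            lo, hi = orf_interval
            if lo <= site < hi:
                codon_start = lo + ((site - lo) // 3) * 3
                codon = chars[codon_start : codon_start + 3]
                codon[site - codon_start] = new
                if "".join(codon) in STOP_CODONS:
                    continue
        chars[site] = new
        applied += 1
    return "".join(chars), applied


def _apply_indels(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Optional geometric-length indels (mean 8 nt), used to exercise filters."""
    if rate <= 0:
        return seq
    n = rng.poisson(rate * len(seq))
    for _ in range(n):
        pos = int(rng.integers(5, max(6, len(seq) - 5)))
        length = int(rng.geometric(1 / 8.0))
        if rng.random() < 0.5:
            seq = seq[:pos] + seq[pos + length :]
        else:
            seq = seq[:pos] + _random_seq(rng, length, 0.41) + seq[pos:]
    return seq


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = _random_seq(rng, 3, gc)
        if codon not in STOP_CODONS:
            return codon


def make_consensus_set(seed: int = 0) -> ConsensusSet:
    """Build the five synthetic subfamily LTR consensuses plus the internal.

    LTR consensuses diverge 5-15% pairwise from a shared ancestor, all start
    TGTTG and end CAACA, and the GGERV10A-like one carries a tandem 24-nt
    duplication absent elsewhere.  The internal consensus carries a pbs
    motif 3 nt after the 5' LTR, a 450-codon open reading frame starting in
    the 5' third, and a 13-purine polypurine tract just before the 3' LTR.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    gc = 0.41
    ancestor = _random_seq(rng, 340, gc)
    rates = {
        "GGERV10A": 0.045,
        "GGERV10B": 0.055,
        "GGERV10C1": 0.035,
        "GGERV10C2": 0.050,
        "GGERV10D": 0.065,
    }
    consensuses = []
    for name in SUBFAMILIES:
        seq, _ = mutate_sequence(ancestor, rates[name], rng)
        target = LTR_LENGTHS[name]
        if name == "GGERV10A":
            # plant the tandem 24-nt duplication before resizing
            pos = 150
            seq = seq[:pos] + DUPLICATED_BLOCK + DUPLICATED_BLOCK + seq[pos:]
        delta = target - len(seq)
        if delta > 0:
            pos = int(rng.integers(30, len(seq) - 30))
            seq = seq[:pos] + _random_seq(rng, delta, gc) + seq[pos:]
        elif delta < 0:
            # delete outside the duplicated block
            lo, hi = (220, len(seq) - 30) if name == "GGERV10A" else (30, len(seq) - 30)
            pos = int(rng.integers(lo, hi + delta))
            seq = seq[:pos] + seq[pos - delta :]
        seq = "TGTTG" + seq[5:-5] + "CAACA"
        assert len(seq) == target
        consensuses.append(SubfamilyConsensus(name, seq))

    internal = list(_random_seq(rng, INTERNAL_LEN, gc))
    pbs = DEFAULT_PBS_MOTIFS[0]
    internal[PBS_OFFSET : PBS_OFFSET + len(pbs)] = pbs
    orf = ["ATG"] + [_random_codon(rng, gc) for _ in range(ORF_CODONS - 2)] + ["TAA"]
    internal[ORF_START : ORF_START + 3 * ORF_CODONS] = "".join(orf)
    ppt = "".join(rng.choice(["A", "G"], size=PPT_LEN))
    lo = INTERNAL_LEN - PPT_START_FROM_END
    internal[lo : lo + PPT_LEN] = ppt
    return ConsensusSet(consensuses, "".join(internal))


def evolve_ltr_pair(
    consensus: str | SubfamilyConsensus,
    age_myr: float,
    mu: float = 0.0019,
    ts_tv_ratio: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> tuple[str, str]:
    """Evolve a 5'/3' LTR pair independently from one consensus.

    Each LTR receives Poisson(mu * age * len) substitutions, so the
    expected pairwise divergence is about 2 * mu * age.
    """
    if age_myr < 0:
        raise ValueError("age_myr must be >= 0")
    seq = consensus.sequence if isinstance(consensus, SubfamilyConsensus) else consensus
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ltr5, _ = mutate_sequence(seq, mu * age_myr, rng, ts_tv_ratio)
    ltr3, _ = mutate_sequence(seq, mu * age_myr, rng, ts_tv_ratio)
    return ltr5, ltr3


# ----------------------------------------------------------------- internal engineering


def _engineer_frameshift(internal: str, rng: np.random.Generator) -> str:
    """Insert one base mid-gag so the frame splits into two sub-ORFs."""
    orf_end = ORF_START + 3 * ORF_CODONS
    x = ORF_START + 3 * int(rng.integers(int(0.45 * ORF_CODONS), int(0.60 * ORF_CODONS)))
    ins = BASES[int(rng.integers(4))]
    return internal[:x] + ins + internal[x:]


def _engineer_absent(internal: str, rng: np.random.Generator) -> str:
    """Pepper the gag frame with stops: no qualifying ORF survives."""
    chars = list(internal)
    stop_choices = sorted(STOP_CODONS)
    for k in range(0, ORF_CODONS, 80):
        pos = ORF_START + 3 * k
        chars[pos : pos + 3] = stop_choices[int(rng.integers(3))]
    return "".join(chars)


def _scramble_pbs(internal: str, rng: np.random.Generator, motif: str) -> str:
    while True:
        repl = _random_seq(rng, len(motif), 0.41)
        mism = sum(a != b for a, b in zip(repl, motif))
        if mism > 2:
            return internal[:PBS_OFFSET] + repl + internal[PBS_OFFSET + len(motif) :]


def _build_internal(
    cs: ConsensusSet,
    gag_state: str,
    pbs_present: bool,
    age_myr: float,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> str:
    """Engineer the planted structure state, then evolve with protections."""
    params = StructureParams()
    for _ in range(50):
        internal = cs.internal
        if not pbs_present:
            internal = _scramble_pbs(internal, rng, cs.pbs_motif)
        orf_end = ORF_START + 3 * ORF_CODONS
        if gag_state == "frameshifted":
            internal = _engineer_frameshift(internal, rng)
            orf_end += 1
        elif gag_state == "absent":
            internal = _engineer_absent(internal, rng)

        protected = [
            (0, PBS_OFFSET + len(cs.pbs_motif)),
            (len(internal) - 30, len(internal)),
        ]
        if gag_state == "intact":
            orf_interval = (ORF_START, orf_end)
        else:
            # keep the engineered frame structure fixed under evolution
            protected.append((ORF_START - 3, orf_end + 90))
            orf_interval = None
        internal, _ = mutate_sequence(
            internal, cfg.mu * age_myr, rng, cfg.ts_tv_ratio, protected, orf_interval
        )
        orfs = find_orfs(internal, params.min_codons)
        realized = _gag_state(orfs, len(internal), params)
        if realized == gag_state:
            return internal
    raise RuntimeError(f"could not engineer gag state {gag_state!r}")


# ----------------------------------------------------------------- event planning


def _allocate(total: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of ``total`` items across weights."""
    names = sorted(weights)
    wsum = sum(weights[n] for n in names)
    raw = {n: total * weights[n] / wsum for n in names}
    counts = {n: int(raw[n]) for n in names}
    remainder = total - sum(counts.values())
    order = sorted(names, key=lambda n: (counts[n] - raw[n], n))
    for n in order[:remainder]:
        counts[n] += 1
    return counts


def _plan_events(cfg: SimConfig, rng: np.random.Generator) -> list[dict]:
    """Decide subfamily, age, strand, structure state for every event."""
    counts = dict(cfg.counts)
    events: list[dict] = []

    def subfam_alloc(total: int, table: Mapping[str, int]) -> dict[str, int]:
        if total == sum(table.values()):
            return dict(table)
        return _allocate(total, cfg.subfamily_weights)

    for sf, k in subfam_alloc(counts.get("full_length", 0), TABLE_FULL).items():
        events += [{"event_type": "full_length", "sf5": sf, "sf3": sf} for _ in range(k)]
    n_chim = counts.get("chimeric", 0)
    for i in range(n_chim):
        sf5, sf3 = CHIMERIC_PAIRS[i % len(CHIMERIC_PAIRS)]
        events.append({"event_type": "chimeric", "sf5": sf5, "sf3": sf3})
    for sf, k in subfam_alloc(counts.get("solo_ltr", 0), TABLE_SOLO).items():
        events += [{"event_type": "solo_ltr", "sf5": sf, "sf3": sf} for _ in range(k)]
    for sf, k in subfam_alloc(counts.get("truncated", 0), TABLE_TRUNCATED).items():
        events += [{"event_type": "truncated", "sf5": sf, "sf3": sf} for _ in range(k)]

    # gag/pbs structure states for proviruses (full-length + chimeric)
    proviruses = [e for e in events if e["event_type"] in {"full_length", "chimeric"}]
    states = []
    alloc = _allocate(len(proviruses), cfg.structure_counts) if proviruses else {}
    for state, k in sorted(alloc.items()):
        states += [state] * k
    rng.shuffle(states)
    for event, state in zip(proviruses, states):
        if state == "pbs_deficient":
            event["gag_state"], event["pbs_present"] = "intact", False
        else:
            event["gag_state"], event["pbs_present"] = state, True

    for event in events:
        mean_age = cfg.subfamily_ages[event["sf3"]]
        lo, hi = mean_age * (1 - cfg.age_spread), mean_age * (1 + cfg.age_spread)
        event["age"] = float(rng.uniform(lo, hi))
        event["strand"] = "+" if rng.random() < 0.5 else "-"
        event["tsd_len"] = int(rng.integers(cfg.tsd_len_range[0], cfg.tsd_len_range[1] + 1))
        if event["event_type"] == "truncated":
            event["trunc_kind"] = ["ltr_int", "int_ltr", "int_only"][int(rng.integers(3))]
    rng.shuffle(events)
    return events


# ----------------------------------------------------------------- sequence assembly


def _build_event_sequence(
    event: dict, cs: ConsensusSet, cfg: SimConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[str, str, int, int, int]]]:
    """Element sequence (element orientation) + component layout.

    Layout entries are (repeat_name, kind, offset, length, n_sub) with
    offsets relative to the element start.
    """
    by_name = cs.by_name()
    etype = event["event_type"]
    parts: list[tuple[str, str, str]] = []  # (repeat_name, kind, seq)

    def evolved_ltr(sf: str) -> tuple[str, str]:
        seq, _ = mutate_sequence(by_name[sf], cfg.mu * event["age"], rng, cfg.ts_tv_ratio)
        seq = _apply_indels(seq, cfg.indel_rate, rng)
        return f"{sf}-LTR", seq

    if etype in {"full_length", "chimeric"}:
        name5, ltr5 = evolved_ltr(event["sf5"])
        name3, ltr3 = evolved_ltr(event["sf3"])
        internal = _build_internal(
            cs, event["gag_state"], event["pbs_present"], event["age"], cfg, rng
        )
        parts = [
            (name5, "LTR", ltr5),
            (f"{event['sf3']}-int", "INTERNAL", internal),
            (name3, "LTR", ltr3),
        ]
    elif etype == "solo_ltr":
        name, ltr = evolved_ltr(event["sf5"])
        parts = [(name, "LTR", ltr)]
    else:  # truncated
        internal = _build_internal(cs, "intact", True, event["age"], cfg, rng)
        name, ltr = evolved_ltr(event["sf5"])
        kind = event["trunc_kind"]
        if kind == "ltr_int":
            parts = [(name, "LTR", ltr), (f"{event['sf5']}-int", "INTERNAL", internal)]
        elif kind == "int_ltr":
            parts = [(f"{event['sf5']}-int", "INTERNAL", internal), (name, "LTR", ltr)]
        else:
            parts = [(f"{event['sf5']}-int", "INTERNAL", internal)]

    layout = []
    offset = 0
    for repeat_name, kind, seq in parts:
        layout.append((repeat_name, kind, offset, len(seq)))
        offset += len(seq)
    element = "".join(seq for _, _, seq in parts)
    return element, layout


def _place_positions(
    n: int, sizes: Sequence[int], usable_lo: int, usable_hi: int, min_gap: int, rng
) -> list[int]:
    """Non-overlapping insertion points with at least ``min_gap`` spacing."""
    total = sum(sizes) + (n - 1) * min_gap if n else 0
    free = (usable_hi - usable_lo) - total
    if n and free <= 0:
        raise RuntimeError("cannot place events: genome too crowded")
    offsets = np.sort(rng.uniform(0, free, size=n))
    positions = []
    acc = usable_lo
    for i in range(n):
        positions.append(int(acc + offsets[i]))
        acc += sizes[i] + min_gap
    return positions


def _tsd_is_ambiguous(bg: str, p: int, k: int, kmax: int = 8) -> bool:
    s = bg[p : p + k]
    if "N" in s:
        return True
    for k2 in range(k + 1, kmax + 1):
        left = bg[p - (k2 - k) : p] + s
        right = s + bg[p + k : p + k2]
        if left == right:
            return True
    return False


def simulate_genome(cfg: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Generate a genome with planted ERV events, annotation and truth.

    Returns the in-memory result; if ``outdir`` is given, also writes
    genome FASTA, truth TSV, annotation in both rmsk dialects, gene BED and
    the consensus FASTAs.  Byte-identical outputs for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    cs = make_consensus_set(cfg.seed)
    events = _plan_events(cfg, rng)

    # round-robin split across chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    per_chrom: dict[str, list[dict]] = {c: [] for c in chrom_names}
    for i, event in enumerate(events):
        per_chrom[chrom_names[i % cfg.n_chroms]].append(event)

    genome: dict[str, str] = {}
    truths: list[SimTruth] = []
    hits: list[RepeatHit] = []
    genes: list[GeneModel] = []
    margin = cfg.margin()
    locus_counter = 0
    linkage_counter = 0

    for chrom in chrom_names:
        bg = _random_seq(rng, cfg.chrom_len, cfg.background_gc)
        chrom_events = per_chrom[chrom]

        built = []
        for event in chrom_events:
            element, layout = _build_event_sequence(event, cs, cfg, rng)
            if event["strand"] == "-":
                element_genomic = reverse_complement(element)
            else:
                element_genomic = element
            built.append((event, element_genomic, layout))

        sizes = [len(e) + ev["tsd_len"] for (ev, e, _) in built]
        positions = _place_positions(
            len(built), sizes, margin, cfg.chrom_len - margin, cfg.min_gap_bp, rng
        )

        pieces = []
        prev = 0
        offset = 0
        for (event, element_genomic, layout), p in zip(built, positions):
            k = event["tsd_len"]
            shift = 0
            while _tsd_is_ambiguous(bg, p + shift, k) and shift < cfg.min_gap_bp // 3:
                shift += 11
            p += shift
            tsd = bg[p : p + k]
            pieces.append(bg[prev:p])
            pieces.append(tsd)
            pieces.append(element_genomic)
            prev = p
            start = p + offset + k
            end = start + len(element_genomic)
            offset += len(element_genomic) + k

            locus_id = f"sim_{locus_counter:05d}"
            locus_counter += 1
            linkage_counter += 1
            linkage = str(linkage_counter)

            # component coordinates: layout offsets are in element orientation
            for repeat_name, kind, off, length in layout:
                if event["strand"] == "+":
                    c_start, c_end = start + off, start + off + length
                else:
                    c_end = end - off
                    c_start = c_end - length
                hits.append(
                    RepeatHit(
                        chrom=chrom,
                        start=c_start,
                        end=c_end,
                        strand=event["strand"],
                        repeat_name=repeat_name,
                        repeat_class="LTR/ERVK",
                        consensus_start=0,
                        consensus_end=length,
                        divergence_pct=round(100 * cfg.mu * event["age"], 1),
                        linkage_id=linkage,
                    )
                )

            etype = event["event_type"]
            truths.append(
                SimTruth(
                    locus_id=locus_id,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=event["strand"],
                    event_type=etype,
                    subfamily_5=event["sf5"],
                    subfamily_3=event["sf3"],
                    true_age_myr=round(event["age"], 4),
                    tsd_seq=tsd,
                    gag_state=event.get("gag_state", "NA"),
                    pbs_present=event.get("pbs_present", True),
                )
            )
        pieces.append(bg[prev:])
        genome[chrom] = "".join(pieces)

        # genes: Poisson placement over the final chromosome
        chrom_len = len(genome[chrom])
        n_genes = rng.poisson(cfg.gene_rate_per_mb * chrom_len / 1e6)
        starts = np.sort(rng.integers(0, chrom_len, size=n_genes))
        for gi, gstart in enumerate(starts):
            glen = int(rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1))
            gend = min(int(gstart) + glen, chrom_len)
            if gend - gstart < 100:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(chrom, int(gstart), gend, strand, f"gene_{chrom}_{gi}"))

    result = SimResult(cfg, genome, truths, hits, genes, cs)
    if outdir is not None:
        write_sim_outputs(result, outdir)
    return result


def match_truth(loci: Sequence, truths: Sequence[SimTruth]) -> dict[str, SimTruth]:
    """Map assembled locus ids to planted truth records by exact span."""
    by_span = {(t.chrom, t.start, t.end): t for t in truths}
    return {
        locus.locus_id: by_span[(locus.chrom, locus.start, locus.end)]
        for locus in loci
        if (locus.chrom, locus.start, locus.end) in by_span
    }


TRUTH_COLUMNS = [
    "locus_id",
    "chrom",
    "start",
    "end",
    "strand",
    "event_type",
    "subfamily_5",
    "subfamily_3",
    "true_age_myr",
    "tsd_seq",
    "gag_state",
    "pbs_present",
]


def write_sim_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "truth": outdir / "truth.tsv",
        "rm_out": outdir / "repeats.out",
        "ucsc_rmsk": outdir / "repeats_ucsc.tsv",
        "genes": outdir / "genes.bed",
        "ltr_consensuses": outdir / "ltr_consensuses.fa",
        "internal_consensus": outdir / "internal_consensus.fa",
    }
    write_fasta(result.genome, paths["genome"])
    with open(paths["truth"], "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in result.truths:
            fh.write("\t".join(str(getattr(t, c)) for c in TRUTH_COLUMNS) + "\n")
    write_rmsk(result.hits, paths["rm_out"], "rm_out")
    write_rmsk(result.hits, paths["ucsc_rmsk"], "ucsc_rmsk")
    with open(paths["genes"], "w") as fh:
        for g in result.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    write_fasta(result.consensus_set.by_name(), paths["ltr_consensuses"])
    write_fasta({"internal": result.consensus_set.internal}, paths["internal_consensus"])
    return paths
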