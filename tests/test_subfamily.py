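"""subfamily: consensus assignment, chimera calls, MSA, diagnostic segments."""

import random

import numpy as np
import pytest

from ervpipe.locus_builder import ERVLocus
from ervpipe.subfamily import (
    SubfamilyConsensus,
    assign_subfamily,
    build_subfamily_msa,
    detect_chimera,
    find_diagnostic_segments,
)
from ervpipe.synthetic_data import DUPLICATED_BLOCK, evolve_ltr_pair, mutate_sequence


@pytest.fixture(scope="module")
def consensuses(consensus_set):
    return consensus_set.ltr_consensuses


def full_locus(ltr5, ltr3):
    locus = ERVLocus("L1", "chr1", 0, 1, "+", components=[], classification="full_length")
    locus.ltr5_seq = ltr5
    locus.ltr3_seq = ltr3
    return locus


class TestAssign:
    def test_exact_consensus_has_zero_distance(self, consensuses):
        b = next(c for c in consensuses if c.name == "GGERV10B")
        call = assign_subfamily(b.sequence, consensuses)
        assert call.name == "GGERV10B" and call.distance == 0.0

    def test_mutated_copy_assigned_to_generating_consensus(self, consensuses):
        d = next(c for c in consensuses if c.name == "GGERV10D")
        rng = np.random.default_rng(1)
        seq, _ = mutate_sequence(d.sequence, 0.05, rng)
        call = assign_subfamily(seq, consensuses)
        assert call.name == "GGERV10D" and call.margin > 0

    def test_random_sequence_unassigned(self, consensuses):
        rng = np.random.default_rng(2)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 330)])
        assert assign_subfamily(seq, consensuses).name == "unassigned"

    def test_generating_consensus_is_nearest_up_to_ten_pct_mutation(self, consensuses):
        rng = np.random.default_rng(3)
        violations = 0
        trials = 0
        for cons in consensuses:
            for _ in range(40):
                seq, _ = mutate_sequence(cons.sequence, 0.10, rng)
                trials += 1
                if assign_subfamily(seq, consensuses).name != cons.name:
                    violations += 1
        assert violations / trials <= 0.01


class TestChimera:
    def test_planted_recombinant_detected(self, consensuses):
        by = {c.name: c.sequence for c in consensuses}
        rng = np.random.default_rng(4)
        ltr5, _ = mutate_sequence(by["GGERV10D"], 0.01, rng)
        ltr3, _ = mutate_sequence(by["GGERV10B"], 0.01, rng)
        call = detect_chimera(full_locus(ltr5, ltr3), consensuses)
        assert call.chimeric and call.locus_subfamily == "chimeric"
        assert call.ltr5_best.name == "GGERV10D" and call.ltr3_best.name == "GGERV10B"

    def test_concordant_ltrs_not_chimeric(self, consensuses):
        by = {c.name: c.sequence for c in consensuses}
        ltr5, ltr3 = evolve_ltr_pair(by["GGERV10B"], 3.7, seed=5)
        call = detect_chimera(full_locus(ltr5, ltr3), consensuses)
        assert not call.chimeric and call.locus_subfamily == "GGERV10B"

    def test_low_margin_discordance_resolved_to_five_prime(self):
        # two consensuses differing at 10 known sites; the 3' LTR sits almost
        # exactly between them, so its margin is far below the threshold
        base = list("ACGT" * 75)
        x = "".join(base)
        y_chars = list(base)
        sites = list(range(0, 100, 10))
        for s in sites:
            y_chars[s] = {"A": "G", "C": "T", "G": "A", "T": "C"}[y_chars[s]]
        y = "".join(y_chars)
        cons = [SubfamilyConsensus("X", x), SubfamilyConsensus("Y", y)]
        mid = list(base)
        for s in sites[:6]:  # 6 of 10 toward Y: best=Y, margin 2/300 < 0.02
            mid[s] = y_chars[s]
        call = detect_chimera(full_locus(x, "".join(mid)), cons, margin_min=0.02)
        assert not call.chimeric
        assert call.locus_subfamily == "X"
        assert "discordant_low_margin" in call.flags

    def test_no_false_positives_on_non_recombinant_batch(self, consensuses):
        by = {c.name: c.sequence for c in consensuses}
        rng = np.random.default_rng(6)
        for name in by:
            for _ in range(20):
                ltr5, ltr3 = evolve_ltr_pair(by[name], 5.0, seed=rng)
                call = detect_chimera(full_locus(ltr5, ltr3), consensuses)
                assert not call.chimeric


class TestMSA:
    def test_identical_sequences_align_without_gaps(self):
        seqs = {f"s{i}": "ACGTACGTACGTACGTACGT" * 5 for i in range(3)}
        msa, excluded = build_subfamily_msa(seqs)
        assert excluded == []
        assert all("-" not in s for s in msa.values())

    def test_heavily_deleted_sequence_excluded(self, consensuses):
        b = next(c for c in consensuses if c.name == "GGERV10B").sequence
        seqs = {f"s{i}": b for i in range(4)}
        seqs["short"] = b[:-60]
        msa, excluded = build_subfamily_msa(seqs, max_deletion=50)
        assert excluded == ["short"]
        assert "short" not in msa

    def test_planted_indel_appears_as_gap_block(self, consensuses):
        b = next(c for c in consensuses if c.name == "GGERV10B").sequence
        deleted = b[:150] + b[160:]
        msa, _ = build_subfamily_msa({"full1": b, "full2": b, "del": deleted}, max_deletion=50)
        assert msa["del"].count("-") == 10
        assert "-" * 10 in msa["del"]

    def test_too_few_sequences_raise(self):
        with pytest.raises(ValueError, match="insufficient"):
            build_subfamily_msa({"only": "ACGT" * 50})


def block_msa(block_specs, subfamilies=("A", "B", "C1", "C2", "D"), rows_per=3, core_len=60):
    """MSA with a shared core plus insertion blocks private to subsets."""
    rng = np.random.default_rng(8)
    core = "".join(np.array(list("ACGT"))[rng.integers(0, 4, core_len)])
    blocks = []
    for owners, length in block_specs:
        blocks.append((owners, "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])))
    msa = {}
    labels = {}
    for sf in subfamilies:
        row = core[:20]
        for owners, seq in blocks:
            row += seq if sf in owners else "-" * len(seq)
        row += core[20:]
        for i in range(rows_per):
            name = f"{sf}_{i}"
            msa[name] = row
            labels[name] = sf
    return msa, labels


class TestDiagnosticSegments:
    def test_private_24_column_block_recovered(self):
        msa, labels = block_msa([(("A",), 24)])
        segments = find_diagnostic_segments(msa, labels)
        assert len(segments) == 1
        seg = segments[0]
        assert seg.present_in == frozenset({"A"})
        assert seg.msa_cols[1] - seg.msa_cols[0] == 24

    def test_identical_rows_yield_no_segments(self):
        msa = {f"s{i}": "ACGT" * 30 for i in range(6)}
        labels = {f"s{i}": "A" if i < 3 else "B" for i in range(6)}
        assert find_diagnostic_segments(msa, labels) == []

    def test_shared_blocks_recover_exact_subfamily_sets(self):
        msa, labels = block_msa([(("C1", "C2"), 15), (("C1", "D"), 12)])
        segments = find_diagnostic_segments(msa, labels)
        sets = {seg.present_in for seg in segments}
        assert frozenset({"C1", "C2"}) in sets
        assert frozenset({"C1", "D"}) in sets

    def test_invariant_to_row_order_and_duplication(self):
        msa, labels = block_msa([(("A",), 24), (("C1", "C2"), 15)])
        reference = find_diagnostic_segments(msa, labels)

        items = list(msa.items())
        random.Random(9).shuffle(items)
        shuffled = dict(items)
        assert find_diagnostic_segments(shuffled, labels) == reference

        dup_msa = dict(msa)
        dup_labels = dict(labels)
        dup_msa["A_dup"] = msa["A_0"]
        dup_labels["A_dup"] = "A"
        assert find_diagnostic_segments(dup_msa, dup_labels) == reference

    def test_simulated_subfamily_ltrs_recover_duplication_block(self, consensus_set):
        # evolve a few copies per subfamily, align, and recover the block
        # private to the GGERV10A-like consensus
        rng = np.random.default_rng(10)
        seqs, labels = {}, {}
        for cons in consensus_set.ltr_consensuses:
            for i in range(4):
                seq, _ = mutate_sequence(cons.sequence, 0.01, rng)
                name = f"{cons.name}_{i}"
                seqs[name] = seq
                labels[name] = cons.name
        msa, _ = build_subfamily_msa(seqs)
        segments = find_diagnostic_segments(msa, labels, min_len=10)
        a_private = [
            s for s in segments
            if s.present_in == frozenset({"GGERV10A"})
            and s.msa_cols[1] - s.msa_cols[0] >= 24
        ]
        assert a_private
        assert any(DUPLICATED_BLOCK in s.segment_seq for s in a_private)
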