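"""dating_phylo: K2P closed form, age estimators, NJ correctness, bootstrap."""

import itertools

import numpy as np
import pytest

from ervpipe.dating_phylo import (
    bootstrap_supports,
    consensus_sequence,
    estimate_age,
    k2p_distance,
    k2p_matrix,
    nj_tree,
    p_distance,
    subfamily_age,
    tree_bipartitions,
)
from ervpipe.synthetic_data import evolve_ltr_pair, mutate_sequence

# frozen from an exact symbolic evaluation of
# -1/2 ln(1 - 2/10 - 1/20) - 1/4 ln(1 - 1/10) at 20 significant digits
K2P_P10_Q05 = 0.17018116514034704


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestK2P:
    def test_identical_sequences(self):
        assert k2p_distance("ACGT" * 25, "ACGT" * 25) == (0.0, 0.0, 0.0)

    def test_closed_form_at_p10_q05(self):
        # 100 columns: 10 transitions (A->G), 5 transversions (A->C)
        seq1 = "A" * 100
        seq2 = "G" * 10 + "C" * 5 + "A" * 85
        P, Q, d = k2p_distance(seq1, seq2)
        assert (P, Q) == (0.10, 0.05)
        assert d == pytest.approx(K2P_P10_Q05, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = random_dna(rng, 200)
        b, _ = mutate_sequence(a, 0.1, rng)
        assert k2p_distance(a, b) == k2p_distance(b, a)

    def test_gap_and_n_columns_dropped(self):
        P, Q, d = k2p_distance("ACG-N" + "A" * 20, "ACGTT" + "A" * 20)
        assert (P, Q, d) == (0.0, 0.0, 0.0)

    def test_saturated_pair_raises(self):
        with pytest.raises(ValueError, match="saturated"):
            k2p_distance("A" * 50, "G" * 50)

    def test_no_valid_columns_raises(self):
        with pytest.raises(ValueError, match="valid"):
            k2p_distance("----", "ACGT")

    def test_k2p_at_least_p_distance(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = random_dna(rng, 300)
            b, _ = mutate_sequence(a, rng.uniform(0.0, 0.15), rng)
            _, _, d = k2p_distance(a, b)
            assert d >= p_distance(a, b) - 1e-12

    def test_matrix_agrees_with_pair_function(self):
        rng = np.random.default_rng(2)
        seqs = [random_dna(rng, 150)]
        for _ in range(4):
            s, _ = mutate_sequence(seqs[0], 0.05, rng)
            seqs.append(s)
        dm = k2p_matrix(seqs)
        for i in range(5):
            for j in range(5):
                expected = 0.0 if i == j else k2p_distance(seqs[i], seqs[j])[2]
                assert dm[i, j] == pytest.approx(expected, abs=1e-6)


class TestAges:
    def test_zero_distance_is_zero_age(self):
        assert estimate_age(0.0) == 0.0

    def test_formula_forced_value(self):
        assert estimate_age(0.0038, 0.0019) == pytest.approx(1.0)

    def test_linear_in_d_inverse_in_mu(self):
        assert estimate_age(0.02, 0.0019) == pytest.approx(2 * estimate_age(0.01, 0.0019))
        assert estimate_age(0.02, 0.0038) == pytest.approx(estimate_age(0.02, 0.0019) / 2)

    def test_recovery_bias_small_at_low_divergence(self):
        # >= 200 pairs evolved to d ~ 0.05: mean age within 5% of truth
        truth_myr = 13.0
        rng = np.random.default_rng(3)
        cons = random_dna(rng, 382)
        ages = []
        for _ in range(200):
            l5, l3 = evolve_ltr_pair(cons, truth_myr, seed=rng)
            _, _, d = k2p_distance(l5, l3)
            ages.append(estimate_age(d))
        assert abs(np.mean(ages) - truth_myr) / truth_myr < 0.05


class TestSubfamilyAge:
    def test_identical_ltrs_give_zero(self):
        assert subfamily_age(["ACGT" * 50] * 5) == 0.0

    def test_doubling_mu_halves_age_exactly(self):
        rng = np.random.default_rng(4)
        cons = random_dna(rng, 300)
        seqs = [mutate_sequence(cons, 0.01, rng)[0] for _ in range(6)]
        assert subfamily_age(seqs, 0.0038) == pytest.approx(subfamily_age(seqs, 0.0019) / 2)

    def test_requires_three_sequences(self):
        with pytest.raises(ValueError):
            subfamily_age(["ACGT" * 30] * 2)

    def test_recovers_simulated_subfamily_age(self):
        # copies diverge independently from one ancestor for 3.7 myr
        rng = np.random.default_rng(5)
        cons = random_dna(rng, 382)
        seqs = [mutate_sequence(cons, 0.0019 * 3.7, rng)[0] for _ in range(30)]
        age = subfamily_age(seqs, 0.0019)
        assert age == pytest.approx(3.7, rel=0.2)


def ls_best_quartet_topology(D):
    """Brute-force least-squares fit of the 3 unrooted 4-taxon topologies.

    For topology ((a,b),(c,d)) the tree has 5 branches; pairwise path
    lengths are linear in branch lengths, so each topology is a least-
    squares problem; the generating topology has residual ~0.
    """
    pairs = list(itertools.combinations(range(4), 2))
    best = None
    for split in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        (a, b), (c, d) = split
        # branches: e_a, e_b, e_c, e_d, internal
        rows = []
        y = []
        for i, j in pairs:
            row = [0.0] * 5
            row[i] = 1.0
            row[j] = 1.0
            same_side = {i, j} in ({a, b}, {c, d})
            if not same_side:
                row[4] = 1.0
            rows.append(row)
            y.append(D[i, j])
        sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
        residual = float(res[0]) if len(res) else 0.0
        if best is None or residual < best[0]:
            best = (residual, frozenset([frozenset([a, b]), frozenset([c, d])]))
    return best[1]


def random_additive_quartet(rng):
    """Distances from a random 4-taxon tree with positive branch lengths."""
    e = rng.uniform(0.05, 1.0, size=5)  # 4 pendant + 1 internal
    split = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))][rng.integers(3)]
    (a, b), (c, d) = split
    D = np.zeros((4, 4))
    for i, j in itertools.combinations(range(4), 2):
        same = {i, j} in ({a, b}, {c, d})
        D[i, j] = D[j, i] = e[i] + e[j] + (0.0 if same else e[4])
    return D


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.4], [0.3, 0.0, 0.5], [0.4, 0.5, 0.0]])
        tree = nj_tree(["a", "b", "c"], D)
        lengths = {tip.name: tip.length for tip in tree.tips()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.4 - 0.5))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.4))
        assert lengths["c"] == pytest.approx(0.5 * (0.4 + 0.5 - 0.3))

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(["a", "b"], np.zeros((2, 2)))

    def test_quartets_recover_generating_topology_and_path_lengths(self):
        rng = np.random.default_rng(6)
        labels = ["t0", "t1", "t2", "t3"]
        for _ in range(100):
            D = random_additive_quartet(rng)
            truth = ls_best_quartet_topology(D)
            tree = nj_tree(labels, D)
            parts = tree_bipartitions(tree)
            assert len(parts) == 1
            (part,) = parts
            as_indices = frozenset(int(name[1]) for name in part)
            complement = frozenset(range(4)) - as_indices
            assert frozenset([as_indices, complement]) == truth
            for i, j in itertools.combinations(range(4), 2):
                path = tree.find(labels[i]).distance(tree.find(labels[j]))
                assert path == pytest.approx(D[i, j], abs=1e-9)

    def test_agrees_with_reference_nj_implementation(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as reference_nj

        rng = np.random.default_rng(7)
        seqs = [random_dna(rng, 300)]
        for _ in range(7):
            seqs.append(mutate_sequence(seqs[0], 0.08, rng)[0])
        labels = [f"t{i}" for i in range(8)]
        D = k2p_matrix(seqs)
        mine = nj_tree(labels, D)
        ref = reference_nj(DistanceMatrix(D, labels))
        assert tree_bipartitions(mine) == tree_bipartitions(ref)

    def test_subfamily_ltrs_cluster_monophyletically(self, consensus_set):
        rng = np.random.default_rng(8)
        labels, seqs = [], []
        for cons in consensus_set.ltr_consensuses:
            for i in range(4):
                labels.append(f"{cons.name}|{i}")
                seqs.append(mutate_sequence(cons.sequence, 0.01, rng)[0])
        from ervpipe.subfamily import build_subfamily_msa

        msa, _ = build_subfamily_msa(dict(zip(labels, seqs)))
        tree = nj_tree(list(msa), k2p_matrix(list(msa.values())))
        parts = tree_bipartitions(tree)
        for cons in consensus_set.ltr_consensuses:
            clade = frozenset(l for l in labels if l.startswith(cons.name + "|"))
            assert clade in parts, f"{cons.name} LTRs not monophyletic"


class TestBootstrap:
    def _two_clade_alignment(self):
        rng = np.random.default_rng(9)
        ancestor = random_dna(rng, 400)
        left = mutate_sequence(ancestor, 0.25, rng)[0]
        labels, seqs = [], []
        for i, base in enumerate([ancestor] * 4 + [left] * 4):
            labels.append(f"{'AB'[i // 4]}{i}")
            seqs.append(mutate_sequence(base, 0.01, rng)[0])
        return labels, seqs

    def test_strong_split_gets_high_support(self):
        labels, seqs = self._two_clade_alignment()
        tree, supports = bootstrap_supports(labels, seqs, n_reps=200, seed=0)
        clade = frozenset(l for l in labels if l.startswith("A"))
        comp = frozenset(labels) - clade
        canonical = min(clade, comp, key=lambda s: (len(s), tuple(sorted(s))))
        assert supports[canonical] > 95.0

    def test_zero_replicates_is_empty(self):
        labels, seqs = self._two_clade_alignment()
        _, supports = bootstrap_supports(labels, seqs, n_reps=0, seed=0)
        assert supports == {}

    def test_same_seed_reproduces_supports(self):
        labels, seqs = self._two_clade_alignment()
        _, s1 = bootstrap_supports(labels, seqs, n_reps=50, seed=42)
        _, s2 = bootstrap_supports(labels, seqs, n_reps=50, seed=42)
        assert s1 == s2


class TestConsensus:
    def test_majority_with_alphabetical_ties(self):
        assert consensus_sequence(["AC", "AG", "TG"]) == "AG"
        # tie A/T in column 0 resolves alphabetically
        assert consensus_sequence(["AA", "TA"]) == "AA"
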