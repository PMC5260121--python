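"""LTR dating and phylogeny.

At integration the 5' and 3' LTRs of a provirus are identical; they then
accumulate substitutions independently, so their Kimura 2-parameter (K2P)
distance d gives the insertion age as d / (2*mu) for a per-site, per-myr
substitution rate mu (default 0.0019, i.e. 0.19%/myr).  A subfamily's age is
taken as the mean K2P distance of its LTRs to the subfamily consensus
divided by mu (single-lineage accumulation from the ancestral sequence) — a
reproducible mean-divergence proxy for the rho statistic of median-joining
network dating.  Trees are neighbor-joining over K2P distances with
column-resampling bootstrap supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skbio import TreeNode

DEFAULT_MU = 0.0019  # substitutions / site / myr

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


@dataclass(frozen=True)
class AgeEstimate:
    """K2P-based insertion age: P/Q proportions, distance, rate, age."""

    P: float
    Q: float
    d: float
    mu: float = DEFAULT_MU

    @property
    def age_myr(self) -> float:
        return estimate_age(self.d, self.mu)


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to codes A=0 C=1 G=2 T=3, anything else 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def k2p_distance(seq1: str, seq2: str) -> tuple[float, float, float]:
    """Kimura 2-parameter distance between two aligned sequences.

    Columns containing a gap or N in either sequence are dropped
    (pairwise deletion).  Returns (P, Q, d) where P and Q are the
    transition and transversion proportions and

        d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

    Raises ValueError on saturation (log argument <= 0) or when no valid
    columns remain.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    a = encode(seq1)
    b = encode(seq2)
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid (gap/N-free) columns")
    av, bv = a[valid], b[valid]
    diff = av != bv
    transition = diff & ((av ^ bv) == 2)  # A<->G and C<->T both xor to 2
    P = float(transition.sum()) / n
    Q = float((diff & ~transition).sum()) / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("distance saturated: K2P undefined for this pair")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return P, Q, d


def p_distance(seq1: str, seq2: str) -> float:
    """Proportion of differing valid columns (pairwise deletion)."""
    a = encode(seq1)
    b = encode(seq2)
    valid = (a < 4) & (b < 4)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid columns")
    return float(((a != b) & valid).sum()) / n


def estimate_age(d: float, mu: float = DEFAULT_MU) -> float:
    """Insertion age in myr from an inter-LTR distance: d / (2 mu)."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return d / (2.0 * mu)


def consensus_sequence(aligned: Sequence[str]) -> str:
    """Column-majority consensus (gap counts as a state; ties alphabetical)."""
    arr = np.array([list(s.upper()) for s in aligned])
    cols = []
    for j in range(arr.shape[1]):
        vals, counts = np.unique(arr[:, j], return_counts=True)
        order = np.lexsort((vals, -counts))  # most frequent, ties alphabetical
        cols.append(vals[order[0]])
    return "".join(cols)


def subfamily_age(aligned_ltrs: Sequence[str], mu: float = DEFAULT_MU) -> float:
    """Subfamily age from mean K2P distance of member LTRs to their consensus.

    Each LTR diverges from the shared ancestral (consensus) sequence along a
    single lineage, so age = mean_d / mu, not mean_d / (2 mu).
    Requires >= 3 aligned LTRs.
    """
    if len(aligned_ltrs) < 3:
        raise ValueError("subfamily age requires >= 3 aligned LTRs")
    cons = consensus_sequence(aligned_ltrs)
    dists = [k2p_distance(seq, cons)[2] for seq in aligned_ltrs]
    return float(np.mean(dists)) / mu


def k2p_matrix(seqs: Sequence[str]) -> np.ndarray:
    """All-pairs K2P distance matrix over aligned sequences (vectorized).

    Uses one-hot matrix products for pair counts; saturated pairs are
    assigned the largest finite distance in the matrix times two (they carry
    no reliable signal but must not break clustering).
    """
    codes = np.stack([encode(s) for s in seqs])
    return _k2p_matrix_codes(codes)


def _k2p_matrix_codes(codes: np.ndarray) -> np.ndarray:
    onehot = np.stack([(codes == b).astype(np.float32) for b in range(4)])  # (4, n, L)
    V = onehot.sum(axis=0)  # valid mask, (n, L)
    valid = V @ V.T
    match = sum(onehot[b] @ onehot[b].T for b in range(4))
    ts = onehot[0] @ onehot[2].T + onehot[2] @ onehot[0].T \
        + onehot[1] @ onehot[3].T + onehot[3] @ onehot[1].T
    with np.errstate(divide="ignore", invalid="ignore"):
        P = ts / valid
        Q = (valid - match - ts) / valid
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    bad = ~np.isfinite(d)
    if bad.any():
        finite = d[np.isfinite(d)]
        fill = 2.0 * float(finite.max()) if finite.size else 1.0
        d[bad] = fill
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0


def nj_tree(labels: Sequence[str], dist_matrix: np.ndarray) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Standard Saitou–Nei agglomeration; negative branch lengths are clamped
    to zero with the deficit shifted to the sister branch so path lengths
    are preserved.  Returns an unrooted tree (trifurcating root) as a
    scikit-bio TreeNode, serializable as newick.
    """
    D = np.asarray(dist_matrix, dtype=float).copy()
    n = D.shape[0]
    if n != D.shape[1] or n != len(labels):
        raise ValueError("labels and matrix dimensions disagree")
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes: list[TreeNode] = [TreeNode(name=str(lbl)) for lbl in labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        ai, aj = active[i], active[j]
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        nodes[ai].length = li
        nodes[aj].length = lj
        # distances from the new node to every remaining taxon
        new_row = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D = np.vstack([D, new_row])
        new_col = np.append(new_row, 0.0)
        D = np.column_stack([D, new_col])
        nodes.append(parent)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Canonical internal bipartitions (as the smaller/lexi-min leaf set)."""
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(leaf.name for leaf in node.tips())
        comp = all_leaves - clade
        if len(clade) < 2 or len(comp) < 2:
            continue
        canonical = min(clade, comp, key=lambda s: (len(s), tuple(sorted(s))))
        parts.add(canonical)
    return parts


def bootstrap_supports(
    labels: Sequence[str],
    aligned_seqs: Sequence[str],
    n_reps: int = 1000,
    seed: int | None = None,
    tree: TreeNode | None = None,
) -> tuple[TreeNode, dict[frozenset, float]]:
    """Column-resampling bootstrap supports for an NJ tree.

    Resamples alignment columns with replacement ``n_reps`` times, rebuilds
    the NJ tree each time, and reports for every internal bipartition of the
    reference tree the percentage of replicates containing it.  Supports are
    written into the reference tree's internal node names.  Reproducible
    given ``seed``; ``n_reps=0`` returns the reference tree with no supports.
    """
    codes = np.stack([encode(s) for s in aligned_seqs])
    L = codes.shape[1]
    if L < 2:
        raise ValueError("alignment must have >= 2 columns")
    if tree is None:
        tree = nj_tree(labels, _k2p_matrix_codes(codes))
    ref_parts = tree_bipartitions(tree)
    if n_reps == 0:
        return tree, {}
    rng = np.random.default_rng(seed)
    counts = {part: 0 for part in ref_parts}
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_tree = nj_tree(labels, _k2p_matrix_codes(codes[:, idx]))
        rep_parts = tree_bipartitions(rep_tree)
        for part in ref_parts:
            if part in rep_parts:
                counts[part] += 1
    supports = {part: 100.0 * c / n_reps for part, c in counts.items()}

    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    for node in tree.non_tips(include_self=False):
        clade = frozenset(leaf.name for leaf in node.tips())
        canonical = min(clade, all_leaves - clade, key=lambda s: (len(s), tuple(sorted(s))))
        if canonical in supports:
            node.name = f"{supports[canonical]:.0f}"
    return tree, supports
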