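import math

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ervography.comparative import (DistanceMatrix, bootstrap_support, dotplot,
                                    k2p_distance, k2p_matrix,
                                    majority_consensus, nj_tree,
                                    p_distance_cpg_stripped, pairwise_align,
                                    progressive_msa, same_topology, tree_splits)
from ervography.io_core import ValidationError
from ervography.synthetic_data import mutate, random_dna


class TestPairwiseAlign:
    def test_identical_gap_free(self):
        a, b = pairwise_align("ACGTACGT", "ACGTACGT")
        assert a == b == "ACGTACGT"

    def test_single_gap_three_matches(self):
        a, b = pairwise_align("ACGT", "AGT")
        assert len(a) == len(b) == 4
        assert b.count("-") == 1
        assert sum(x == y for x, y in zip(a, b)) == 3

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        x, y = random_dna(rng, 300), random_dna(rng, 280)
        a1, b1 = pairwise_align(x, y)
        b2, a2 = pairwise_align(y, x)
        score = lambda p, q: sum(
            1 if u == v else -1 for u, v in zip(p, q) if u != "-" and v != "-")
        assert score(a1, b1) == score(a2, b2)


class TestProgressiveMSA:
    def test_identical_pair(self):
        aln = progressive_msa(["ACGTACGT", "ACGTACGT"])
        assert aln == ["ACGTACGT", "ACGTACGT"]

    def test_known_deletion_block(self):
        rng = np.random.default_rng(2)
        master = random_dna(rng, 600)
        deleted = master[:300] + master[310:]
        third = mutate(master, 0.02, 2.0, rng)
        aln = progressive_msa([master, deleted, third])
        assert "-" * 10 in aln[1]
        assert aln[1].count("-") == 10

    def test_losslessness(self):
        rng = np.random.default_rng(3)
        master = random_dna(rng, 500)
        seqs = [mutate(master, 0.05, 2.0, rng) for _ in range(6)]
        seqs[2] = seqs[2][:100] + seqs[2][130:]
        aln = progressive_msa(seqs)
        assert len({len(r) for r in aln}) == 1
        for row, seq in zip(aln, seqs):
            assert row.replace("-", "") == seq

    def test_single_sequence_unchanged(self):
        assert progressive_msa(["ACGT"]) == ["ACGT"]

    def test_precomputed_hook(self):
        seqs = ["ACGT", "AGT"]
        pre = ["ACGT", "A-GT"]
        assert progressive_msa(seqs, precomputed=pre) == pre
        with pytest.raises(ValidationError):
            progressive_msa(seqs, precomputed=["ACGT", "AGGT"])


class TestConsensus:
    def test_majority_and_support(self):
        cons = majority_consensus(["AAA", "AAA", "AAT"])
        assert cons.seq == "AAA"
        assert cons.support == pytest.approx([1.0, 1.0, 2 / 3])

    def test_tie_gives_n(self):
        cons = majority_consensus(["AC", "TC"])
        assert cons.seq == "NC"

    def test_gap_majority_deletes_column(self):
        cons = majority_consensus(["A-C", "A-C", "AAC"])
        assert cons.seq == "AC"

    def test_idempotence(self):
        rows = ["ACGTAC", "ACGTAC", "ACCTAT", "ACGAAC"]
        c1 = majority_consensus(rows)
        c2 = majority_consensus(rows + [c1.seq])
        assert c1.seq == c2.seq

    def test_recovers_master_from_divergent_copies(self):
        rng = np.random.default_rng(4)
        master = random_dna(rng, 4000)
        rows = [mutate(master, 0.05, 2.0, rng) for _ in range(10)]
        cons = majority_consensus(rows)
        agree = sum(a == b for a, b in zip(cons.seq, master)) / len(master)
        assert agree >= 0.999


class TestDistances:
    def test_p_distance_identical(self):
        assert p_distance_cpg_stripped("ACGTT", "ACGTT") == 0.0

    def test_p_distance_cpg_columns_removed(self):
        # CpG at positions 1-2 of the first row removes those columns;
        # the remaining columns agree
        assert p_distance_cpg_stripped("ACGTT", "ATGTT") == 0.0

    def test_p_distance_definition(self):
        # CpG-free, gap-free pair with exactly 10 mismatches over 100 columns
        a = "AT" * 50
        b = "CT" * 10 + "AT" * 40
        assert p_distance_cpg_stripped(a, b) == pytest.approx(0.10)

    def test_p_distance_gap_pairwise_deletion(self):
        assert p_distance_cpg_stripped("AAT-T", "AATAT") == 0.0

    def test_p_distance_no_columns_flagged(self):
        assert math.isnan(p_distance_cpg_stripped("--", "AA"))

    def test_k2p_zero(self):
        assert k2p_distance("AAAA", "AAAA") == 0.0

    def test_k2p_closed_form(self):
        """100 sites, 8 transitions, 2 transversions -> d ~= 0.1094."""
        a = "A" * 100
        b = "G" * 8 + "C" * 2 + "A" * 90
        d = k2p_distance(a, b)
        P, Q = 0.08, 0.02
        oracle = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert d == pytest.approx(oracle, abs=1e-12)
        assert d == pytest.approx(0.1094, abs=5e-5)

    def test_k2p_saturation_flagged(self):
        a = "A" * 100
        b = "G" * 50 + "A" * 50   # P = 0.5, Q = 0
        assert math.isinf(k2p_distance(a, b))

    def test_k2p_dominates_p_distance(self):
        """Jensen-type inequality: the K2P correction never shrinks distance."""
        rng = np.random.default_rng(6)
        master = random_dna(rng, 2000)
        for mu in (0.01, 0.05, 0.15, 0.3):
            other = mutate(master, mu, 2.0, rng)
            p_raw = sum(a != b for a, b in zip(master, other)) / len(master)
            d = k2p_distance(master, other)
            assert d >= p_raw
        assert k2p_distance(master, master) == 0.0


def _tree_distances(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    n = len(labels)
    m = np.zeros((n, n))
    tn = tree.taxon_namespace
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = pdm.patristic_distance(tn.get_taxon(a), tn.get_taxon(b))
                m[i, j] = m[j, i] = d
    return tree, DistanceMatrix(labels, m)


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        """NJ on an additive matrix recovers topology and branch lengths; the
        four-point condition over all three pairings is the oracle."""
        tree, dm = _tree_distances("((A:1,B:2):1,(C:3,D:4):1);")
        d = dm.get
        sums = {"AB|CD": d("A", "B") + d("C", "D"),
                "AC|BD": d("A", "C") + d("B", "D"),
                "AD|BC": d("A", "D") + d("B", "C")}
        assert min(sums, key=sums.get) == "AB|CD"   # four-point oracle
        njt = nj_tree(dm)
        assert tree_splits(njt) == {frozenset({"C", "D"})}
        # branch lengths: leaf edges recover exactly
        for leaf, expected in (("A", 1.0), ("B", 2.0), ("C", 3.0), ("D", 4.0)):
            node = [l for l in njt.leaf_node_iter() if l.taxon.label == leaf][0]
            assert node.edge.length == pytest.approx(expected)

    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        njt = nj_tree(dm)
        lengths = {l.taxon.label: l.edge.length for l in njt.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_label_order_invariance(self):
        _, dm = _tree_distances("((A:1,B:2):1,(C:3,D:4):1);")
        perm = [2, 0, 3, 1]
        labels = [dm.labels[i] for i in perm]
        m = dm.matrix[np.ix_(perm, perm)]
        assert same_topology(nj_tree(dm), nj_tree(DistanceMatrix(labels, m)))

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0.0]]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(4, 8), st.integers(0, 10_000))
    def test_recovers_random_additive_trees(self, n_taxa, seed):
        """Any additive matrix from a random binary tree yields its topology."""
        rng = np.random.default_rng(seed)
        labels = [f"T{i}" for i in range(n_taxa)]
        # random binary tree by sequential joining, branch lengths in [0.1, 2]
        nodes = [f"T{i}" for i in range(n_taxa)]
        newick = {lab: lab for lab in nodes}
        while len(nodes) > 2:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            a, b = nodes[i], nodes[j]
            la, lb = rng.uniform(0.1, 2, size=2)
            merged = f"({newick[a]}:{la:.3f},{newick[b]}:{lb:.3f})"
            key = a + b
            newick[key] = merged
            nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [key]
        la, lb = rng.uniform(0.1, 2, size=2)
        text = f"({newick[nodes[0]]}:{la:.3f},{newick[nodes[1]]}:{lb:.3f});"
        gen_tree, dm = _tree_distances(text)
        assert same_topology(nj_tree(dm), gen_tree)

    def test_matches_independent_nj_implementation(self):
        """Cross-check against scikit-bio's neighbor joining on a noisy matrix."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(12)
        _, dm = _tree_distances("(((A:1,B:1.5):0.7,(C:2,D:1):0.4):0.6,(E:2,F:0.8):1.1);")
        noisy = dm.matrix + rng.uniform(0, 0.05, dm.matrix.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        mine = nj_tree(DistanceMatrix(dm.labels, noisy))
        sk = skbio_nj(skbio.DistanceMatrix(noisy, dm.labels))
        sk_splits = set()
        labels = set(dm.labels)
        first = min(labels)
        for node in sk.non_tips():
            side = frozenset(t.name for t in node.tips())
            if first in side:
                side = frozenset(labels) - side
            if 1 < len(side) < len(labels) - 1:
                sk_splits.add(side)
        assert tree_splits(mine) == sk_splits


class TestBootstrap:
    def _clade_alignment(self, rng):
        base = random_dna(rng, 1000)
        other = mutate(base, 0.2, 2.0, rng)
        labels, rows = [], []
        for i in range(4):
            labels.append(f"A{i}")
            rows.append(mutate(base, 0.01, 2.0, rng))
        for i in range(4):
            labels.append(f"B{i}")
            rows.append(mutate(other, 0.01, 2.0, rng))
        return labels, rows

    def test_true_split_strongly_supported(self):
        rng = np.random.default_rng(7)
        labels, rows = self._clade_alignment(rng)
        support = bootstrap_support(labels, rows, reps=100, seed=11)
        split = frozenset({"B0", "B1", "B2", "B3"})
        assert support[split] >= 95.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(8)
        labels, rows = self._clade_alignment(rng)
        s1 = bootstrap_support(labels, rows, reps=25, seed=3)
        s2 = bootstrap_support(labels, rows, reps=25, seed=3)
        assert s1 == s2

    def test_identical_sequences_vacuous(self):
        labels = [f"S{i}" for i in range(4)]
        rows = ["ACGTACGT" * 10] * 4
        support = bootstrap_support(labels, rows, reps=10, seed=1)
        assert support == {}


class TestDotPlot:
    def test_identical_full_diagonal(self):
        rng = np.random.default_rng(9)
        s = random_dna(rng, 2000)
        dp = dotplot(s, s, window=100, step=25, threshold=0.5)
        assert np.all(np.diag(dp.highlight))

    def test_unrelated_random_zero_highlights(self):
        rng = np.random.default_rng(10)
        a, b = random_dna(rng, 10_000), random_dna(rng, 10_000)
        dp = dotplot(a, b, window=100, step=25, threshold=0.5)
        assert int(dp.highlight.sum()) == 0

    def test_deletion_offsets_diagonal(self):
        rng = np.random.default_rng(11)
        a = random_dna(rng, 6000)
        b = a[:2000] + a[4000:]   # 2 kb internal deletion
        dp = dotplot(a, b, window=100, step=100, threshold=0.5)
        ii, jj = np.nonzero(dp.highlight)
        offsets = (dp.a_starts[ii] - dp.b_starts[jj])
        assert set(offsets) == {0, 2000}

    def test_window_longer_than_sequence_rejected(self):
        with pytest.raises(ValidationError):
            dotplot("ACGT", "ACGT", window=100)

    def test_reverse_complement_mode(self):
        rng = np.random.default_rng(12)
        from ervography.io_core import revcomp

        a = random_dna(rng, 1000)
        dp = dotplot(a, revcomp(a), window=100, step=50, threshold=0.5,
                     both_strands=True)
        assert int(dp.highlight.sum()) == 0
        assert np.all(np.diag(dp.highlight_rc))
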