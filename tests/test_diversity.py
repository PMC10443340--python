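"""Per-gene variability statistics, HVG detection, p-distances,
neighbor joining (with scikit-bio as independent oracle) and bootstrap."""
import numpy as np
import pytest

from conftest import table_from_truth
from microdiv.corevar import build_core_alignments
from microdiv.diversity import (
    DistanceMatrix,
    GeneVariabilityStats,
    bipartitions,
    bootstrap_support,
    conserved_genes,
    detect_hvgs,
    hvg_tree,
    neighbor_joining,
    p_distance_matrix,
    per_gene_snp_stats,
    robinson_foulds,
    select_reference_strain,
)
from microdiv.records import CoreAlignment, concatenate_alignments
from microdiv.simulate import SimulationConfig, simulate_pangenome


def _stats(means):
    return [
        GeneVariabilityStats(family_id=f"fam{i}", counts={}, mean=m, sd=0.0)
        for i, m in enumerate(means)
    ]


def _aln(rows, ids=None, fam="f"):
    return CoreAlignment(
        family_id=fam,
        genome_ids=ids or [f"g{i}" for i in range(len(rows))],
        rows=rows,
    )


class TestPerGeneStats:
    def test_mean_over_non_reference_rows(self):
        # rows differ from the reference at 0, 2 and 4 positions
        ref = "AAAAAAAAAA"
        aln = _aln(
            [ref, "AAAAAAAACC", "AAAAAACCCC"], ids=["ref", "x", "y"]
        )
        stats = per_gene_snp_stats([aln], "ref")
        assert stats[0].counts == {"x": 2, "y": 4}
        assert stats[0].mean == pytest.approx(3.0)

    def test_zero_rate_families_have_zero_mean(self, zero_rate_sim):
        _, genomes, truth = zero_rate_sim
        table = table_from_truth(truth)
        alignments = build_core_alignments(genomes, table, "S01")
        stats = per_gene_snp_stats(alignments, "S01")
        assert all(s.mean == 0.0 for s in stats)


class TestDetectHvgs:
    def test_degenerate_distribution_has_no_hvgs(self):
        hvgs, cutoff = detect_hvgs(_stats([5.0] * 8))
        assert hvgs == set()
        assert cutoff == pytest.approx(5.0)

    def test_hand_computed_quartiles(self):
        # means (1,2,3,4,100): Q1=2, Q3=4, cutoff 4 + 1.5*2 = 7
        stats = _stats([1, 2, 3, 4, 100])
        hvgs, cutoff = detect_hvgs(stats)
        assert cutoff == pytest.approx(7.0)
        assert hvgs == {"fam4"}
        assert stats[4].rate_class == "HVG"

    def test_order_invariance(self):
        means = [3.0, 50.0, 1.0, 2.0, 4.0, 2.5, 60.0, 3.5]
        a, _ = detect_hvgs(_stats(means))
        permuted = list(reversed(means))
        b, _ = detect_hvgs(_stats(permuted))
        flagged_a = {means[int(f[3:])] for f in a}
        flagged_b = {permuted[int(f[3:])] for f in b}
        assert flagged_a == flagged_b

    def test_too_few_families_errors(self):
        with pytest.raises(ValueError):
            detect_hvgs(_stats([1, 2, 3]))


class TestConservedGenes:
    def test_interpolated_first_quartile(self):
        # means (1,2,3,4): Q1 = 1.75, only the mean-1 family lies below
        stats = _stats([1, 2, 3, 4])
        assert conserved_genes(stats) == {"fam0"}

    def test_all_equal_gives_empty_set(self):
        assert conserved_genes(_stats([2.0] * 6)) == set()

    def test_zero_rate_genes_among_mutated_selected(self):
        stats = _stats([0, 0, 0, 5, 6, 7, 8, 9, 10, 11])
        assert conserved_genes(stats) == {"fam0", "fam1", "fam2"}


class TestPDistance:
    def test_identical_rows_zero(self):
        dm = p_distance_matrix(_aln(["ACGT" * 10] * 4))
        assert np.allclose(dm.matrix, 0.0)

    def test_direct_proportion(self):
        a = "A" * 100
        b = "A" * 95 + "C" * 5
        dm = p_distance_matrix(_aln([a, b, a]))
        assert dm.matrix[0, 1] == pytest.approx(0.05)

    def test_matches_brute_force_on_random_alignment(self):
        rng = np.random.default_rng(8)
        rows = [
            "".join(rng.choice(list("ACGT-"), size=500, p=[0.24] * 4 + [0.04]))
            for _ in range(10)
        ]
        dm = p_distance_matrix(_aln(rows))
        for i in range(10):
            for j in range(10):
                comparable = diffs = 0
                for x, y in zip(rows[i], rows[j]):
                    if x in "ACGT" and y in "ACGT":
                        comparable += 1
                        diffs += x != y
                assert dm.matrix[i, j] == pytest.approx(diffs / comparable)


def _additive_matrix_4taxa():
    # tree ((A:1,B:2):1,(C:3,D:4))
    ids = list("ABCD")
    d = {
        ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
        ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
    }
    mat = np.zeros((4, 4))
    for (x, y), v in d.items():
        i, j = ids.index(x), ids.index(y)
        mat[i, j] = mat[j, i] = v
    return DistanceMatrix(ids=ids, matrix=mat)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        mat = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids=list("ABC"), matrix=mat))
        lengths = {leaf.name: leaf.branch_length for leaf in tree.leaves()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_recovery(self):
        tree = neighbor_joining(_additive_matrix_4taxa())
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {leaf.name: leaf.branch_length for leaf in tree.leaves()}
        for taxon, expected in zip("ABCD", (1, 2, 3, 4)):
            assert lengths[taxon] == pytest.approx(expected, abs=1e-9)
        internal = [
            c for c in tree.children if not c.is_leaf
        ]
        assert internal and internal[0].branch_length == pytest.approx(
            1.0, abs=1e-9
        )

    def test_asymmetric_matrix_rejected(self):
        mat = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=list("ABC"), matrix=mat)

    @pytest.mark.parametrize("seed", range(5))
    def test_topology_agrees_with_scikit_bio(self, seed):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(seed)
        n = 7
        coords = rng.random((n, 4))
        mat = np.sqrt(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        )
        np.fill_diagonal(mat, 0.0)
        ids = [f"t{i}" for i in range(n)]
        mine = neighbor_joining(DistanceMatrix(ids=ids, matrix=mat))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(mat, ids))
        their_splits = set()
        for node in theirs.non_tips():
            below = frozenset(t.name for t in node.tips())
            if 1 < len(below) < n - 1:
                if "t0" in below:
                    below = frozenset(set(ids) - below)
                their_splits.add(below)
        assert bipartitions(mine) == their_splits

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_six_taxon_tree_recovered(self, seed):
        """Distances read off a random tree are reproduced exactly."""
        rng = np.random.default_rng(100 + seed)
        from microdiv.simulate import random_coalescent_tree

        tree = random_coalescent_tree(6, rng)
        ids = sorted(leaf.name for leaf in tree.leaves())
        # path-length (patristic) matrix via leaf-to-root paths
        paths = {}

        def walk(node, acc):
            acc = acc + [node]
            if node.is_leaf:
                paths[node.name] = acc
            for c in node.children:
                walk(c, acc)

        walk(tree, [])
        mat = np.zeros((6, 6))
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i < j:
                    pa, pb = paths[a], paths[b]
                    shared = sum(1 for x, y in zip(pa, pb) if x is y)
                    d = sum(n.branch_length for n in pa[shared:]) + sum(
                        n.branch_length for n in pb[shared:]
                    )
                    mat[i, j] = mat[j, i] = d
        inferred = neighbor_joining(DistanceMatrix(ids=ids, matrix=mat))
        assert robinson_foulds(inferred, tree) == 0


class TestBootstrap:
    def _signal_alignment(self):
        # single clean bipartition {A,B} | {C,D} repeated over 60 columns
        rows = {"A": "A" * 60, "B": "A" * 60, "C": "C" * 60, "D": "C" * 60}
        # add unique noise so distances are distinct
        rows["A"] = rows["A"][:-1] + "G"
        rows["C"] = rows["C"][:-2] + "TA"
        ids = sorted(rows)
        return [_aln([rows[g] for g in ids], ids=ids)]

    def test_perfect_signal_gets_full_support(self):
        for seed in (1, 2, 3):
            tree, support = bootstrap_support(
                self._signal_alignment(), n_replicates=50, seed=seed
            )
            assert support[frozenset({"C", "D"})] == pytest.approx(100.0)

    def test_single_replicate_support_is_binary(self):
        _, support = bootstrap_support(
            self._signal_alignment(), n_replicates=1, seed=0
        )
        assert set(support.values()) <= {0.0, 100.0}

    def test_same_seed_reproducible_and_converged(self, small_sim):
        _, genomes, truth = small_sim
        table = table_from_truth(truth)
        alignments = build_core_alignments(genomes, table, "S01")
        _, s1 = bootstrap_support(alignments, n_replicates=100, seed=5)
        _, s1b = bootstrap_support(alignments, n_replicates=100, seed=5)
        assert s1 == s1b
        _, s2 = bootstrap_support(alignments, n_replicates=100, seed=6)
        for split, val in s1.items():
            assert abs(val - s2[split]) < 15  # strong signal converges


class TestReferenceSelection:
    def test_outgroup_selected(self):
        ids = ["in1", "in2", "in3", "out"]
        mat = np.full((4, 4), 0.01)
        mat[3, :] = mat[:, 3] = 0.1
        np.fill_diagonal(mat, 0.0)
        dm = DistanceMatrix(ids=ids, matrix=mat)
        assert select_reference_strain(dm) == "out"

    def test_tie_broken_lexicographically(self):
        mat = np.full((3, 3), 0.05)
        np.fill_diagonal(mat, 0.0)
        dm = DistanceMatrix(ids=["b", "a", "c"], matrix=mat)
        assert select_reference_strain(dm) == "a"

    def test_long_terminal_branch_selected_on_simulations(self):
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(
                n_strains=8, n_core_genes=40, gene_length_range=(400, 700),
                fast_gene_fraction=0.0, gain_loss_rate=0.0,
                n_unique_genes_per_strain=0, seed=200 + seed,
            )
            genomes, truth = simulate_pangenome(cfg)
            table = table_from_truth(truth)
            alignments = build_core_alignments(genomes, table, "S01")
            dm = p_distance_matrix(concatenate_alignments(alignments))
            chosen = select_reference_strain(dm)
            # truth: leaf with the largest mean patristic distance
            ids = dm.ids
            means = dm.mean_distances()
            assert chosen == min(means, key=lambda g: (-means[g], g))
            hits += 1
        assert hits == 10


class TestHvgTree:
    def test_all_families_equals_full_tree(self, small_sim):
        _, genomes, truth = small_sim
        table = table_from_truth(truth)
        alignments = build_core_alignments(genomes, table, "S01")
        fams = {a.family_id for a in alignments}
        full = neighbor_joining(
            p_distance_matrix(concatenate_alignments(alignments))
        )
        restricted = hvg_tree(alignments, fams)
        assert robinson_foulds(full, restricted) == 0

    def test_empty_hvg_set_errors(self, small_sim):
        _, genomes, truth = small_sim
        table = table_from_truth(truth)
        alignments = build_core_alignments(genomes, table, "S01")
        with pytest.raises(ValueError, match="empty HVG set"):
            hvg_tree(alignments, set())

    def test_two_signal_simulation_separates_trees(self):
        """Fast genes carrying their own clade signal dominate the HVG
        tree while the full-core tree follows the majority signal."""
        rows_slow = {
            "A": "A" * 200, "B": "A" * 200, "C": "T" * 200, "D": "T" * 200,
        }
        # fast gene groups A+C vs B+D instead
        rows_fast = {
            "A": "G" * 200, "C": "G" * 200, "B": "C" * 200, "D": "C" * 200,
        }
        ids = sorted(rows_slow)
        noise = {"A": "ACGT", "B": "AGGT", "C": "ATGT", "D": "ACCT"}
        slow = [
            _aln(
                [rows_slow[g] + noise[g] for g in ids], ids=ids,
                fam=f"slow{i}",
            )
            for i in range(3)
        ]
        fast = [_aln([rows_fast[g] + noise[g] for g in ids], ids=ids, fam="fast")]
        full = neighbor_joining(
            p_distance_matrix(concatenate_alignments(slow + fast))
        )
        hvg = hvg_tree(slow + fast, {"fast"})
        assert bipartitions(full) == {frozenset({"C", "D"})}
        assert bipartitions(hvg) == {frozenset({"B", "D"})}
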