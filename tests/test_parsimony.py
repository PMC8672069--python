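"""Fitch scoring, exact/heuristic search, CI/RI and strict consensus."""

import itertools

import numpy as np
import pytest

import heterodont as hd
from heterodont import parsimony as P


def brute_force_length(tree: P.SimpleTree, matrix: P.CharacterMatrix) -> int:
    """Exhaustive minimum over all internal (and ambiguous-leaf) state labelings."""
    internals = [n for n in tree.adj if n >= matrix.n_taxa]
    edges = tree.edges()
    nstates = len(matrix.symbols)
    total = 0
    for c in range(matrix.n_chars):
        cells = matrix.masks[:, c]
        leaf_opts = [
            [s for s in range(nstates) if cells[i] >> s & 1] for i in range(matrix.n_taxa)
        ]
        nodes = list(range(matrix.n_taxa)) + internals
        idx = {n: i for i, n in enumerate(nodes)}
        opts = leaf_opts + [list(range(nstates))] * len(internals)
        best = None
        for assign in itertools.product(*opts):
            cost = sum(assign[idx[u]] != assign[idx[v]] for u, v in edges)
            if best is None or cost < best:
                best = cost
        total += best
    return total


def random_matrix(taxa, n_chars, rng, symbols="012", missing_frac=0.1):
    rows = {}
    for t in taxa:
        chars = []
        for _ in range(n_chars):
            if rng.random() < missing_frac:
                chars.append("?")
            else:
                chars.append(symbols[rng.integers(len(symbols))])
        rows[t] = "".join(chars)
    return P.CharacterMatrix.from_strings(rows, symbols=symbols)


class TestMatrixIO:
    def test_question_mark_is_full_state_set(self):
        m = P.CharacterMatrix.from_strings({"A": "?", "B": "0", "C": "1", "D": "2"}, "012")
        assert m.cell_states(0, 0) == frozenset("012")

    def test_polymorphism_parsed_as_state_set(self):
        m = P.CharacterMatrix.from_strings({"A": "(01)", "B": "0", "C": "1", "D": "2"}, "012")
        assert m.cell_states(0, 0) == frozenset("01")

    def test_nexus_round_trip(self, tmp_path):
        m = P.CharacterMatrix.from_strings(
            {"Tax_A": "01?(01)1", "Tax_B": "11010", "Tax_C": "00110", "Tax_D": "?1(12)00"},
            symbols="012",
        )
        f = tmp_path / "m.nex"
        P.write_nexus(m, f)
        back = P.read_nexus(f)
        assert back.taxa == m.taxa
        assert np.array_equal(back.masks, m.masks)

    def test_interleaved_equals_sequential(self, tmp_path):
        rng = np.random.default_rng(8)
        m = random_matrix(tuple("ABCDEF"), 23, rng)
        f1, f2 = tmp_path / "seq.nex", tmp_path / "int.nex"
        P.write_nexus(m, f1)
        P.write_nexus(m, f2, interleave_every=7)
        a, b = P.read_nexus(f1), P.read_nexus(f2)
        assert a.taxa == b.taxa
        assert np.array_equal(a.masks, b.masks)

    def test_malformed_nexus_rejected(self, tmp_path):
        f = tmp_path / "bad.nex"
        f.write_text("#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=3 NCHAR=2;\nMATRIX\nA 01\n;\nEND;\n")
        with pytest.raises(P.FormatError):
            P.read_nexus(f)


class TestFitch:
    def test_invariant_character_is_zero_steps(self):
        m = P.CharacterMatrix.from_strings({t: "0" for t in "ABCDE"})
        for tree in P.enumerate_topologies(tuple("ABCDE")):
            assert P.fitch_length(tree, m)[0] == 0

    def test_four_taxon_textbook_case(self):
        m = P.CharacterMatrix.from_strings({"A": "0", "B": "0", "C": "1", "D": "1"})
        good = P.SimpleTree.from_newick("((A,B),(C,D));", taxa=m.taxa)
        bad = P.SimpleTree.from_newick("((A,C),(B,D));", taxa=m.taxa)
        assert P.fitch_length(good, m)[0] == 1
        assert P.fitch_length(bad, m)[0] == 2

    @pytest.mark.parametrize("n_taxa", [5, 6, 7, 8])
    def test_matches_exhaustive_labeling_oracle(self, n_taxa):
        """Fitch equals brute-force internal-state enumeration on random instances."""
        rng = np.random.default_rng(n_taxa)
        taxa = tuple("ABCDEFGH"[:n_taxa])
        n_chars = 4 if n_taxa >= 7 else 6
        reps = 16 if n_taxa < 7 else 9
        for _ in range(reps):
            tree = P.SimpleTree.random_topology(taxa, rng)
            m = random_matrix(taxa, n_chars, rng)
            assert P.fitch_length(tree, m)[0] == brute_force_length(tree, m)

    def test_agrees_with_dendropy(self):
        """Independent library cross-check on a polymorphism-free matrix."""
        import dendropy
        from dendropy.model.parsimony import fitch_down_pass

        rng = np.random.default_rng(19)
        taxa = tuple("ABCDEFG")
        m = random_matrix(taxa, 30, rng, symbols="01", missing_frac=0.0)
        tree = P.SimpleTree.random_topology(taxa, rng)
        tns = dendropy.TaxonNamespace(list(taxa))
        dmat = dendropy.StandardCharacterMatrix.get(
            data="#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=7 NCHAR=30;\n"
            "FORMAT SYMBOLS=\"01\" MISSING=?;\nMATRIX\n"
            + "\n".join(
                f"{t} {''.join(next(iter(m.cell_states(i, c))) for c in range(30))}"
                for i, t in enumerate(taxa)
            )
            + "\n;\nEND;\n",
            schema="nexus",
            taxon_namespace=tns,
        )
        dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick", taxon_namespace=tns)
        taxon_states = dmat.taxon_state_sets_map(gaps_as_missing=True)
        score = fitch_down_pass(dtree.postorder_node_iter(), taxon_state_sets_map=taxon_states)
        assert P.fitch_length(tree, m)[0] == score

    def test_invariant_to_leaf_permutation(self):
        rng = np.random.default_rng(2)
        taxa = tuple("ABCDEF")
        tree = P.SimpleTree.random_topology(taxa, rng)
        m = random_matrix(taxa, 20, rng)
        base = P.fitch_length(tree, m)[0]
        perm = [3, 1, 5, 0, 2, 4]
        new_taxa = tuple(taxa[i] for i in perm)
        new_rows = {t: "".join(sorted(m.cell_states(taxa.index(t), c))[0] if len(m.cell_states(taxa.index(t), c)) == 1 else "?" for c in range(m.n_chars)) for t in new_taxa}
        m2 = P.CharacterMatrix.from_strings(new_rows, symbols=m.symbols)
        tree2 = P.SimpleTree.from_newick(tree.to_newick(), taxa=new_taxa)
        assert P.fitch_length(tree2, m2)[0] == base

    def test_leaf_mismatch_rejected(self):
        m = P.CharacterMatrix.from_strings({"A": "0", "B": "1", "C": "0", "D": "1"})
        tree = P.SimpleTree.from_newick("((A,B),(C,E));", taxa=("A", "B", "C", "E"))
        with pytest.raises(P.StructureError):
            P.fitch_length(tree, m)


class TestSearch:
    def test_four_taxa_equals_exhaustive(self):
        m = P.CharacterMatrix.from_strings(
            {"A": "0011", "B": "0101", "C": "1100", "D": "1111"}
        )
        exhaustive = min(
            P.fitch_length(t, m)[0] for t in P.enumerate_topologies(m.taxa)
        )
        res = P.search(m, "branch_and_bound")
        assert res.best_length == exhaustive

    def test_branch_and_bound_equals_exhaustive_at_eight_taxa(self):
        taxa = tuple("ABCDEFGH")
        gen = P.SimpleTree.random_topology(taxa, np.random.default_rng(3))
        m, _ = hd.simulate_matrix(gen, 50, change_prob=0.05, n_states=2, seed=3)
        trees = list(P.enumerate_topologies(taxa))
        assert len(trees) == 10395
        lengths = [P.fitch_length(t, m)[0] for t in trees]
        best = min(lengths)
        best_ids = {
            t.topology_id() for t, l in zip(trees, lengths) if l == best
        }
        res = P.search(m, "branch_and_bound")
        assert res.best_length == best
        assert {t.topology_id() for t in res.trees} == best_ids

    @pytest.mark.parametrize("seed", range(10))
    def test_randomized_bb_vs_exhaustive_small(self, seed):
        rng = np.random.default_rng(100 + seed)
        taxa = tuple("ABCDEF")
        m = random_matrix(taxa, 12, rng)
        best = min(P.fitch_length(t, m)[0] for t in P.enumerate_topologies(taxa))
        assert P.search(m, "branch_and_bound").best_length == best

    def test_heuristic_never_beats_exact(self):
        taxa = tuple("ABCDEFGH")
        gen = P.SimpleTree.random_topology(taxa, np.random.default_rng(3))
        m, _ = hd.simulate_matrix(gen, 50, change_prob=0.05, n_states=2, seed=3)
        exact = P.search(m, "branch_and_bound").best_length
        hits = 0
        for seed in range(10):
            h = P.search(m, "heuristic", seed=seed).best_length
            assert h >= exact
            hits += h == exact
        assert hits >= 9

    def test_generating_topology_recovery_rate(self):
        """Simulated matrices recover the generating tree in >= 90% of replicates."""
        taxa = tuple("ABCDEFGH")
        hits = 0
        for rep in range(20):
            g = P.SimpleTree.random_topology(taxa, np.random.default_rng(1000 + rep))
            m, _ = hd.simulate_matrix(g, 100, change_prob=0.05, n_states=2, seed=2000 + rep)
            res = P.search(m, "branch_and_bound")
            hits += g.topology_id() in {t.topology_id() for t in res.trees}
        assert hits >= 18

    def test_too_many_taxa_refused(self):
        taxa = tuple(f"t{i}" for i in range(30))
        m = P.CharacterMatrix.from_strings({t: "01" for t in taxa})
        with pytest.raises(ValueError):
            P.search(m, "branch_and_bound")


class TestCiRi:
    def test_perfect_fit_gives_unity(self):
        m = P.CharacterMatrix.from_strings(
            {"A": "00", "B": "00", "C": "11", "D": "11"}
        )
        res = P.search(m, "branch_and_bound")
        assert res.best_length == 2
        assert res.ci == pytest.approx(1.0)
        assert res.ri == pytest.approx(1.0)

    def test_six_taxon_binary_character_extremes(self):
        """3+3 binary character: CI=RI=1 on the grouping tree; CI=1/3, RI=0 at worst."""
        rows = {"A": "0", "B": "0", "C": "0", "D": "1", "E": "1", "F": "1"}
        m = P.CharacterMatrix.from_strings(rows)
        grouping = P.SimpleTree.from_newick("((A,B,C),(D,E,F));", taxa=m.taxa)
        # resolve the polytomies arbitrarily: any resolution keeps 1 step
        grouping = P.SimpleTree.from_newick("(((A,B),C),((D,E),F));", taxa=m.taxa)
        s = P.fitch_length(grouping, m)[0]
        assert s == 1
        assert P.ci_ri(m, s) == (1.0, 1.0)
        worst = max(P.fitch_length(t, m)[0] for t in P.enumerate_topologies(m.taxa))
        assert worst == 3
        ci, ri = P.ci_ri(m, worst)
        assert ci == pytest.approx(1 / 3)
        assert ri == pytest.approx(0.0)

    def test_bounds_respected_on_random_trees(self):
        rng = np.random.default_rng(7)
        taxa = tuple("ABCDEFG")
        m = random_matrix(taxa, 25, rng)
        from heterodont.parsimony import _max_steps_per_char, _min_steps_per_char

        mmin, mmax = _min_steps_per_char(m).sum(), _max_steps_per_char(m).sum()
        for _ in range(15):
            tree = P.SimpleTree.random_topology(taxa, rng)
            s = P.fitch_length(tree, m)[0]
            assert mmin <= s <= mmax
            ci, ri = P.ci_ri(m, s)
            assert 0 <= ci <= 1 and 0 <= ri <= 1

    def test_impossible_score_rejected(self):
        m = P.CharacterMatrix.from_strings({"A": "0", "B": "1", "C": "0", "D": "1"})
        with pytest.raises(ValueError):
            P.ci_ri(m, 0)


class TestStrictConsensus:
    def test_identical_trees_return_the_tree(self):
        t = P.SimpleTree.from_newick("((A,B),(C,(D,E)));", taxa=tuple("ABCDE"))
        cons = P.strict_consensus([t, t.copy(), t.copy()])
        assert cons.bipartitions() == t.bipartitions()

    def test_single_nni_collapses_one_edge(self):
        t1 = P.SimpleTree.from_newick("(((A,B),C),(D,E));", taxa=tuple("ABCDE"))
        t2 = P.SimpleTree.from_newick("(((A,C),B),(D,E));", taxa=tuple("ABCDE"))
        cons = P.strict_consensus([t1, t2])
        assert cons.bipartitions() == t1.bipartitions() & t2.bipartitions()
        assert len(cons.bipartitions()) == len(t1.bipartitions()) - 1

    def test_matches_bipartition_intersection_oracle(self):
        taxa = tuple("ABCDEFGH")
        gen = P.SimpleTree.random_topology(taxa, np.random.default_rng(3))
        m, _ = hd.simulate_matrix(gen, 30, change_prob=0.12, n_states=2, seed=6)
        res = P.search(m, "branch_and_bound")
        cons = P.strict_consensus(res.trees)
        oracle = res.trees[0].bipartitions()
        for t in res.trees[1:]:
            oracle = oracle & t.bipartitions()
        assert cons.bipartitions() == oracle

    def test_leaf_set_mismatch_rejected(self):
        t1 = P.SimpleTree.from_newick("((A,B),(C,D));", taxa=tuple("ABCD"))
        t2 = P.SimpleTree.from_newick("((A,B),(C,E));", taxa=("A", "B", "C", "E"))
        with pytest.raises(P.StructureError):
            P.strict_consensus([t1, t2])
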