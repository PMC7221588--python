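import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact

from bdmshift.ancestral import AncestralStates, marginal_ancestral
from bdmshift.bdm import (
    BdmError,
    bdm_branch_test,
    branch_replacements,
    derive_bdm,
    fisher_one_tail,
    neighbor_branches,
    read_bdm_matrix,
)
from bdmshift.io import AMINO_ACIDS, ProteinAlignment, read_newick_string
from bdmshift.models import ScoreMatrix, load_blosum62

from oracles import fisher_tail_exact


class TestBdmDerivation:
    def test_diagonal_is_zero(self):
        bdm = derive_bdm()
        assert np.all(np.diag(bdm.scores) == 0)
        assert bdm.score("L", "L") == 0

    def test_aspartate_glutamate_is_seven(self):
        # hand lookup: s(D,D)=6, s(E,E)=5, s(D,E)=2 -> 6+5-2*2 = 7
        assert derive_bdm().score("D", "E") == 7

    def test_symmetric_and_nonnegative(self):
        bdm = derive_bdm()
        assert np.array_equal(bdm.scores, bdm.scores.T)
        assert np.all(bdm.scores >= 0)

    def test_matches_elementwise_formula(self):
        s = load_blosum62()
        bdm = derive_bdm(s)
        for a in "AWDEK":
            for b in "AWDEK":
                expected = s.score(a, a) + s.score(b, b) - 2 * s.score(a, b)
                assert bdm.score(a, b) == expected

    def test_asymmetric_input_rejected(self):
        scores = load_blosum62().scores.copy().astype(float)
        scores[0, 1] += 1
        with pytest.raises(BdmError):
            derive_bdm(ScoreMatrix(AMINO_ACIDS, scores))

    def test_user_matrix_roundtrip(self, tmp_path):
        bdm = derive_bdm()
        path = tmp_path / "custom.bdm"
        with open(path, "w") as fh:
            fh.write(" ".join(AMINO_ACIDS) + "\n")
            for i, a in enumerate(AMINO_ACIDS):
                fh.write(a + " " + " ".join(str(x) for x in bdm.scores[i]) + "\n")
        loaded = read_bdm_matrix(path)
        assert np.array_equal(loaded.scores, bdm.scores)
        assert loaded.provenance == "user-supplied"


class TestNeighborBranches:
    def test_fully_internal_focal_has_four_neighbors(self):
        # every branch adjacent to the focal one leads to another internal
        # node: parent-side branch, internal sibling, two internal children
        tree = read_newick_string(
            "(((((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1):1,(G:1,H:1):1):1,I:1);"
        )
        w = next(
            n
            for n in tree.postorder()
            if not n.is_leaf and all(not c.is_leaf for c in n.children)
            and n.parent is not None and n.parent.parent is not None
        )
        neighbors = neighbor_branches(tree, (w.parent, w))
        assert len(neighbors) == 4

    def test_leaf_incident_neighbors_excluded_with_warning(self):
        # two adjacent branches lead to leaves; only the internal sibling and
        # the internal child remain, and fewer than three neighbors warns
        tree = read_newick_string(
            "(((A:1,B:1):1,C:1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        )
        focal = tree.parse_branch(
            f"{tree.root.index}-{tree.root.children[0].index}"
        )
        with pytest.warns(UserWarning, match="only 2"):
            neighbors = neighbor_branches(tree, focal)
        assert len(neighbors) == 2

    def test_root_adjacent_branch_has_three_neighbors(self):
        # no parent-side branch above the root: internal sibling plus the
        # focal child's two internal children
        tree = read_newick_string(
            "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
        )
        focal = tree.parse_branch(
            f"{tree.root.index}-{tree.root.children[0].index}"
        )
        neighbors = neighbor_branches(tree, focal)
        assert len(neighbors) == 3

    def test_terminal_focal_rejected(self):
        tree = read_newick_string("((A:1,B:1):1,(C:1,D:1):1);")
        leaf_branch = next(
            (n.parent, n) for n in tree.postorder() if n.is_leaf
        )
        with pytest.raises(BdmError, match="terminal"):
            neighbor_branches(tree, leaf_branch)


def _states_for(tree, seqs, probs):
    """Hand-built AncestralStates for the internal nodes of a tree."""
    node_ids, post, map_state, map_prob = [], {}, {}, {}
    for node in tree.postorder():
        if node.is_leaf or node.index not in seqs:
            continue
        seq = seqs[node.index]
        p = np.asarray(probs[node.index], dtype=float)
        node_ids.append(node.index)
        map_state[node.index] = np.array(list(seq))
        map_prob[node.index] = p
        post[node.index] = np.zeros((len(seq), 20))
    return AncestralStates(node_ids, post, map_state, map_prob)


class TestBranchReplacements:
    @pytest.fixture
    def little_tree(self):
        return read_newick_string("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")

    def test_identical_confident_endpoints_count_zero(self, little_tree):
        tree = little_tree
        inner = [n for n in tree.postorder() if not n.is_leaf and n.parent]
        parent, child = inner[-1].parent or tree.root, inner[0]
        parent, child = child.parent, child
        seqs = {parent.index: "ADE", child.index: "ADE"}
        probs = {parent.index: [0.9] * 3, child.index: [0.9] * 3}
        anc = _states_for(tree, seqs, probs)
        aln = ProteinAlignment(names=list("ABCDEF"), rows=["ADE"] * 6)
        reps = branch_replacements(anc, aln, tree, (parent, child), derive_bdm(), 0.5)
        assert reps.R == 0 and reps.BDM == 0

    def test_single_confident_replacement_scores_bdm(self, little_tree):
        tree = little_tree
        child = next(n for n in tree.postorder() if not n.is_leaf and n.parent)
        parent = child.parent
        seqs = {parent.index: "ADE", child.index: "AEE"}
        probs = {parent.index: [0.9, 0.9, 0.9], child.index: [0.9, 0.8, 0.9]}
        anc = _states_for(tree, seqs, probs)
        aln = ProteinAlignment(names=list("ABCDEF"), rows=["ADE"] * 6)
        reps = branch_replacements(anc, aln, tree, (parent, child), derive_bdm(), 0.5)
        assert reps.R == 1
        assert reps.BDM == 7  # D->E under the BLOSUM62-derived scores
        assert reps.sites[0].site == 2

    def test_low_confidence_site_excluded(self, little_tree):
        tree = little_tree
        child = next(n for n in tree.postorder() if not n.is_leaf and n.parent)
        parent = child.parent
        seqs = {parent.index: "ADE", child.index: "AEE"}
        probs = {parent.index: [0.9, 0.4, 0.9], child.index: [0.9, 0.9, 0.9]}
        anc = _states_for(tree, seqs, probs)
        aln = ProteinAlignment(names=list("ABCDEF"), rows=["ADE"] * 6)
        reps = branch_replacements(anc, aln, tree, (parent, child), derive_bdm(), 0.5)
        assert reps.R == 0

    def test_threshold_is_strict_at_exactly_half(self, little_tree):
        tree = little_tree
        child = next(n for n in tree.postorder() if not n.is_leaf and n.parent)
        parent = child.parent
        seqs = {parent.index: "D", child.index: "E"}
        probs = {parent.index: [0.5], child.index: [0.9]}
        anc = _states_for(tree, seqs, probs)
        aln = ProteinAlignment(names=list("ABCDEF"), rows=["D"] * 6)
        strict = branch_replacements(anc, aln, tree, (parent, child), derive_bdm(), 0.5)
        assert strict.R == 0
        inclusive = branch_replacements(
            anc, aln, tree, (parent, child), derive_bdm(), 0.5, inclusive=True
        )
        assert inclusive.R == 1

    def test_site_order_invariance_of_sums(self, little_tree):
        tree = little_tree
        child = next(n for n in tree.postorder() if not n.is_leaf and n.parent)
        parent = child.parent
        rng = np.random.default_rng(0)
        L = 30
        sp = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        sc = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        perm = rng.permutation(L)
        anc1 = _states_for(
            tree,
            {parent.index: sp, child.index: sc},
            {parent.index: [0.9] * L, child.index: [0.9] * L},
        )
        anc2 = _states_for(
            tree,
            {parent.index: "".join(sp[i] for i in perm),
             child.index: "".join(sc[i] for i in perm)},
            {parent.index: [0.9] * L, child.index: [0.9] * L},
        )
        aln = ProteinAlignment(names=list("ABCDEF"), rows=["A" * L] * 6)
        r1 = branch_replacements(anc1, aln, tree, (parent, child), derive_bdm(), 0.5)
        r2 = branch_replacements(anc2, aln, tree, (parent, child), derive_bdm(), 0.5)
        assert r1.R == r2.R and r1.BDM == r2.BDM


class TestFisherOneTail:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[1714, 130], [719, 79]], 0.01),
            ([[719, 54], [453, 41]], 0.22),
            ([[1656, 126], [1483, 112]], 0.55),
        ],
    )
    def test_reported_branch_contrasts(self, table, expected):
        assert round(fisher_one_tail(table), 2) == expected

    def test_agrees_with_scipy_greater_tail(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 200, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            mine = fisher_one_tail([[a, b], [c, d]])
            ref = fisher_exact([[a, b], [c, d]], alternative="greater").pvalue
            assert mine == pytest.approx(ref, rel=1e-10)

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    @settings(max_examples=200, derandomize=True)
    def test_agrees_with_exact_integer_enumeration(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        assert fisher_one_tail([[a, b], [c, d]]) == pytest.approx(
            fisher_tail_exact(a, b, c, d), rel=1e-12
        )

    def test_tail_consistency_identity(self):
        # P(X >= a) + P(X <= a) = 1 + P(X = a); swapping rows flips the tail
        for table in ([[3, 5], [7, 2]], [[1, 1], [1, 1]], [[10, 0], [3, 9]]):
            (a, b), (c, d) = table
            upper = fisher_one_tail([[a, b], [c, d]])
            lower = fisher_one_tail([[c, d], [a, b]])
            point = fisher_tail_exact(a, b, c, d) - (
                fisher_tail_exact(a + 1, b - 1, c - 1, d + 1)
                if b > 0 and c > 0
                else 0.0
            )
            assert upper + lower == pytest.approx(1 + point, rel=1e-10)

    def test_doubling_counts_sharpens_enrichment(self):
        table = [[40, 10], [20, 20]]  # odds ratio > 1
        p1 = fisher_one_tail(table)
        p2 = fisher_one_tail([[2 * x for x in row] for row in table])
        assert p2 <= p1

    def test_negative_cell_rejected(self):
        with pytest.raises(BdmError):
            fisher_one_tail([[-1, 2], [3, 4]])

    def test_empty_margin_rejected(self):
        with pytest.raises(BdmError):
            fisher_one_tail([[0, 0], [3, 4]])


class TestBranchContrast:
    def test_balanced_table_is_not_significant(self):
        # identical BDM-per-replacement on both sides with large counts
        p = fisher_one_tail([[1000, 100], [1000, 100]])
        assert 0.4 <= p <= 0.6

    def test_full_contrast_on_simulated_family(self, wag, gamma2):
        from bdmshift.simulate import SimConfig, central_internal_branch, simulate_alignment

        cfg = SimConfig(seed=21)
        aln, truth = simulate_alignment(cfg)
        anc = marginal_ancestral(aln, truth.tree, wag, gamma2)
        focal = central_internal_branch(truth.tree)
        result = bdm_branch_test(anc, aln, truth.tree, focal)
        assert result.R1 == len(result.focal_replacements.sites)
        assert result.BDM2 == pytest.approx(
            sum(r.BDM for r in result.neighbor_replacements)
        )
        assert 0.0 <= result.p_value <= 1.0
        assert result.table[0][0] == round(result.BDM1)

    def test_no_replacements_yields_na(self):
        tree = read_newick_string("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")
        child = next(n for n in tree.postorder() if not n.is_leaf and n.parent)
        parent = child.parent
        anc = _states_for(
            tree,
            {n.index: "A" for n in tree.postorder() if not n.is_leaf},
            {n.index: [0.9] for n in tree.postorder() if not n.is_leaf},
        )
        aln = ProteinAlignment(names=list("ABCDEF"), rows=["A"] * 6)
        result = bdm_branch_test(anc, aln, tree, (parent, child))
        assert result.p_value is None
        assert "undefined" in result.note
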