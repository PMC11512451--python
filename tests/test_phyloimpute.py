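import numpy as np
import pytest

from opsinpred.encode import alignment_from_records
from opsinpred.phyloimpute import (
    ComparisonResult,
    PhyloTree,
    TreeError,
    bm_vcv,
    compare_ml_vs_imputation,
    impute_bm,
)
from opsinpred.synthdata import StudyConfig, generate_study, simulate_bm, simulate_tree


def random_tree(n_tips, seed):
    """Yule topology with branch lengths jittered away from ultrametricity."""
    tree = simulate_tree(n_tips, seed=seed)
    rng = np.random.default_rng(seed + 1000)
    for edge in tree.tree.preorder_edge_iter():
        if edge.length:
            edge.length = float(edge.length * rng.uniform(0.3, 2.0) + 0.01)
    return tree


def brute_force_conditional(tree, observed, missing):
    """Independent oracle: assemble the joint covariance from explicit
    root-to-tip edge sets and condition the multivariate normal directly."""
    t = tree.tree
    paths = {}
    for leaf in t.leaf_node_iter():
        edges = []
        node = leaf
        while node.parent_node is not None:
            edges.append((id(node), node.edge.length))
            node = node.parent_node
        paths[leaf.taxon.label] = edges
    labels = sorted(paths)
    n = len(labels)
    C = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            ids_b = {e for e, _ in paths[b]}
            C[i, j] = sum(l for e, l in paths[a] if e in ids_b)
    o = [i for i, l in enumerate(labels) if l in observed]
    mi = [i for i, l in enumerate(labels) if l in missing]
    y = np.array([observed[labels[i]] for i in o])
    Coo_inv = np.linalg.inv(C[np.ix_(o, o)])
    ones = np.ones(len(o))
    mu = (ones @ Coo_inv @ y) / (ones @ Coo_inv @ ones)
    cond = mu + C[np.ix_(mi, o)] @ Coo_inv @ (y - mu)
    return {labels[i]: v for i, v in zip(mi, cond)}


class TestBmVcv:
    def test_two_tips_from_root(self):
        tree = PhyloTree.from_newick("(A:1.5,B:2.5);")
        C, labels = bm_vcv(tree)
        i, j = labels.index("A"), labels.index("B")
        assert C[i, i] == pytest.approx(1.5)
        assert C[j, j] == pytest.approx(2.5)
        assert C[i, j] == 0.0

    def test_three_tip_hand_trace(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        C, labels = bm_vcv(tree)
        idx = {l: i for i, l in enumerate(labels)}
        assert C[idx["A"], idx["A"]] == pytest.approx(2.0)
        assert C[idx["B"], idx["B"]] == pytest.approx(2.0)
        assert C[idx["A"], idx["B"]] == pytest.approx(1.0)
        assert C[idx["A"], idx["C"]] == 0.0
        assert C[idx["C"], idx["C"]] == pytest.approx(2.0)

    def test_star_tree_is_scaled_identity(self):
        tree = PhyloTree.from_newick("(A:2,B:2,C:2,D:2);")
        C, _ = bm_vcv(tree)
        assert np.allclose(C, 2.0 * np.eye(4))

    def test_symmetric_positive_semidefinite(self):
        for seed in range(5):
            tree = random_tree(7, seed)
            C, _ = bm_vcv(tree)
            assert np.allclose(C, C.T)
            assert np.linalg.eigvalsh(C).min() > -1e-10

    def test_terminal_branch_extension_hits_diagonal_only(self):
        tree_a = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        tree_b = PhyloTree.from_newick("((A:1.7,B:1.7):1,C:2.7);")
        Ca, la = bm_vcv(tree_a)
        Cb, lb = bm_vcv(tree_b)
        assert la == lb
        off_diag = ~np.eye(3, dtype=bool)
        assert np.allclose(Ca[off_diag], Cb[off_diag])
        assert np.allclose(np.diag(Cb) - np.diag(Ca), 0.7)


class TestImputeBm:
    def test_star_tree_imputes_mean_of_observed(self):
        tree = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        res = impute_bm(tree, {"A": 500.0, "B": 510.0, "C": 523.0})
        assert res.means["D"] == pytest.approx((500 + 510 + 523) / 3)

    def test_short_cherry_tracks_sister_tip(self):
        tree = PhyloTree.from_newick("((A:0.0001,B:0.0001):1,C:1.0001);")
        res = impute_bm(tree, {"A": 520.0, "C": 480.0})
        assert res.means["B"] == pytest.approx(520.0, abs=0.1)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_conditioning(self, seed):
        tree = random_tree(6, seed)
        rng = np.random.default_rng(seed)
        tips = tree.tip_labels
        values = dict(zip(tips, 500 + 20 * rng.standard_normal(len(tips))))
        missing = set(rng.choice(tips, size=2, replace=False).tolist())
        observed = {t: v for t, v in values.items() if t not in missing}
        res = impute_bm(tree, observed)
        oracle = brute_force_conditional(tree, observed, missing)
        for tip in missing:
            assert res.means[tip] == pytest.approx(oracle[tip], abs=1e-8)

    def test_translation_equivariance(self):
        tree = random_tree(8, 99)
        rng = np.random.default_rng(0)
        tips = tree.tip_labels
        observed = {t: float(500 + rng.normal(0, 10)) for t in tips[:-2]}
        base = impute_bm(tree, observed)
        shifted = impute_bm(tree, {t: v + 37.0 for t, v in observed.items()})
        for tip in base.means:
            assert shifted.means[tip] == pytest.approx(base.means[tip] + 37.0)

    def test_no_missing_tips_gives_empty_result(self):
        tree = PhyloTree.from_newick("(A:1,B:1);")
        res = impute_bm(tree, {"A": 500.0, "B": 510.0})
        assert res.means == {} and res.variances == {}

    def test_bad_partition_rejected(self):
        tree = PhyloTree.from_newick("(A:1,B:1,C:1);")
        with pytest.raises(TreeError, match="partition"):
            impute_bm(tree, {"A": 500.0}, missing={"B"})

    def test_duplicate_zero_length_tips_ridge_warns(self):
        tree = PhyloTree.from_newick("((A:0,B:0):1,C:1);")
        with pytest.warns(UserWarning, match="ridge"):
            res = impute_bm(tree, {"A": 500.0, "B": 502.0})
        assert 490 < res.means["C"] < 512

    def test_conditional_variances_non_negative(self):
        tree = random_tree(7, 5)
        tips = tree.tip_labels
        observed = {t: 500.0 + i for i, t in enumerate(tips[:-3])}
        res = impute_bm(tree, observed)
        assert all(v >= 0 for v in res.variances.values())


class TestTreeValidation:
    def test_negative_branch_rejected(self):
        with pytest.raises(TreeError, match="bad branch length"):
            PhyloTree.from_newick("(A:1,B:-0.5);")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(TreeError):
            PhyloTree.from_newick("(A:1,A:1);")


class TestCompareMlVsImputation:
    def test_single_holdout_emits_one_prediction_each(self, small_study):
        res = compare_ml_vs_imputation(
            small_study.dataset, small_study.alignment, small_study.tree,
            holdout_n=1, estimator="ridge", seed=0,
        )
        assert isinstance(res, ComparisonResult)
        assert len(res.table) == 1

    def test_pure_brownian_trait_favors_imputation(self):
        """A strongly phylogenetic trait over nearly uninformative sequences:
        the tree is the only real signal, so imputation should win most
        splits."""
        wins = 0
        for seed in range(5):
            cfg = StudyConfig(
                n_tips=40, L=60, rate=0.05, n_effect_sites=0, n_interactions=0,
                sigma_phylo2=400.0, sigma_e=1.0, min_minor_count=4,
                n_mutant_parents=0, epistatic_trio_parents=0, pair_double_parents=0,
            )
            study = generate_study(cfg, seed=seed)
            res = compare_ml_vs_imputation(
                study.dataset, study.alignment, study.tree,
                holdout_n=8, estimator="ridge", seed=seed,
            )
            wins += res.imputation.mae < res.ml.mae
        assert wins >= 3

    def test_pure_additive_trait_favors_ml(self):
        """Large additive site effects with no Brownian component: sequence
        features carry the signal directly, so regression should win most
        splits (the trait still has phylogenetic structure because residues
        are inherited, which keeps imputation competitive)."""
        wins = 0
        for seed in range(5):
            cfg = StudyConfig(
                n_tips=60, L=60, n_effect_sites=4, effect_range_nm=(15.0, 25.0),
                n_interactions=0, sigma_phylo2=0.0, sigma_e=1.0, min_minor_count=6,
                n_mutant_parents=0, epistatic_trio_parents=0, pair_double_parents=0,
            )
            study = generate_study(cfg, seed=seed)
            res = compare_ml_vs_imputation(
                study.dataset, study.alignment, study.tree,
                holdout_n=10, estimator="gbr", seed=seed,
            )
            wins += res.ml.mae < res.imputation.mae
        assert wins >= 3

    def test_tree_tip_missing_from_dataset(self, small_study):
        ds = small_study.dataset
        pruned = ds.with_records(ds.records[1:])
        with pytest.raises(TreeError, match="missing from dataset"):
            compare_ml_vs_imputation(
                pruned, small_study.alignment, small_study.tree,
                holdout_n=2, estimator="ridge", seed=0,
            )
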