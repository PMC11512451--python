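import itertools

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from opsinpred.epistasis import (
    bonferroni,
    cases_to_frame,
    classify_epistatic,
    eamv,
    find_decomposable_multimutants,
    leave_epistatic_out,
    wilcoxon_signed_rank,
)
from opsinpred.seqdata import Dataset
from opsinpred.synthdata import (
    StudyConfig,
    TruthModel,
    generate_study,
    spawn_mutants,
)
from opsinpred.mutagen import apply_mutations, parse_mutation_notation

from conftest import make_record


class TestEamv:
    def test_no_singles_returns_wild_type(self):
        assert eamv(500.0, []) == 500.0

    def test_shifts_add(self):
        # singles at 514 (+14) and 502 (+2) from a 500 nm wild type
        assert eamv(500.0, [514.0, 502.0]) == pytest.approx(516.0)

    def test_symmetric_cancellation(self):
        assert eamv(500.0, [495.0, 505.0]) == pytest.approx(500.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        singles = list(rng.uniform(480, 560, size=5))
        assert eamv(500.0, singles) == pytest.approx(eamv(500.0, singles[::-1]))


class TestClassifyEpistatic:
    def test_two_nm_deviation_is_epistatic(self):
        assert classify_epistatic(514.0, 516.0)

    def test_zero_deviation_is_not(self):
        assert not classify_epistatic(516.0, 516.0)

    def test_exactly_one_nm_is_not(self):
        assert not classify_epistatic(515.0, 516.0)

    def test_sign_symmetric(self):
        assert classify_epistatic(514.0, 516.5) == classify_epistatic(519.0, 516.5)


class TestFindDecomposable:
    def test_full_trio_found(self, epistasis_toy):
        cases = find_decomposable_multimutants(epistasis_toy)
        assert len(cases) == 1
        case = cases[0]
        assert len(case.single_records) == 2
        assert case.eamv == pytest.approx(516.0)
        assert case.deviation == pytest.approx(2.0)
        assert case.is_epistatic

    def test_missing_single_no_case(self, epistasis_toy):
        pruned = Dataset(records=[r for r in epistasis_toy if r.accession != "m_c4s"])
        assert find_decomposable_multimutants(pruned) == []

    def test_triple_mutant_with_three_singles(self):
        wt = make_record("wt1", "MDACVA", 500.0)
        singles = [
            make_record(f"s{i}", apply_mutations("MDACVA", parse_mutation_notation(n)),
                        500.0 + d, record_type="mutant", mutation_notation=n,
                        parent_accession="wt1")
            for i, (n, d) in enumerate([("D2N", 5.0), ("C4S", -3.0), ("A6V", 2.0)])
        ]
        triple = make_record(
            "t1", "MNASVV", 510.0, record_type="mutant",
            mutation_notation="D2N_C4S_A6V", parent_accession="wt1",
        )
        cases = find_decomposable_multimutants(Dataset(records=[wt, *singles, triple]))
        assert len(cases) == 1
        assert len(cases[0].single_records) == 3
        assert cases[0].eamv == pytest.approx(504.0)

    def test_unparseable_notation_warns_and_skips(self, epistasis_toy):
        bad = make_record(
            "bad", "MDAAVA", 505.0, record_type="mutant",
            mutation_notation="C4?A", parent_accession="wt1",
        )
        ds = Dataset(records=list(epistasis_toy.records) + [bad])
        with pytest.warns(UserWarning, match="unparseable"):
            cases = find_decomposable_multimutants(ds)
        assert len(cases) == 1

    def test_cross_background_singles_not_matched(self, epistasis_toy):
        # same single-edit notation under a different parent must not count
        records = [r for r in epistasis_toy if r.accession != "m_c4s"]
        other_wt = make_record("wt2", "MDACVC", 490.0)
        foreign = make_record(
            "m_c4s_other", "MDASVC", 493.0, record_type="mutant",
            mutation_notation="C4S", parent_accession="wt2",
        )
        ds = Dataset(records=records + [other_wt, foreign])
        assert find_decomposable_multimutants(ds) == []


class TestWilcoxon:
    def test_all_positive_fixture(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert res.statistic == 6.0
        assert res.p_two_sided == pytest.approx(0.25)
        assert res.method == "exact"

    def test_mixed_sign_fixture(self):
        res = wilcoxon_signed_rank([1.0, -2.0, 3.0])
        assert res.statistic == 4.0
        assert res.p_two_sided == pytest.approx(0.75)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0, 0.0])

    def test_zeros_dropped_before_ranking(self):
        with_zeros = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0, 0.0])
        without = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert with_zeros.n_effective == 3
        assert with_zeros.p_two_sided == pytest.approx(without.p_two_sided)

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        d = rng.integers(-5, 6, size=n).astype(float)
        d = d[d != 0]
        if d.size == 0:
            d = np.array([1.0])
        res = wilcoxon_signed_rank(d)
        ranks = rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        stats = [
            sum(r for r, s in zip(ranks, signs) if s > 0)
            for signs in itertools.product([-1, 1], repeat=d.size)
        ]
        stats = np.array(stats)
        p_le = np.mean(stats <= w_obs)
        p_ge = np.mean(stats >= w_obs)
        expected = min(1.0, 2.0 * min(p_le, p_ge))
        assert res.p_two_sided == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_exact_on_untied_data(self):
        rng = np.random.default_rng(3)
        d = rng.normal(1.0, 2.0, size=12)
        ours = wilcoxon_signed_rank(d)
        ref = scipy_wilcoxon(d, alternative="two-sided", method="exact")
        assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_close_to_scipy(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.5, 2.0, size=60)
        ours = wilcoxon_signed_rank(d)
        assert ours.method == "normal-approx"
        ref = scipy_wilcoxon(d, alternative="two-sided", method="approx", correction=True)
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-6)

    def test_bonferroni_adjustment_attached(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], m=3)
        assert res.p_adjusted == pytest.approx(min(1.0, 3 * res.p_two_sided))


class TestBonferroni:
    def test_simple(self):
        assert bonferroni([0.01, 0.03], m=2) == pytest.approx([0.02, 0.06])

    def test_capped_at_one(self):
        assert bonferroni([0.9], m=3) == [1.0]

    def test_m_one_is_identity(self):
        assert bonferroni([0.2], m=1) == [0.2]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bonferroni([1.5], m=2)

    def test_m_smaller_than_list_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            bonferroni([0.1, 0.2, 0.3], m=2)


class TestLeaveEpistaticOut:
    def test_training_excludes_epistatic_multimutants(self, small_study):
        res = leave_epistatic_out(small_study.dataset, estimator="xgb", seed=0)
        assert len(res.table) > 0
        assert set(res.metrics) == {"pred_minusepi", "pred_wt_only", "eamv"}
        # the targets really are the epistatic multimutants, predicted once each
        assert res.table["accession"].is_unique

    def test_no_epistatic_cases_rejected(self, epistasis_toy):
        pruned = Dataset(records=[r for r in epistasis_toy if r.accession != "m_dbl"])
        with pytest.raises(ValueError, match="no epistatic"):
            leave_epistatic_out(pruned)

    def test_zero_interactions_mean_zero_truth_deviation(self):
        """Without planted interactions the truth model is additive: every
        multimutant's phenotype equals its EAMV exactly."""
        cfg = StudyConfig(n_tips=40, L=80, n_interactions=0, min_minor_count=4,
                          epistatic_trio_parents=0, pair_double_parents=0)
        study = generate_study(cfg, seed=5)
        wt = study.dataset.records[0]
        muts = spawn_mutants(wt, study.truth, n=10, max_edits=3, seed=1)
        for m in muts:
            spec = parse_mutation_notation(m.mutation_notation)
            singles = []
            for e in spec.edits:
                seq = apply_mutations(wt.aa_seq, parse_mutation_notation(str(e)))
                lam = wt.lambda_max + study.truth.genetic_value(seq) - study.truth.genetic_value(wt.aa_seq)
                singles.append(lam)
            assert m.lambda_max == pytest.approx(eamv(wt.lambda_max, singles), abs=1e-9)

    def test_planted_interaction_recovery_beats_additive_baseline(self, small_study):
        """A model that keeps single mutants in training predicts epistatic
        multimutants better than the additive EAMV expectation."""
        res = leave_epistatic_out(small_study.dataset, estimator="xgb", seed=0)
        frame = cases_to_frame(find_decomposable_multimutants(small_study.dataset))
        assert frame["is_epistatic"].any()
        assert res.metrics["pred_minusepi"].rmse < res.metrics["eamv"].rmse
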