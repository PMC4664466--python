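"""MDR cell classification, cross-validated search, and permutation p."""

import itertools

import numpy as np
import pytest

from conftest import oracle_cell_labels, oracle_fold_search
from mdrpipe.io_tables import MISSING, GenotypeMatrix, SnpMeta
from mdrpipe.mdr import (
    _CvEngine,
    balanced_accuracy,
    classify_cells,
    cross_validated_search,
    empirical_p,
    permutation_test,
    run_mdr,
    stratified_folds,
)
from mdrpipe.synthetic import PenetranceModel, SimConfig, fixture_small, simulate


def _gm(codes):
    codes = np.asarray(codes, dtype=np.int8)
    snps = [SnpMeta(f"rs{j}", "A", "G") for j in range(codes.shape[1])]
    return GenotypeMatrix([f"s{i}" for i in range(codes.shape[0])], snps, codes)


class TestClassifyCells:
    def test_majority_case_cell_high(self):
        codes = np.array([[0]] * 4, dtype=np.int8)
        y = np.array([1, 1, 1, 0])
        high, *_ = classify_cells(codes, y, t=1.0)
        assert high[0]  # 3 cases : 1 control >= 1

    def test_boundary_ratio_is_high(self):
        codes = np.array([[0]] * 4, dtype=np.int8)
        y = np.array([1, 1, 0, 0])
        high, *_ = classify_cells(codes, y, t=1.0)
        assert high[0]  # exactly T counts as high

    def test_empty_cell_low_and_case_only_cell_high(self):
        codes = np.array([[0], [2]], dtype=np.int8)
        y = np.array([1, 0])
        high, *_ = classify_cells(codes, y, t=1.0)
        assert high[0] and not high[1] and not high[2]

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(8, 51))
            k = int(rng.integers(1, 3))
            codes = rng.integers(0, 3, size=(n, k)).astype(np.int8)
            codes[rng.random((n, k)) < 0.1] = MISSING
            y = (rng.random(n) < 0.35).astype(int)
            if y.sum() == 0 or y.sum() == n:
                continue
            valid = (codes != MISSING).all(axis=1)
            if (y[valid] == 0).sum() == 0 or (y[valid] == 1).sum() == 0:
                continue
            high, *_ = classify_cells(codes, y)
            expected, _, _ = oracle_cell_labels(codes, y)
            assert set(np.flatnonzero(high)) == expected

    def test_unbalanced_design_threshold(self):
        # with a 226:575-shaped imbalance the default threshold is the
        # case:control ratio, so a cell at population rates is low risk
        rng = np.random.default_rng(23)
        n_cases, n_ctrl = 226, 575
        codes = np.concatenate(
            [rng.integers(0, 3, n_cases + n_ctrl)]
        ).reshape(-1, 1).astype(np.int8)
        y = np.array([1] * n_cases + [0] * n_ctrl)
        high, case_counts, ctrl_counts, t = classify_cells(codes, y)
        assert t == pytest.approx(n_cases / n_ctrl)
        expected, case_or, ctrl_or = oracle_cell_labels(codes, y)
        assert set(np.flatnonzero(high)) == expected


class TestBalancedAccuracy:
    def test_perfect_separation(self):
        y = np.array([1, 1, 0, 0])
        assert balanced_accuracy(np.array([1, 1, 0, 0]), y) == 1.0

    def test_all_high_is_half(self):
        y = np.array([1, 1, 0, 0])
        assert balanced_accuracy(np.ones(4), y) == 0.5

    def test_formula(self):
        # sens 0.8 (4/5 cases), spec 0.6 (3/5 controls) -> 0.7
        y = np.array([1] * 5 + [0] * 5)
        pred = np.array([1, 1, 1, 1, 0, 1, 1, 0, 0, 0])
        assert balanced_accuracy(pred, y) == pytest.approx(0.7)

    def test_prevalence_invariance_by_control_duplication(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 30 + [0] * 50)
        pred = rng.integers(0, 2, size=80)
        ba = balanced_accuracy(pred, y)
        y_dup = np.concatenate([y, np.zeros(50, int)])
        pred_dup = np.concatenate([pred, pred[30:]])
        assert balanced_accuracy(pred_dup, y_dup) == pytest.approx(ba)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            balanced_accuracy(np.array([1, 0]), np.array([1, 1]))


class TestCrossValidatedSearch:
    def test_perfect_snp_wins_every_fold(self, small_dataset):
        gm, pheno, truth = small_dataset
        res = cross_validated_search(gm, pheno.status, k=1, n_folds=5, seed=0)
        assert res.loci == (truth["perfect_snp"],)
        assert res.cvc == 5
        assert res.avg_testing_ba == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_small_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            n = int(rng.integers(16, 51))
            m = int(rng.integers(2, 5))
            k = int(rng.integers(1, min(m, 3) + 1))
            codes = rng.integers(0, 3, size=(n, m)).astype(np.int8)
            codes[rng.random((n, m)) < 0.05] = MISSING
            y = np.zeros(n, dtype=int)
            y[rng.choice(n, size=max(4, n // 3), replace=False)] = 1
            n_folds = 4
            folds = stratified_folds(y, n_folds, rng)
            engine = _CvEngine(codes, folds, k)
            _, _, _, winners = engine.search(y)
            oracle_winners, oracle_tr, oracle_te = oracle_fold_search(
                codes, folds, y, engine.sets, n_folds
            )
            assert np.array_equal(winners, oracle_winners)
            tr, te = engine.evaluate(y)
            assert np.allclose(tr, oracle_tr, equal_nan=True, atol=1e-12)
            assert np.allclose(te, oracle_te, equal_nan=True, atol=1e-12)

    def test_two_fold_toy_instance(self):
        # 4 samples, 2 SNPs, 2 folds: fully enumerable by hand/oracle
        codes = np.array([[0, 2], [2, 0], [0, 2], [2, 0]], dtype=np.int8)
        y = np.array([1, 0, 1, 0])
        folds = np.array([0, 0, 1, 1])
        engine = _CvEngine(codes, folds, k=1)
        _, _, _, winners = engine.search(y)
        oracle_winners, _, _ = oracle_fold_search(codes, folds, y, engine.sets, 2)
        assert np.array_equal(winners, oracle_winners)
        best, cvc, mean_te, _ = engine.search(y)
        assert cvc == 2 and mean_te == pytest.approx(1.0)

    def test_null_testing_ba_near_half(self):
        # pure-noise SNPs: the selected model's mean testing BA sits around
        # 0.5 (small upward selection bias shrinks with n)
        bas = []
        for rep in range(12):
            cfg = SimConfig(n_cases=300, n_controls=300, n_snps=6,
                            missing_rate=0.0, seed=600 + rep)
            gm, pheno, _ = simulate(cfg)
            res = cross_validated_search(gm, pheno.status, k=2, n_folds=20, seed=rep)
            bas.append(res.avg_testing_ba)
        assert abs(np.mean(bas) - 0.5) <= 0.05

    def test_cvc_bounded_by_folds(self):
        gm, pheno, _ = fixture_small(seed=1)
        res = cross_validated_search(gm, pheno.status, k=2, n_folds=5, seed=3)
        assert 0 <= res.cvc <= 5

    def test_too_few_snps_errors(self):
        gm, pheno, _ = fixture_small(seed=0)
        with pytest.raises(ValueError):
            cross_validated_search(gm, pheno.status, k=2, n_folds=5,
                                   snp_ids=["rs000001"])


class TestPermutation:
    def test_add_one_estimator(self):
        permuted = np.linspace(0.6, 0.9, 19)
        assert empirical_p(0.5, permuted) == pytest.approx(1.0)   # below all 19
        assert empirical_p(0.95, permuted) == pytest.approx(0.05)  # above all 19
        # 10 of the 19 permuted values lie at or above 0.75
        assert empirical_p(0.75, permuted) == pytest.approx((1 + 10) / 20)

    def test_invalid_n_perm(self, small_dataset):
        gm, pheno, _ = small_dataset
        with pytest.raises(ValueError):
            permutation_test(gm, pheno.status, k=1, n_perm=0, n_folds=5)

    def test_planted_effect_detected(self, small_dataset):
        gm, pheno, _ = small_dataset
        p, res = permutation_test(gm, pheno.status, k=1, n_perm=99, n_folds=5, seed=0)
        assert p <= 0.05
        assert res.loci == ("rs000001",)

    def test_strong_two_locus_effect_detected(self):
        hits, reps = 0, 15
        for rep in range(reps):
            cfg = SimConfig(
                n_cases=150, n_controls=150, n_snps=8, missing_rate=0.0,
                penetrance=PenetranceModel.xor_two_locus((0, 1), p_high=0.6, p_low=0.15),
                maf_overrides={0: 0.3, 1: 0.4}, seed=700 + rep,
            )
            gm, pheno, _ = simulate(cfg)
            p, _ = permutation_test(gm, pheno.status, k=2, n_perm=200,
                                    n_folds=10, seed=rep)
            if p <= 0.05:
                hits += 1
        assert hits >= 14  # power ~> 95%


class TestRunMdr:
    def test_planted_pair_only_k2_significant(self):
        cfg = SimConfig(
            n_cases=226, n_controls=574, n_snps=8, missing_rate=0.0,
            penetrance=PenetranceModel.xor_two_locus((0, 1)),
            maf_overrides={0: 0.3, 1: 0.4}, seed=42,
        )
        gm, pheno, truth = simulate(cfg)
        report = run_mdr(gm, pheno.status, ks=(1, 2), n_folds=20, n_perm=199, seed=0)
        assert report.significant[2]
        assert set(report.results[2].loci) == set(truth["penetrance"]["loci"])

    def test_null_type_one_error_bounded(self):
        # per-k rejection stays near the nominal level; the any-k union is
        # bounded by the sum of the levels
        reps, any_k, per_k = 40, 0, {1: 0, 2: 0}
        for rep in range(reps):
            cfg = SimConfig(n_cases=60, n_controls=90, n_snps=6,
                            missing_rate=0.0, seed=900 + rep)
            gm, pheno, _ = simulate(cfg)
            report = run_mdr(gm, pheno.status, ks=(1, 2), n_folds=10,
                             n_perm=99, seed=rep)
            if any(report.significant.values()):
                any_k += 1
            for k in (1, 2):
                per_k[k] += int(report.significant[k])
        for k in (1, 2):
            assert per_k[k] / reps <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)
        assert any_k / reps <= 0.10 + 2 * np.sqrt(0.10 * 0.90 / reps)

    def test_perfect_snp_flagged_significant(self, small_dataset):
        gm, pheno, _ = small_dataset
        report = run_mdr(gm, pheno.status, ks=(1,), n_folds=5, n_perm=99, seed=0)
        assert report.significant[1]
        assert report.results[1].avg_testing_ba == pytest.approx(1.0)
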