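"""Statistical battery: Pearson, Bonferroni, AUC, permutation p-values,
and the dataset-level screen with family-wise correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vqnorm import (
    PermutationSpec,
    bonferroni_adjust,
    evaluate_dataset,
    pearson_association,
    permutation_auc_pvalue,
    roc_auc,
)
from vqnorm.associations import results_to_frame, significant_effect_matrix


class TestPearson:
    def test_perfect_positive_linear(self):
        x = np.arange(10.0)
        r, p = pearson_association(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-9

    def test_perfect_negative(self):
        x = np.arange(10.0)
        r, _ = pearson_association(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_longhand_formula(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r, p = pearson_association(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        t = r_hand * np.sqrt(18 / (1 - r_hand**2))
        p_hand = 2 * stats.t.sf(abs(t), df=18)
        assert abs(r - r_hand) < 1e-12
        assert abs(p - p_hand) < 1e-12

    def test_zero_variance_fails(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_association(np.ones(5), np.arange(5.0))

    def test_too_short_fails(self):
        with pytest.raises(ValueError, match="at least 3"):
            pearson_association(np.arange(2.0), np.arange(2.0))


class TestBonferroni:
    def test_scalar_examples(self):
        assert bonferroni_adjust([0.01], 5)[0] == pytest.approx(0.05)
        assert bonferroni_adjust([0.5], 10)[0] == 1.0  # capped

    def test_vector_matches_scalar_map(self, rng):
        p = rng.random(12)
        vec = bonferroni_adjust(p, 20)
        np.testing.assert_array_equal(vec, [bonferroni_adjust([x], 20)[0] for x in p])

    def test_order_preserving(self, rng):
        p = np.sort(rng.random(10) * 0.04)
        corr = bonferroni_adjust(p, 10)
        assert np.all(np.diff(corr) >= 0)

    def test_family_smaller_than_pvalues_fails(self):
        with pytest.raises(ValueError, match="family size"):
            bonferroni_adjust([0.1, 0.2, 0.3], 2)


class TestAUC:
    def test_perfect_separation(self):
        # typicality scores: cases lower -> AUC 1 under the fixed orientation
        scores = np.r_[np.full(5, 0.2), np.full(5, 0.8)]
        labels = np.r_[np.ones(5), np.zeros(5)]
        assert roc_auc(scores, labels) == 1.0

    def test_all_tied_gives_half(self):
        assert roc_auc(np.full(10, 0.5), np.r_[np.ones(5), np.zeros(5)]) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        auc = roc_auc(scores, labels)
        cases = scores[labels == 1]
        controls = scores[labels == 0]
        wins = sum((c < d) + 0.5 * (c == d) for c in cases for d in controls)
        assert auc == pytest.approx(wins / (len(cases) * len(controls)), abs=1e-12)

    def test_label_swap_symmetry(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(1 - roc_auc(scores, 1 - labels))

    def test_single_class_fails(self):
        with pytest.raises(ValueError, match="two classes"):
            roc_auc(np.arange(5.0), np.ones(5))


class TestPermutationP:
    def test_perfect_separation_gives_add_one_minimum(self):
        scores = np.r_[np.full(20, 0.1), np.full(20, 0.9)]
        labels = np.r_[np.ones(20), np.zeros(20)]
        auc, p = permutation_auc_pvalue(scores, labels, PermutationSpec(1000, seed=0))
        assert auc == 1.0
        assert p == pytest.approx(1 / 1001)

    def test_single_permutation_boundary(self):
        scores = np.arange(10.0)
        labels = np.r_[np.ones(5), np.zeros(5)]
        _, p = permutation_auc_pvalue(scores, labels, PermutationSpec(1, seed=3))
        assert p in (0.5, 1.0)

    def test_lower_bound_never_violated(self, rng):
        for b in (1, 5, 50):
            scores = rng.normal(size=16)
            labels = np.r_[np.ones(8), np.zeros(8)]
            _, p = permutation_auc_pvalue(scores, labels, PermutationSpec(b, seed=int(b)))
            assert 1 / (b + 1) <= p <= 1.0

    def test_null_p_values_approximately_uniform(self, rng):
        """Under independent labels the permutation p is ~Uniform(0,1)."""
        pvals = []
        labels = np.r_[np.ones(10), np.zeros(10)]
        for i in range(100):
            scores = rng.normal(size=20)
            _, p = permutation_auc_pvalue(scores, labels, PermutationSpec(199, seed=i))
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def _roi_table(rng, n=40, rois=5):
    cols = [f"ROI_{i:03d}" for i in range(1, rois + 1)] + ["whole_brain"]
    table = pd.DataFrame(
        rng.random((n, rois + 1)), columns=cols,
        index=pd.Index([f"s{i}" for i in range(n)], name="subject_id"),
    )
    return table


class TestEvaluateDataset:
    def test_family_counting_dataset_rule(self, rng):
        table = _roi_table(rng)
        pheno = pd.DataFrame({
            "subject_id": table.index,
            "a": rng.normal(size=40), "b": rng.normal(size=40), "c": rng.normal(size=40),
        })
        results = evaluate_dataset(table, pheno, {"a": "numeric", "b": "numeric", "c": "numeric"})
        assert len(results) == 18  # (5 ROIs + whole_brain) x 3 targets
        for r in results:
            assert r.p_corrected == pytest.approx(min(1.0, 18 * r.p_raw))
            assert r.significant == (r.p_corrected < 0.05)

    def test_per_target_family_rule(self, rng):
        table = _roi_table(rng)
        pheno = pd.DataFrame({
            "subject_id": table.index,
            "a": rng.normal(size=40), "b": rng.normal(size=40),
        })
        results = evaluate_dataset(
            table, pheno, {"a": "numeric", "b": "numeric"}, family_rule="per_target"
        )
        for r in results:
            assert r.p_corrected == pytest.approx(min(1.0, 6 * r.p_raw))

    def test_binary_target_uses_auc(self, rng):
        table = _roi_table(rng, n=30)
        pheno = pd.DataFrame({
            "subject_id": table.index,
            "dx": rng.integers(0, 2, 30),
        })
        pheno.loc[0, "dx"] = 1
        pheno.loc[1, "dx"] = 0
        results = evaluate_dataset(
            table, pheno, {"dx": "binary"}, permutation=PermutationSpec(99, seed=1)
        )
        assert all(r.statistic_kind == "auc" for r in results)
        assert all(0 <= r.effect <= 1 for r in results)

    def test_missing_subjects_listed(self, rng):
        table = _roi_table(rng, n=10)
        pheno = pd.DataFrame({"subject_id": [f"s{i}" for i in range(8)], "a": range(8)})
        with pytest.raises(ValueError, match="s8"):
            evaluate_dataset(table, pheno, {"a": "numeric"})

    def test_unknown_target_fails(self, rng):
        table = _roi_table(rng, n=10)
        pheno = pd.DataFrame({"subject_id": table.index, "a": range(10)})
        with pytest.raises(ValueError, match="unknown target"):
            evaluate_dataset(table, pheno, {"zzz": "numeric"})

    def test_significance_invariant_to_evaluation_order(self, rng):
        table = _roi_table(rng)
        pheno = pd.DataFrame({
            "subject_id": table.index,
            "a": rng.normal(size=40), "b": rng.normal(size=40),
        })
        res_ab = evaluate_dataset(table, pheno, {"a": "numeric", "b": "numeric"})
        res_ba = evaluate_dataset(table, pheno, {"b": "numeric", "a": "numeric"})
        key = lambda r: (r.roi_name, r.target_name)
        assert {key(r): r.significant for r in res_ab} == {key(r): r.significant for r in res_ba}

    def test_familywise_error_controlled_on_null(self):
        """Bonferroni validity: fraction of null datasets with any
        significant pair stays near alpha."""
        rng = np.random.default_rng(99)
        hits = 0
        n_sets = 150
        for _ in range(n_sets):
            table = _roi_table(rng, n=30, rois=3)
            pheno = pd.DataFrame({
                "subject_id": table.index,
                "a": rng.normal(size=30), "b": rng.normal(size=30),
            })
            results = evaluate_dataset(table, pheno, {"a": "numeric", "b": "numeric"})
            hits += any(r.significant for r in results)
        se = np.sqrt(0.05 * 0.95 / n_sets)
        assert hits / n_sets <= 0.05 + 2 * se

    def test_output_frames(self, rng):
        table = _roi_table(rng, n=20, rois=2)
        pheno = pd.DataFrame({"subject_id": table.index, "a": rng.normal(size=20)})
        results = evaluate_dataset(table, pheno, {"a": "numeric"})
        frame = results_to_frame(results)
        assert set(frame.columns) >= {"roi_name", "target_name", "effect", "p_raw", "p_corrected"}
        matrix = significant_effect_matrix(results)
        assert matrix.shape == (3, 1)
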