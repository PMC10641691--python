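"""Predictive-ability metrics, training-set assembly and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rrsgs import (
    build_training_set,
    coincidence_rate,
    cross_validate,
    family_assessment,
    prediction_bias,
    rank_concordance,
    realized_predictive_ability,
    top_k_count,
)
from rrsgs.assessment import AssessmentError, direct_validation, make_folds


def series(vals, ids=None):
    ids = ids or [f"i{k}" for k in range(len(vals))]
    return pd.Series(list(vals), index=ids, dtype=float)


class TestTrainingSets:
    COHORTS = {
        "H": [f"h{k}" for k in range(1842)],
        "P": [f"p{k}" for k in range(18)],
        "U": [f"u{k}" for k in range(214)],
    }

    @pytest.mark.parametrize(
        "combo,expected",
        [("H", 1842), ("P", 18), ("U", 214), ("H+P", 1860),
         ("H+U", 2056), ("P+U", 232), ("H+P+U", 2074)],
    )
    def test_study_cohort_arithmetic(self, combo, expected):
        assert build_training_set(self.COHORTS, combo).size == expected

    def test_provenance_partition(self):
        t = build_training_set(self.COHORTS, "H+P+U")
        assert sum(len(v) for v in t.provenance.values()) == t.size

    def test_empty_cohort_rejected(self):
        with pytest.raises(AssessmentError):
            build_training_set({"H": []}, "H")

    def test_unknown_cohort_rejected(self):
        with pytest.raises(AssessmentError):
            build_training_set(self.COHORTS, "H+X")

    def test_overlapping_cohorts_rejected(self):
        with pytest.raises(AssessmentError):
            build_training_set({"H": ["a", "b"], "P": ["b"]}, "H+P")


class TestPairedMetrics:
    def test_rpa_identity_and_sign(self):
        x = series([1, 2, 3, 4])
        assert realized_predictive_ability(x, x) == pytest.approx(1.0)
        assert realized_predictive_ability(x, -x) == pytest.approx(-1.0)

    def test_rpa_hand_computed_example(self):
        # by hand: cov = 11/3, sd_g = sqrt(5/3), sd_r = sqrt(26/3)
        g = series([1, 2, 3, 4])
        r = series([2, 4, 5, 9])
        expected = 11 / np.sqrt(5 * 26)
        assert realized_predictive_ability(g, r) == pytest.approx(expected, abs=1e-9)

    def test_bias_slope_examples(self):
        g = series([0.5, 1.5, 2.0, 3.2])
        assert prediction_bias(g, g) == pytest.approx(0.0)
        assert prediction_bias(g, 2 * g) == pytest.approx(-1.0)

    def test_bias_matches_ols_oracle(self, rng):
        g = series(rng.normal(size=30))
        r = series(0.7 * g.to_numpy() + rng.normal(0, 0.3, 30))
        X = np.column_stack([np.ones(30), g.to_numpy()])
        slope = np.linalg.lstsq(X, r.to_numpy(), rcond=None)[0][1]
        assert prediction_bias(g, r) == pytest.approx(1 - slope)

    def test_spearman_monotone_and_reversed(self, rng):
        g = series(rng.normal(size=20))
        assert rank_concordance(g, np.exp(g)) == pytest.approx(1.0)
        assert rank_concordance(g, -g) == pytest.approx(-1.0)

    def test_spearman_with_tie_matches_midrank_brute_force(self):
        g = series([1.0, 2.0, 2.0, 3.0, 4.0])
        r = series([2.0, 1.0, 4.0, 3.0, 5.0])
        ranks_g = np.array([1.0, 2.5, 2.5, 4.0, 5.0])
        ranks_r = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        brute = np.corrcoef(ranks_g, ranks_r)[0, 1]
        assert rank_concordance(g, r) == pytest.approx(brute)

    def test_zero_variance_reported(self):
        with pytest.raises(AssessmentError):
            realized_predictive_ability(series([1, 1, 1]), series([1, 2, 3]))

    @given(shift=st.floats(-50, 50), scale=st.floats(0.1, 20))
    @settings(max_examples=30, deadline=None)
    def test_invariance_to_shift_and_positive_rescale(self, shift, scale):
        g = series([0.3, -1.2, 0.8, 2.0, -0.5])
        r = series([0.1, -0.9, 1.1, 1.5, -0.2])
        base = realized_predictive_ability(g, r)
        assert realized_predictive_ability(g * scale + shift, r + shift) == pytest.approx(base, abs=1e-9)
        assert rank_concordance(g * scale + shift, r + shift) == pytest.approx(
            rank_concordance(g, r), abs=1e-9
        )


class TestCoincidence:
    def test_top_k_mapping_197_trees(self):
        assert top_k_count(197, 0.025) == 5
        assert top_k_count(197, 0.05) == 10
        assert top_k_count(3, 0.01) == 1  # minimum of one

    def test_identical_rankings_full_coincidence(self, rng):
        g = series(rng.normal(size=40))
        for p in (0.025, 0.1, 0.5, 1.0):
            assert coincidence_rate(g, g, p) == 100.0

    def test_disjoint_top_k_zero(self):
        g = series([4, 3, 2, 1, 0, -1, -2, -3])
        r = -g
        assert coincidence_rate(g, r, 0.25) == 0.0

    def test_proportion_one_always_full(self, rng):
        g = series(rng.normal(size=17))
        r = series(rng.normal(size=17))
        assert coincidence_rate(g, r, 1.0) == 100.0

    def test_empty_set_rejected(self):
        with pytest.raises(AssessmentError):
            top_k_count(0, 0.1)

    def test_deterministic_tie_break_by_id(self):
        g = series([1.0, 1.0, 0.0], ids=["a", "b", "c"])
        r = series([1.0, 0.0, 1.0], ids=["a", "b", "c"])
        # k=1: genomic top is 'a' (tie a/b broken by id), reference top is 'a'
        assert coincidence_rate(g, r, 1 / 3) == 100.0


class TestFamilyLevel:
    def test_singleton_families_equal_individual_metrics(self, rng):
        g = series(rng.normal(size=12))
        r = series(rng.normal(size=12))
        fam = pd.Series([f"f{k}" for k in range(12)], index=g.index)
        out = family_assessment(pd.DataFrame({"genomic": g, "reference": r}), fam)
        assert out["rpa"] == pytest.approx(realized_predictive_ability(g, r))

    def test_family_means_match_groupby_oracle(self, rng):
        n = 60
        ids = [f"i{k}" for k in range(n)]
        fam = pd.Series([f"f{k % 6}" for k in range(n)], index=ids)
        df = pd.DataFrame(
            {"genomic": rng.normal(size=n), "reference": rng.normal(size=n)}, index=ids
        )
        out = family_assessment(df, fam)
        assert out["n_families"] == 6
        brute = df.join(fam.rename("family")).groupby("family").mean()
        np.testing.assert_allclose(out["family_means"], brute[["genomic", "reference"]])


class TestCrossValidation:
    def test_folds_partition_exactly(self, rng):
        ids = [f"i{k}" for k in range(53)]
        folds = make_folds(ids, 10, seed=1)
        flat = [i for f in folds for i in f]
        assert sorted(flat) == sorted(ids)
        assert len(set(flat)) == len(ids)

    def test_family_stratification_keeps_sibs_together(self):
        ids = [f"i{k}" for k in range(40)]
        fam = pd.Series([f"f{k // 4}" for k in range(40)], index=ids)
        folds = make_folds(ids, 5, seed=2, family_map=fam)
        for f in folds:
            fams_here = set(fam.loc[f])
            for other in folds:
                if other is not f:
                    assert fams_here.isdisjoint(set(fam.loc[other]))

    def test_leave_one_out_degenerate_rejected(self):
        with pytest.raises(AssessmentError):
            make_folds([f"i{k}" for k in range(10)], 10, seed=0)

    def test_cross_validate_recovers_signal(self, rng):
        """A predictor equal to signal+noise yields positive mean PA."""
        n = 100
        ids = [f"i{k}" for k in range(n)]
        signal = pd.Series(rng.normal(size=n), index=ids)

        def fit_predict(train, test):
            return signal.loc[test] + rng.normal(0, 0.5, len(test))

        ref = signal + rng.normal(0, 0.5, n)
        out = cross_validate(fit_predict, ref, k=5, seed=3)
        assert out["n_folds"] == 5
        assert out["mean_pa"] > 0.5

    def test_direct_validation_is_single_correlation(self, rng):
        pred = series(rng.normal(size=30))
        ref = series(0.5 * pred.to_numpy() + rng.normal(0, 1, 30))
        assert direct_validation(pred, ref) == pytest.approx(
            realized_predictive_ability(pred, ref)
        )
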