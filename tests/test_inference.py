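import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nirsentropy.exceptions import DegenerateTableError
from nirsentropy.inference import (
    auc_power,
    combined_model_auc,
    compare_categorical,
    compare_means,
    logistic_from_counts,
    multivariate_logistic_backward_lr,
    roc_auc,
    univariate_logistic,
)

from oracles import auc_pair_count, cross_product_or, mann_whitney_u_count

# printed 2x2 cohort tables: rows (non-improver, improver), cols (no, yes)
COHORT_TABLES = {
    "hypertension": ([[3, 21], [12, 21]], "pearson", 4.081),
    "blood_pressure_lowering": ([[5, 19], [19, 14]], "pearson", 7.695),
    "hyperlipidemia": ([[7, 17], [14, 19]], "pearson", 1.050),
    "diabetes": ([[14, 10], [20, 13]], "pearson", 0.030),
    "stroke_history": ([[15, 9], [23, 10]], "pearson", 0.324),
    "tia_history": ([[13, 11], [19, 14]], "pearson", 0.066),
    "smoke_history": ([[8, 16], [9, 24]], "pearson", 0.244),
    "alcohol_history": ([[6, 18], [10, 23]], "pearson", 0.194),
    "education": ([[14, 10], [23, 10]], "pearson", 0.788),
    "glucose_lowering": ([[14, 10], [23, 10]], "pearson", 0.788),
    "coronary_heart_disease": ([[18, 6], [32, 1]], "yates", 4.353),
    "symptomatic": ([[1, 23], [5, 28]], "yates", 0.805),
    "antiplatelet": ([[3, 21], [7, 26]], "yates", 0.251),
    "lipid_altering": ([[2, 22], [7, 26]], "yates", 0.900),
}
FISHER_TABLES = {
    "gender": [[1, 23], [1, 32]],
    "anticoagulation": [[24, 0], [32, 1]],
}


class TestCompareCategorical:
    @pytest.mark.parametrize("name", sorted(COHORT_TABLES))
    def test_cohort_replay(self, name):
        table, method, expected = COHORT_TABLES[name]
        res = compare_categorical(table)
        assert res.method == method
        assert res.statistic == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("name", sorted(FISHER_TABLES))
    def test_fisher_rows(self, name):
        res = compare_categorical(FISHER_TABLES[name])
        assert res.method == "fisher"
        assert res.p == pytest.approx(1.000, abs=5e-4)
        assert np.isnan(res.statistic)

    def test_independence_gives_zero(self):
        res = compare_categorical([[10, 10], [10, 10]])
        assert res.method == "pearson"
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_zero_margin_raises(self):
        with pytest.raises(DegenerateTableError):
            compare_categorical([[0, 10], [0, 12]])

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError):
            compare_categorical([[1.5, 2], [3, 4]])


class TestCompareMeans:
    def test_identical_groups_t_zero(self):
        res = compare_means((20, 5.0, 1.0), (30, 5.0, 1.0))
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_printed_moca_summaries(self):
        # published group summaries reproduce the printed t up to rounding
        res = compare_means((24, 20.3, 3.9), (33, 18.0, 4.3), variant="pooled")
        assert res.statistic == pytest.approx(2.087, abs=0.05)
        assert res.p < 0.05

    def test_welch_matches_scipy(self, rng):
        a, b = rng.standard_normal(30), 0.5 + 1.7 * rng.standard_normal(40)
        res = compare_means(a, b, variant="welch")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_pooled_matches_scipy(self, rng):
        a, b = rng.standard_normal(25), rng.standard_normal(35) + 0.3
        res = compare_means(a, b, variant="pooled")
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_mann_whitney_u_against_pair_counting(self):
        a = [3.0, 1.0, 4.0, 1.0, 5.0]
        b = [2.0, 6.0, 2.0, 3.0, 5.0]
        u = mann_whitney_u_count(a, b)  # exhaustive oracle
        res = compare_means(a, b, variant="mann_whitney")
        n1, n2 = len(a), len(b)
        # invert the z back to U to compare with the oracle
        combined = np.concatenate([a, b])
        _, counts = np.unique(combined, return_counts=True)
        n = n1 + n2
        sigma2 = n1 * n2 / 12 * ((n + 1) - np.sum(counts**3 - counts) / (n * (n - 1)))
        u_from_z = res.statistic * np.sqrt(sigma2) + n1 * n2 / 2
        assert u_from_z == pytest.approx(u)

    def test_mann_whitney_requires_raw(self):
        with pytest.raises(ValueError):
            compare_means((10, 1.0, 1.0), (10, 2.0, 1.0), variant="mann_whitney")

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_means((1, 0.0, 1.0), (10, 1.0, 1.0))


class TestUnivariateLogistic:
    @pytest.mark.parametrize(
        "counts, expected_or, expected_ci",
        [
            ((5, 19, 19, 14), 0.19, (0.06, 0.65)),
            ((3, 12, 21, 21), 0.25, (0.06, 1.02)),
            ((18, 32, 6, 1), 0.09, (0.01, 0.84)),
        ],
    )
    def test_published_rows(self, counts, expected_or, expected_ci):
        fit = logistic_from_counts(*counts)
        term = fit.terms[0]
        assert round(term.odds_ratio, 2) == expected_or
        assert round(term.ci_low, 2) == expected_ci[0]
        assert round(term.ci_high, 2) == expected_ci[1]
        assert not fit.separation

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_cross_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 30, size=4)
        a, b, c, d = (int(v) for v in table)
        fit = logistic_from_counts(a, b, c, d)
        oracle_or, oracle_lo, oracle_hi = cross_product_or([[a, b], [c, d]])
        term = fit.terms[0]
        assert term.odds_ratio == pytest.approx(oracle_or, rel=1e-4)
        assert term.ci_low == pytest.approx(oracle_lo, rel=1e-3)
        assert term.ci_high == pytest.approx(oracle_hi, rel=1e-3)

    def test_independent_predictor_or_one(self):
        fit = logistic_from_counts(10, 10, 10, 10)
        assert fit.terms[0].odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_per_sd_scaling(self, rng):
        x = rng.standard_normal(300) * 4.0
        y = (rng.random(300) < 1 / (1 + np.exp(-0.5 * x / 4.0))).astype(int)
        raw = univariate_logistic(y, x)
        scaled = univariate_logistic(y, x, per_sd=True)
        sd = np.std(x, ddof=1)
        assert scaled.terms[0].coefficient == pytest.approx(raw.terms[0].coefficient * sd, rel=1e-5)
        assert scaled.scaling == {"x": pytest.approx(sd)}

    def test_separation_flagged_not_raised(self):
        y = np.array([0] * 20 + [1] * 20)
        x = np.concatenate([np.zeros(20), np.ones(20)])
        fit = univariate_logistic(y, x)
        assert fit.separation

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            univariate_logistic(np.ones(20), np.arange(20))


class TestBackwardLR:
    def test_single_significant_candidate_retained(self, rng):
        n = 300
        x = rng.standard_normal(n)
        y = (rng.random(n) < 1 / (1 + np.exp(-1.2 * x))).astype(int)
        fit = multivariate_logistic_backward_lr(y, pd.DataFrame({"x": x}))
        assert [t.name for t in fit.terms] == ["x"]
        assert fit.selection_trace == ()

    def test_noise_term_removed_first(self):
        # one real signal + one pure-noise candidate: the noise term must be
        # eliminated first in the overwhelming majority of replicates
        removed_noise_first = 0
        kept_signal = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            n = 500
            x = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            y = (rng.random(n) < 1 / (1 + np.exp(-0.9 * x))).astype(int)
            fit = multivariate_logistic_backward_lr(
                y, pd.DataFrame({"signal": x, "noise": noise})
            )
            names = [t.name for t in fit.terms]
            if "signal" in names:
                kept_signal += 1
            if fit.selection_trace and fit.selection_trace[0][0] == "noise":
                removed_noise_first += 1
            elif not fit.selection_trace:
                pass  # both retained: noise not removed at all
        assert kept_signal >= 95
        # noise survives only when its LR p lands under 0.10 by chance
        assert removed_noise_first >= 80

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            multivariate_logistic_backward_lr(np.array([0, 1]), pd.DataFrame())

    def test_all_noise_removes_everything(self, rng):
        n = 400
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        fit = multivariate_logistic_backward_lr(y, X, p_remove=0.01)
        assert len(fit.terms) + len(fit.selection_trace) == 2


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0

    def test_all_tied_scores(self):
        res = roc_auc([5.0] * 10, [0, 1] * 5)
        assert res.auc == 0.5

    def test_small_derived_example(self):
        # 4 positive-negative pairs, 3 concordant -> 0.75
        res = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(10))
    def test_pair_count_identity(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.standard_normal(60), 1)  # ties likely
        labels = rng.integers(0, 2, 60)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = roc_auc(scores, labels)
        assert res.auc == pytest.approx(auc_pair_count(scores, labels))

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(80)
        labels = (rng.random(80) < 0.4).astype(int)
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(scores), labels)
        assert a.auc == pytest.approx(b.auc)

    def test_ci_brackets_auc(self, rng):
        scores = rng.standard_normal(100) + (rng.random(100) < 0.5)
        labels = (rng.random(100) < 0.5).astype(int)
        for method in ("delong", "hanley_mcneil"):
            res = roc_auc(scores, labels, ci_method=method)
            assert res.ci_low <= res.auc <= res.ci_high

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_delong_coverage_binormal(self):
        # ~95% coverage of the true binormal AUC over 500 replicates
        true_auc = stats.norm.cdf(1.0 / np.sqrt(2.0))
        rng = np.random.default_rng(7)
        covered = 0
        reps = 500
        for _ in range(reps):
            neg = rng.standard_normal(100)
            pos = rng.standard_normal(100) + 1.0
            res = roc_auc(
                np.concatenate([neg, pos]),
                np.concatenate([np.zeros(100), np.ones(100)]),
            )
            covered += res.ci_low <= true_auc <= res.ci_high
        rate = covered / reps
        band = 2.576 * np.sqrt(0.95 * 0.05 / reps)
        assert 0.95 - band <= rate <= min(1.0, 0.95 + band + 1e-12)


class TestCombinedModel:
    def test_single_variable_matches_raw_auc(self, rng):
        x = rng.standard_normal(120)
        y = (rng.random(120) < 1 / (1 + np.exp(-x))).astype(int)
        single = roc_auc(x, y)
        combined, fit = combined_model_auc(y, pd.DataFrame({"x": x}))
        assert combined.auc == pytest.approx(single.auc)

    def test_nested_auc_non_decreasing(self, rng):
        x = rng.standard_normal(150)
        noise = rng.standard_normal(150)
        y = (rng.random(150) < 1 / (1 + np.exp(-x))).astype(int)
        base, _ = combined_model_auc(y, pd.DataFrame({"x": x}))
        bigger, _ = combined_model_auc(y, pd.DataFrame({"x": x, "noise": noise}))
        assert bigger.auc >= base.auc - 1e-12


class TestAucPower:
    def test_published_design(self):
        power = auc_power(33, 24, 0.5, 0.715, 0.05)
        assert power == pytest.approx(0.83, abs=0.02)

    def test_vanishing_effect(self):
        power = auc_power(33, 24, 0.5, 0.5001, 0.05)
        assert power < 0.10

    def test_monotone_in_n(self):
        p1 = auc_power(33, 24, 0.5, 0.715, 0.05)
        p2 = auc_power(66, 48, 0.5, 0.715, 0.05)
        assert p2 > p1

    def test_monotone_in_effect(self):
        p1 = auc_power(33, 24, 0.5, 0.65, 0.05)
        p2 = auc_power(33, 24, 0.5, 0.75, 0.05)
        assert p2 > p1

    def test_invalid_ordering(self):
        with pytest.raises(ValueError):
            auc_power(33, 24, 0.7, 0.6, 0.05)
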