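import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ecshock.cohort_stats import (cohen_class, correlations, relative_changes,
                                  stage_comparison_table,
                                  wilcoxon_null_rejection_rate,
                                  wilcoxon_vs_baseline)
from ecshock.errors import DataError, EvaluationError


def exact_wilcoxon_p(diffs):
    """Oracle: exhaustive sign-flip enumeration of the signed-rank null."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum([r for r, s in zip(ranks, signs) if s])
          for signs in itertools.product([0, 1], repeat=len(d))]
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestRelativeChanges:
    def test_reference_ratio(self):
        table = pd.DataFrame({
            "subject_id": ["a", "a"], "stage": ["baseline", "lbnp45"],
            "sv": [100.0, 65.7]})
        rel = relative_changes(table, ["sv"])
        assert rel.loc[rel.stage == "lbnp45", "sv"].item() == pytest.approx(0.657)
        assert rel.loc[rel.stage == "baseline", "sv"].item() == 1.0

    def test_zero_baseline_excluded_with_warning(self):
        table = pd.DataFrame({
            "subject_id": ["a", "a", "b", "b"],
            "stage": ["baseline", "lbnp45"] * 2,
            "sv": [0.0, 50.0, 100.0, 80.0]})
        with pytest.warns(UserWarning):
            rel = relative_changes(table, ["sv"])
        assert np.isnan(rel.loc[(rel.subject_id == "a") & (rel.stage == "lbnp45"),
                                "sv"].item())

    def test_missing_baseline_rows_rejected(self):
        table = pd.DataFrame({"subject_id": ["a"], "stage": ["lbnp45"],
                              "sv": [50.0]})
        with pytest.raises(DataError):
            relative_changes(table, ["sv"])


class TestWilcoxon:
    def test_all_positive_six_pairs_exact(self):
        res = wilcoxon_vs_baseline([1, 2, 3, 4, 5, 6], [0] * 6)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 2**6)

    def test_degenerate_identical_vectors(self):
        res = wilcoxon_vs_baseline([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and res.p_value == 1.0

    def test_matches_signflip_enumeration_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 11))
            # distinct magnitudes avoid rank ties
            mags = rng.permutation(np.arange(1, n + 1)).astype(float)
            signs = rng.choice([-1.0, 1.0], n)
            d = mags * signs
            res = wilcoxon_vs_baseline(d, np.zeros(n))
            assert res.p_value == pytest.approx(exact_wilcoxon_p(d), abs=1e-12)

    def test_large_n_uses_corrected_normal_approximation(self, rng):
        x = rng.normal(0.3, 1.0, 40)
        res = wilcoxon_vs_baseline(x, np.zeros(40))
        ref = sps.wilcoxon(x, zero_method="wilcox", method="approx",
                           correction=True)
        assert res.method == "approx"
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_null_rejection_rate_helper_matches_single_tests(self, rng):
        # the vectorised null simulation must agree with the per-vector test
        d = rng.standard_normal(29)
        ranks = sps.rankdata(np.abs(d))
        w = ranks[d > 0].sum()
        mu, sigma = 29 * 30 / 4, np.sqrt(29 * 30 * 59 / 24)
        p_vec = 2 * sps.norm.sf((abs(w - mu) - 0.5) / sigma)
        ref = sps.wilcoxon(d, zero_method="wilcox", method="approx",
                           correction=True)
        assert p_vec == pytest.approx(ref.pvalue)

    def test_rate_is_seeded(self):
        a = wilcoxon_null_rejection_rate(10, 500, seed=3)
        b = wilcoxon_null_rejection_rate(10, 500, seed=3)
        assert a == b


class TestCohen:
    @pytest.mark.parametrize("rho, expected", [
        (0.05, "below-small"), (0.1, "small"), (0.29, "small"),
        (0.3, "medium"), (0.49, "medium"), (0.5, "large"),
        (-0.9, "large"), (-0.1, "small"),
    ])
    def test_boundaries_inclusive(self, rho, expected):
        assert cohen_class(rho) == expected


class TestCorrelations:
    def _table(self, x, y):
        return pd.DataFrame({"subject_id": "s", "x": x, "y": y})

    def test_affine_relationship(self):
        x = np.arange(10.0)
        res = correlations(self._table(x, 2 * x + 1), "x", "y")
        assert res.pearson == pytest.approx(1.0)
        assert res.spearman == pytest.approx(1.0)

    def test_monotone_nonlinearity(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0])
        res = correlations(self._table(x, x**3), "x", "y")
        assert res.spearman == pytest.approx(1.0)
        assert res.pearson < 1.0

    def test_zero_variance_flagged(self):
        with pytest.raises(EvaluationError):
            correlations(self._table(np.ones(5), np.arange(5.0)), "x", "y")

    def test_spearman_is_pearson_on_ranks(self, rng):
        x = rng.normal(0, 1, 25)
        y = rng.normal(0, 1, 25)
        res = correlations(self._table(x, y), "x", "y")
        assert res.spearman == pytest.approx(
            sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic)

    def test_per_subject_pep_negatively_large_on_synthetic_cohort(self, feature_table):
        res = correlations(feature_table, "pep_mean", "sv_tte_ml",
                           scope="per-subject")
        assert res.pearson < 0
        assert res.cohen == "large"
        assert len(res.per_subject) <= 8


def test_stage_comparison_table_on_synthetic_cohort(feature_table):
    tab = stage_comparison_table(feature_table, ["sv_tte_ml", "hr_mean"])
    assert set(tab["stage"]) == {"lbnp15", "lbnp30", "lbnp45", "recovery"}
    row = tab[(tab.parameter == "sv_tte_ml") & (tab.stage == "lbnp45")]
    assert row["q25"].item() <= row["median_rel"].item() <= row["q75"].item()
    assert row["median_rel"].item() < 0.8  # strong decline at -45 mmHg
    assert 0 < row["p_value"].item() <= 1
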