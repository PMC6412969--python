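import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fentsar.core import ValidationError
from fentsar.rescoring import (
    external_validate,
    optimal_score,
    optimal_score_table,
    reweight_components,
    score_affinity_correlation,
)
from fentsar.synthetic import ScoreSpec, generate_score_table


def _table(rows):
    return pd.DataFrame(
        [
            {"derivative_id": d, "replica": 1, "time_ns": 40.0 + i,
             "function": "PLP1", "total": s}
            for i, (d, s) in enumerate(rows)
        ]
    )


class TestOptimalScore:
    DIRECTIONS = {"PLP1": "minimize"}

    def test_single_snapshot(self):
        t = _table([("F01", -4.2)])
        assert optimal_score(t, "F01", "PLP1", self.DIRECTIONS) == -4.2

    def test_minimize_takes_the_minimum(self):
        t = _table([("F01", -5.0), ("F01", -7.0), ("F01", -3.0)])
        assert optimal_score(t, "F01", "PLP1", self.DIRECTIONS) == -7.0
        assert optimal_score(
            t, "F01", "PLP1", {"PLP1": "maximize"}
        ) == -3.0
        assert optimal_score(
            t, "F01", "PLP1", self.DIRECTIONS, aggregate="mean"
        ) == pytest.approx(-5.0)

    def test_row_order_invariance_and_brute_force(self):
        table, _, truth = generate_score_table(ScoreSpec(seed=5, jitter_sd=0.4))
        directions = {"SYNSCORE": "maximize"}
        opt = optimal_score_table(table, directions).set_index("derivative_id")
        rng = np.random.default_rng(1)
        shuffled = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
        for did, sub in table.groupby("derivative_id"):
            brute = sub["total"].max()
            assert opt.loc[did, "score"] == brute
            assert optimal_score(shuffled, did, "SYNSCORE", directions) == brute

    def test_unknown_function_is_an_error(self):
        with pytest.raises(ValidationError):
            optimal_score(_table([("F01", 1.0)]), "F01", "XX", self.DIRECTIONS)


class TestScoreAffinityCorrelation:
    def test_perfect_prediction(self):
        pic = pd.Series({"A": 7.0, "B": 8.0, "C": 9.0})
        r, n = score_affinity_correlation(pic, pic)
        assert r == pytest.approx(1.0) and n == 3

    def test_exclusions_change_n(self):
        idx = [f"F{i:02d}" for i in range(3, 19)]  # includes F07, F08, F18
        rng = np.random.default_rng(2)
        scores = pd.Series(rng.normal(size=16), index=idx)
        pic = pd.Series(rng.normal(size=16), index=idx)
        _, n_all = score_affinity_correlation(scores, pic)
        _, n_sub = score_affinity_correlation(
            scores, pic, exclude=["F07", "F08", "F18"]
        )
        assert (n_all, n_sub) == (16, 13)

    def test_null_rate_of_spurious_correlation(self):
        # analytic null: P(|R| > 0.30) at n = 28 is ~12%; a seeded simulation
        # over 1000 draws should land near it
        rng = np.random.default_rng(42)
        n, hits = 28, 0
        for _ in range(1000):
            r = stats.pearsonr(rng.normal(size=n), rng.normal(size=n)).statistic
            hits += abs(r) > 0.30
        assert 0.08 <= hits / 1000 <= 0.16


class TestReweighting:
    def test_exact_linear_combination_recovered(self):
        table, pic50, truth = generate_score_table(ScoreSpec(seed=7))
        comp = (
            table.groupby("derivative_id")[list(truth["component_weights"])]
            .mean()
            .loc[pic50.index]
        )
        res = reweight_components(comp, pic50)
        for name, w in truth["component_weights"].items():
            got = res.weights[res.component_names.index(name)]
            assert got == pytest.approx(w, abs=1e-8)
        assert res.intercept == pytest.approx(truth["intercept"], abs=1e-8)
        assert res.internal_r == pytest.approx(1.0)

    def test_single_component_equal_to_target(self):
        y = pd.Series([7.0, 8.5, 6.2, 9.1, 8.0])
        comp = pd.DataFrame({"LIPSCO": y.to_numpy()})
        res = reweight_components(comp, y)
        assert res.weights[0] == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)

    def test_collinear_components_named_in_error(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=8)
        comp = pd.DataFrame({"A": a, "B": 2 * a, "C": rng.normal(size=8)})
        with pytest.raises(ValidationError, match="B"):
            reweight_components(comp, rng.normal(size=8))

    def test_ols_dominates_best_single_component(self):
        rng = np.random.default_rng(11)
        comp = pd.DataFrame(rng.normal(size=(20, 3)), columns=["A", "B", "C"])
        y = 0.7 * comp["A"] - 0.2 * comp["C"] + rng.normal(0, 0.5, 20)
        res = reweight_components(comp, y)
        best_single = max(
            abs(stats.pearsonr(comp[c], y).statistic) for c in comp.columns
        )
        assert res.internal_r >= best_single - 1e-12

    def test_lipophilic_component_beats_total_score(self):
        # when one component drives affinity, its own correlation exceeds the
        # correlation of the full (mis-weighted) total
        rng = np.random.default_rng(13)
        n = 24
        lip = rng.normal(size=n)
        other = rng.normal(size=n)
        pic = 7.5 + 1.0 * lip + rng.normal(0, 0.2, n)
        total = lip - 3.0 * other  # total spoiled by a mis-weighted component
        r_lip = abs(stats.pearsonr(lip, pic).statistic)
        r_tot = abs(stats.pearsonr(total, pic).statistic)
        assert r_lip > r_tot

    def test_too_few_observations_rejected(self):
        comp = pd.DataFrame({"A": [1.0, 2.0], "B": [0.0, 1.0]})
        with pytest.raises(ValidationError):
            reweight_components(comp, [1.0, 2.0])


class TestExternalValidation:
    def _fit(self, seed=17):
        table, pic50, truth = generate_score_table(
            ScoreSpec(seed=seed, n_compounds=20)
        )
        names = list(truth["component_weights"])
        comp = table.groupby("derivative_id")[names].mean().loc[pic50.index]
        return reweight_components(comp, pic50), comp, pic50, truth

    def test_training_compound_predicts_its_fit_value(self):
        res, comp, pic50, _ = self._fit()
        val = comp.copy()
        val["compound_id"] = list(comp.index)
        out = external_validate(res, val, band=(-math.inf, math.inf))
        np.testing.assert_allclose(out["predicted_pic50"], res.predict(comp))
        np.testing.assert_allclose(out["predicted_pic50"], pic50, atol=1e-8)

    def test_same_model_passes_and_shifted_model_fails(self):
        res, comp, pic50, truth = self._fit()
        rng = np.random.default_rng(19)
        names = list(truth["component_weights"])
        w = np.array([truth["component_weights"][c] for c in names])
        base = rng.normal(0, 0.3, size=(10, len(names)))
        same = pd.DataFrame(base, columns=names)
        same["compound_id"] = [f"V{i}" for i in range(10)]
        band = (truth["intercept"] - 1.5, truth["intercept"] + 1.5)
        out_same = external_validate(res, same, band)
        assert out_same["passed"].mean() >= 0.8
        shifted = same.copy()
        shifted[names] = base + 8.0  # a very different scoring regime
        out_shift = external_validate(res, shifted, band)
        assert out_shift["passed"].mean() <= 0.2

    def test_missing_component_is_an_error(self):
        res, comp, _, _ = self._fit()
        bad = pd.DataFrame({"compound_id": ["x"], "LIPSCO": [0.0]})
        with pytest.raises(ValidationError):
            external_validate(res, bad, band=(0.0, 10.0))
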