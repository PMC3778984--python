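"""The cohort statistical battery against independent oracles."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fcrkit import (correct_p, paired_t, rm_anova_2x2, spearman,
                    stepwise_regression)


class TestSpearman:
    def test_monotone_relation_gives_unity(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        assert spearman(x, np.exp(x)).value == pytest.approx(1.0)

    def test_oracle_pearson_on_average_ranks(self, rng):
        """rho equals Pearson on average-rank vectors to 1e-12 (with ties)."""
        for _ in range(100):
            x = rng.integers(0, 4, 6).astype(float)   # heavy ties
            y = rng.normal(size=6)
            if np.ptp(x) == 0:
                continue
            res = spearman(x, y)
            rx, ry = sps.rankdata(x), sps.rankdata(y)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert res.value == pytest.approx(oracle, abs=1e-12)

    def test_constant_input_refused(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_antisymmetric_under_order_reversal(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert spearman(x, -y).value == pytest.approx(-spearman(x, y).value)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(0.1, 5, 15)
        y = rng.uniform(0.1, 5, 15)
        base = spearman(x, y).value
        assert spearman(np.log(x), y ** 3).value == pytest.approx(base)

    def test_t_approximation_p_value(self, rng):
        x, y = rng.normal(size=(2, 10))
        res = spearman(x, y)
        t = res.value * np.sqrt((10 - 2) / (1 - res.value ** 2))
        assert res.p_raw == pytest.approx(2 * sps.t.sf(abs(t), 10 - 2), rel=1e-6)


class TestPairedT:
    def test_identical_pairs_refused(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_shift_refused_as_zero_variance(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])

    def test_direction_with_near_constant_differences(self, rng):
        x = np.arange(10.0)
        y = x - 1.0 + rng.normal(0, 1e-3, 10)
        res = paired_t(x, y)
        assert res.value > 100
        assert res.df == 9

    def test_textbook_formula_oracle(self, rng):
        """t equals dbar / (sd / sqrt(n)) with df = n-1, to 1e-12."""
        x, y = rng.normal(size=(2, 10))
        res = paired_t(x, y)
        d = x - y
        oracle = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert res.value == pytest.approx(oracle, abs=1e-12)
        assert res.p_raw == pytest.approx(
            2 * sps.t.sf(abs(oracle), 9), rel=1e-10)


class TestRmAnova2x2:
    def test_all_cells_equal_per_subject(self):
        cells = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        res = rm_anova_2x2(cells)
        assert res.value == 0.0

    def test_additive_effects_no_interaction(self):
        # response = subject + legEffect + sideEffect, noise off -> F = 0
        subj = np.array([0.0, 1.0, 2.0, 5.0])
        leg = np.array([0.0, 0.0, 0.5, 0.5])
        # power-of-two effects keep the additivity exact in floating point
        side = np.array([0.0, 0.25, 0.0, 0.25])
        cells = subj[:, None] + leg[None, :] + side[None, :]
        assert rm_anova_2x2(cells).value == 0.0

    def test_equals_squared_paired_t_oracle(self, rng):
        """Interaction F = t^2 of the difference-of-differences paired t."""
        for _ in range(20):
            cells = rng.normal(size=(8, 4))
            res = rm_anova_2x2(cells)
            dod = (cells[:, 0] - cells[:, 1]) - (cells[:, 2] - cells[:, 3])
            t, p = sps.ttest_1samp(dod, 0.0)
            assert res.value == pytest.approx(t ** 2, abs=1e-10)
            assert res.p_raw == pytest.approx(p, abs=1e-10)
            assert res.df == (1.0, 7.0)

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        cells = rng.normal(size=(9, 4))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(9), 4),
            "leg": np.tile(["p", "p", "n", "n"], 9),
            "side": np.tile(["i", "c", "i", "c"], 9),
            "slope": cells.ravel(),
        })
        aov = pg.rm_anova(data=long, dv="slope", within=["leg", "side"],
                          subject="subject", detailed=True)
        f_pg = float(aov.loc[aov["Source"] == "leg * side", "F"].iloc[0])
        assert rm_anova_2x2(cells).value == pytest.approx(f_pg, rel=1e-9)

    def test_missing_cell_refused(self):
        cells = np.ones((4, 4))
        cells[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2x2(cells)


class TestCorrectP:
    @pytest.mark.parametrize("p, m, expected", [
        (0.02, 3, 0.06),
        (0.5, 4, 1.0),      # capping
        (0.37, 1, 0.37),    # identity
    ])
    def test_examples(self, p, m, expected):
        assert correct_p(p, m) == pytest.approx(expected)

    @given(st.floats(0, 1), st.integers(1, 50))
    @settings(max_examples=100)
    def test_never_exceeds_one_and_monotone(self, p, m):
        c = correct_p(p, m)
        assert 0 <= c <= 1
        assert c >= p or c == 1.0
        assert correct_p(p, m + 1) >= c
        if p < 1:
            assert correct_p(min(1.0, p + 0.01), m) >= c

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            correct_p(1.5, 2)
        with pytest.raises(ValueError):
            correct_p(0.5, 0)


class TestStepwise:
    def test_perfect_single_candidate(self, rng):
        x = rng.normal(size=50)
        with np.errstate(all="ignore"):
            res = stepwise_regression(pd.DataFrame({"a": x}), x)
        assert res.entered == ("a",)
        assert res.r_squared == pytest.approx(1.0)

    def test_null_outcome_mostly_empty(self):
        """Forward selection stays empty under the null in most replicates.

        With two independent candidates and per-candidate entry at
        p < 0.05, the chance some candidate enters is about
        1 - 0.95^2 = 9.75%, so the expected empty fraction is ~0.90;
        asserting >= 0.85 over 100 seeded replicates sits more than two
        binomial standard errors below that expectation.
        """
        empty = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame({"a": rng.normal(size=50),
                              "b": rng.normal(size=50)})
            y = rng.normal(size=50)
            empty += len(stepwise_regression(X, y).entered) == 0
        assert empty / n_rep >= 0.85

    def test_dominant_predictor_enters_first(self, rng):
        sev = rng.uniform(size=60)
        X = pd.DataFrame({
            "weak": sev + rng.normal(0, 2.0, 60),
            "strong": sev + rng.normal(0, 0.05, 60),
        })
        y = 34 - 22 * sev + rng.normal(0, 0.5, 60)
        assert stepwise_regression(X, y).entered[0] == "strong"

    def test_collinear_candidate_dropped_with_warning(self, rng):
        a = rng.normal(size=40)
        X = pd.DataFrame({"a": a, "twice_a": 2 * a, "b": rng.normal(size=40)})
        y = a + rng.normal(0, 0.1, 40)
        with pytest.warns(UserWarning, match="aliased"):
            res = stepwise_regression(X, y)
        assert "twice_a" in res.dropped_aliased

    def test_needs_enough_observations(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 4.0]})
        with pytest.raises(ValueError, match="need n"):
            stepwise_regression(X, [1.0, 2.0, 3.0])
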