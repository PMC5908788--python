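import itertools

import numpy as np
import pytest
from scipy.stats import kendalltau

from circatf import (
    build_reference_grid,
    classify_rhythmic,
    exact_null_pvalue,
    jtk_cycle,
    kendall_s,
)
from circatf.rhythm import admissible_periods

from conftest import TWO_CYCLE, cosine


def brute_force_pvalue(s_obs: int, tie_pattern) -> float:
    """Oracle: enumerate every ordering of n distinct data values against a
    reference with the given tie groups and count |S| >= |s_obs|."""
    ranks = np.repeat(np.arange(len(tie_pattern)), tie_pattern).astype(float)
    n = len(ranks)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        s, _, _ = kendall_s(np.array(perm, dtype=float), ranks)
        total += 1
        if abs(s) >= abs(s_obs):
            count += 1
    return count / total


class TestReferenceGrid:
    def test_default_grid_shape(self, config):
        grid = build_reference_grid(TWO_CYCLE, config)
        periods = sorted({t.period_h for t in grid})
        assert periods == [21.0, 24.0, 27.0]
        lag_counts = {p: sum(1 for t in grid if t.period_h == p) for p in periods}
        assert lag_counts == {21.0: 7, 24.0: 8, 27.0: 9}
        assert len(grid) <= 24

    def test_degenerate_range_single_period(self, config):
        cfg = config.replace(period_range_h=(24.0, 24.0))
        grid = build_reference_grid(TWO_CYCLE, cfg)
        assert {t.period_h for t in grid} == {24.0}
        assert len(grid) == 8

    def test_divisibility_rule(self):
        assert admissible_periods((20, 28), 6.0) == [24.0]

    def test_no_admissible_period_raises(self, config):
        from circatf.io import ConfigError

        with pytest.raises(ConfigError):
            config.replace(period_range_h=(25.0, 26.0))


class TestKendallS:
    def test_perfect_concordance(self):
        ranks = np.arange(8, dtype=float)
        s, tau, _ = kendall_s(ranks + 0.5, ranks)
        assert tau == 1.0

    def test_perfect_discordance(self):
        ranks = np.arange(8, dtype=float)
        s, tau, _ = kendall_s(ranks[::-1].copy(), ranks)
        assert tau == -1.0

    def test_hand_computed_example(self):
        s, tau, _ = kendall_s([3, 1, 4, 2], [1, 2, 3, 4])
        assert s == 0
        assert tau == 0.0

    def test_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            ranks = np.argsort(np.argsort(y)).astype(float)
            _, tau, _ = kendall_s(x, ranks)
            assert tau == pytest.approx(kendalltau(x, y).statistic, abs=1e-12)

    def test_missing_excluded_pairwise(self):
        x = np.array([1.0, np.nan, 2.0, 3.0, 4.0])
        s, tau, n = kendall_s(x, np.arange(5, dtype=float))
        assert n == 4
        assert tau == 1.0


class TestExactNull:
    def test_no_tie_max_s(self):
        assert exact_null_pvalue(6, 4, (1, 1, 1, 1)) == pytest.approx(1 / 12)

    def test_s_zero_is_one(self):
        assert exact_null_pvalue(0, 5, (1, 1, 1, 1, 1)) == 1.0

    def test_tie_pattern_must_sum(self):
        with pytest.raises(ValueError):
            exact_null_pvalue(2, 5, (2, 2))

    @pytest.mark.parametrize(
        "pattern",
        [(1, 1, 1, 1), (2, 2, 1), (2, 3), (1, 1, 2, 2), (3, 3), (2, 2, 2)],
    )
    def test_dp_equals_enumeration(self, pattern):
        n = sum(pattern)
        m_pairs = n * (n - 1) // 2 - sum(t * (t - 1) // 2 for t in pattern)
        for s in range(0, m_pairs + 1):
            assert exact_null_pvalue(s, n, pattern) == pytest.approx(
                brute_force_pvalue(s, pattern), abs=1e-12
            )

    def test_null_symmetric_superuniform(self):
        """Null p-values of white noise are (conservatively) super-uniform."""
        rng = np.random.default_rng(12)
        pattern = (2, 2, 4, 4, 4)  # a default-grid tie pattern at n=16
        ranks = np.repeat(np.arange(5.0), pattern)
        ps = []
        for _ in range(500):
            s, _, _ = kendall_s(rng.normal(size=16), ranks)
            ps.append(exact_null_pvalue(s, 16, pattern))
        ps = np.array(ps)
        for a in (0.05, 0.1, 0.25):
            assert (ps <= a).mean() <= a + 2 * np.sqrt(a * (1 - a) / 500)


class TestJtkCycle:
    def test_noiseless_cosine_recovered(self, matrix_factory, config):
        m = matrix_factory(
            {"A": cosine(TWO_CYCLE, 10, 2, acrophase=6)}, norm_state="raw"
        )
        rt = jtk_cycle(m.with_values(m.data.to_numpy(), "fot"), config)
        row = rt.iloc[0]
        assert row.best_period_h == 24.0
        assert row.best_lag_h == 6.0
        assert row.p_adj < 0.001
        assert row.rhythmic

    def test_constant_feature_degenerate(self, matrix_factory, config):
        m = matrix_factory({"A": [3.0] * 16}, norm_state="raw")
        rt = jtk_cycle(m.with_values(m.data.to_numpy(), "fot"), config)
        assert rt.iloc[0].p_adj == 1.0
        assert not rt.iloc[0].rhythmic

    def test_monotone_transform_invariance(self, matrix_factory, config):
        """A rank test is unchanged by strictly monotone transforms."""
        rng = np.random.default_rng(5)
        x = cosine(TWO_CYCLE, 5, 1, acrophase=9) + rng.normal(0, 0.3, 16)
        m1 = matrix_factory({"A": x}, norm_state="raw")
        m2 = matrix_factory({"A": np.exp(x / 2)}, norm_state="raw")
        r1 = jtk_cycle(m1.with_values(m1.data.to_numpy(), "fot"), config)
        r2 = jtk_cycle(m2.with_values(m2.data.to_numpy(), "fot"), config)
        for col in ("best_period_h", "best_lag_h", "tau", "S", "p_raw", "p_adj"):
            assert r1.iloc[0][col] == pytest.approx(r2.iloc[0][col])

    def test_missing_values_handled(self, matrix_factory, config):
        x = cosine(TWO_CYCLE, 10, 3, acrophase=12).astype(float)
        x[[2, 9]] = np.nan
        rt = jtk_cycle(
            matrix_factory({"A": x}, norm_state="raw").with_values(
                np.array([x]), "fot"
            ),
            config,
        )
        assert rt.iloc[0].p_adj < 0.01
        assert abs(rt.iloc[0].best_lag_h - 12.0) <= 3.0

    def test_bonferroni_relation(self, matrix_factory, config):
        m = matrix_factory(
            {"A": cosine(TWO_CYCLE, 10, 2, acrophase=3)}, norm_state="raw"
        )
        grid = build_reference_grid(TWO_CYCLE, config)
        rt = jtk_cycle(m.with_values(m.data.to_numpy(), "fot"), config)
        assert rt.iloc[0].p_adj == pytest.approx(
            min(1.0, rt.iloc[0].p_raw * len(grid))
        )


class TestClassifyRhythmic:
    def test_strict_boundary(self, matrix_factory, config):
        import pandas as pd

        rt = pd.DataFrame(
            {
                "feature_id": ["a", "b", "c"],
                "p_adj": [0.1, 0.05, 0.01],
            }
        )
        out = classify_rhythmic(rt, 0.1)
        assert list(out.rhythmic) == [False, True, True]
        out = classify_rhythmic(rt, 0.05)
        assert list(out.rhythmic) == [False, False, True]

    def test_alpha_validated(self):
        import pandas as pd

        with pytest.raises(ValueError):
            classify_rhythmic(pd.DataFrame({"p_adj": []}), 0.0)
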