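"""Welch ANOVA and Games-Howell against algebraic identities and pingouin."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from finpheno.errors import DegenerateVarianceError, InsufficientDataError
from finpheno.group_inference import (
    GroupSample,
    games_howell,
    phase_groups,
    phase_summary,
    welch_anova,
)


def groups_from(*value_lists, labels=None):
    labels = labels or [f"g{i}" for i in range(len(value_lists))]
    return [GroupSample(lab, tuple(map(float, v))) for lab, v in zip(labels, value_lists)]


def random_groups(rng, k=None):
    k = k or int(rng.integers(2, 5))
    return groups_from(*[
        rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), size=int(rng.integers(3, 31)))
        for _ in range(k)
    ])


class TestWelchAnova:
    def test_identical_groups_null(self):
        res = welch_anova(groups_from([1, 2, 3], [1, 2, 3]))
        assert res.F == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_group_equals_welch_t_squared(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, size=int(rng.integers(3, 25)))
            b = rng.normal(0.5, 2, size=int(rng.integers(3, 25)))
            res = welch_anova(groups_from(a, b))
            t, p = stats.ttest_ind(a, b, equal_var=False)
            assert res.F == pytest.approx(t**2, abs=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_balanced_equal_variance_matches_classic_f(self):
        # With two groups of equal n and equal sample variance the Welch
        # denominator correction vanishes identically, so Welch F = classic F
        # exactly; for k >= 3 the correction is O(1/n) and the identity is a
        # limit, approached as n grows.
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = a + 1.5
        res = welch_anova(groups_from(a, b))
        f_classic = stats.f_oneway(a, b).statistic
        assert res.F == pytest.approx(f_classic, abs=1e-10)

        rng = np.random.default_rng(1)
        base = rng.normal(size=4000)
        groups3 = [base, base + 0.05, base - 0.02]  # identical sample variances
        res3 = welch_anova(groups_from(*groups3))
        f3 = stats.f_oneway(*groups3).statistic
        # k=3 denominator is 1 + (1/4)(k-1)^2/(k(n-1)) ~ 1 + 8.3e-5
        assert res3.F == pytest.approx(f3, rel=2e-4)

    def test_location_shift_invariance(self, rng):
        gs = random_groups(rng, k=3)
        shifted = [GroupSample(g.label, tuple(v + 17.3 for v in g.values)) for g in gs]
        r0, r1 = welch_anova(gs), welch_anova(shifted)
        assert r1.F == pytest.approx(r0.F, rel=1e-9)
        assert r1.p == pytest.approx(r0.p, rel=1e-9)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(DegenerateVarianceError, match="flat"):
            welch_anova(groups_from([1, 2, 3], [5, 5, 5], labels=["a", "flat"]))

    def test_needs_two_groups_of_two(self):
        with pytest.raises(InsufficientDataError):
            welch_anova(groups_from([1, 2, 3]))
        with pytest.raises(InsufficientDataError):
            welch_anova(groups_from([1, 2], [4]))

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(10):
            gs = random_groups(rng)
            df = pd.DataFrame(
                [(g.label, v) for g in gs for v in g.values], columns=["g", "y"]
            )
            oracle = pingouin.welch_anova(data=df, dv="y", between="g")
            res = welch_anova(gs)
            assert res.F == pytest.approx(float(oracle["F"].iloc[0]), abs=1e-8)
            assert res.p == pytest.approx(float(oracle["p_unc"].iloc[0]), abs=1e-8)
            assert res.df2 == pytest.approx(float(oracle["ddof2"].iloc[0]), abs=1e-6)


class TestGamesHowell:
    def test_identical_groups(self):
        (res,) = games_howell(groups_from([1, 2, 3], [1, 2, 3]))
        assert res.mean_diff == 0.0
        assert res.ci_low < 0 < res.ci_high
        assert res.p_adj == pytest.approx(1.0)

    def test_two_groups_reduce_to_welch_t(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, size=int(rng.integers(3, 20)))
            b = rng.normal(1, 2, size=int(rng.integers(3, 20)))
            (res,) = games_howell(groups_from(a, b))
            _, p = stats.ttest_ind(a, b, equal_var=False)
            assert res.p_adj == pytest.approx(p, abs=1e-10)

    def test_pair_count_and_symmetry(self, rng):
        gs = random_groups(rng, k=4)
        pairs = games_howell(gs)
        assert len(pairs) == 6
        for r in pairs:
            assert r.ci_low <= r.mean_diff <= r.ci_high

    def test_ci_contains_diff_at_any_alpha(self, rng):
        gs = random_groups(rng, k=3)
        wide = games_howell(gs, alpha=0.01)
        narrow = games_howell(gs, alpha=0.20)
        for w, n in zip(wide, narrow):
            assert w.ci_low <= n.ci_low and n.ci_high <= w.ci_high

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(10):
            gs = random_groups(rng)
            df = pd.DataFrame(
                [(g.label, v) for g in gs for v in g.values], columns=["g", "y"]
            )
            oracle = pingouin.pairwise_gameshowell(data=df, dv="y", between="g")
            mine = {frozenset(r.pair): r for r in games_howell(gs)}
            for _, row in oracle.iterrows():
                r = mine[frozenset((row["A"], row["B"]))]
                assert r.p_adj == pytest.approx(float(row["pval"]), abs=1e-6)
                assert r.df == pytest.approx(float(row["df"]), abs=1e-6)


class TestPhaseSummary:
    def test_constant_group(self):
        from datetime import date

        from finpheno.features import FeaturePeriod, Grain
        from finpheno.lifechart import Severity

        periods = [
            FeaturePeriod(date(2017, 1, 1 + i), Grain.DAILY, 4, 0.25, Severity.NONE)
            for i in range(5)
        ]
        table = phase_summary(periods, decimals=None)
        assert table.loc["frequency", "none"] == 4.0
        assert table.loc["volume", "none"] == 0.25

    def test_means_match_brute_force(self, chart, synthetic):
        from datetime import date

        from finpheno.features import Grain, resample
        from finpheno.preprocess import preprocess_ledger

        ledger, _ = synthetic
        labeled = preprocess_ledger(ledger, chart)
        daily = resample(labeled, Grain.DAILY, chart=chart,
                         span=(date(2017, 1, 1), date(2018, 12, 31)))
        table = phase_summary(daily, decimals=None)
        for phase in ("none", "mild", "moderate"):
            vals = [p.frequency for p in daily if p.severity.value == phase]
            assert table.loc["frequency", phase] == pytest.approx(np.mean(vals))

    def test_grouping_orders_phases(self, chart, synthetic):
        from datetime import date

        from finpheno.features import Grain, resample
        from finpheno.preprocess import preprocess_ledger

        ledger, _ = synthetic
        labeled = preprocess_ledger(ledger, chart)
        daily = resample(labeled, Grain.DAILY, chart=chart,
                         span=(date(2017, 1, 1), date(2018, 12, 31)))
        assert [g.label for g in phase_groups(daily, "frequency")] == [
            "none", "mild", "moderate"
        ]
        assert [g.label for g in phase_groups(daily, "frequency", merge=True)] == [
            "none", "symptomatic"
        ]
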