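"""Burstiness statistic and interval schemes against analytic and brute-force oracles."""

import math
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finpheno.errors import InsufficientDataError, UndefinedStatisticError
from finpheno.features import FeaturePeriod, Grain
from finpheno.ledger_ingest import Account
from finpheno.lifechart import Severity
from finpheno.preprocess import LabeledTransaction
from finpheno.temporal_stats import (
    IntervalSample,
    Scheme,
    burstiness,
    burstiness_by_phase,
    burstiness_from_r,
    intervals_C,
    intervals_D,
)


def daily_series(frequencies, start=date(2017, 1, 1), severities=None):
    out = []
    for i, f in enumerate(frequencies):
        sev = severities[i] if severities else Severity.NONE
        out.append(FeaturePeriod(start + timedelta(days=i), Grain.DAILY, f,
                                 0.1 * f, sev))
    return out


class TestIntervalsD:
    def test_same_day_yields_zero_interval(self):
        d = date(2017, 1, 1)
        sample = intervals_D([d, d, date(2017, 1, 3)])
        assert sample.intervals == (0.0, 2.0)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            intervals_D([date(2017, 1, 1)])
        with pytest.raises(InsufficientDataError):
            intervals_D([date(2017, 1, 1), date(2017, 1, 2)])

    @given(offsets=st.lists(st.integers(0, 2000), min_size=3, max_size=300))
    @settings(max_examples=100, deadline=None)
    def test_telescoping_sum(self, offsets):
        dates = [date(2015, 1, 1) + timedelta(days=o) for o in offsets]
        sample = intervals_D(dates)
        assert sample.n == len(dates) - 1
        assert sum(sample.intervals) == (max(dates) - min(dates)).days


class TestIntervalsC:
    def test_zero_run_lengths(self):
        # spend on days 1, 4, 5, 8 of an 8-day span -> runs of 2 and 2
        series = daily_series([1, 0, 0, 1, 1, 0, 0, 1])
        sample = intervals_C(series)
        assert sample.intervals == (2.0, 2.0)

    def test_spending_every_day(self):
        with pytest.raises(InsufficientDataError):
            intervals_C(daily_series([1, 2, 1, 3]))

    def test_edge_runs_included_by_default(self):
        series = daily_series([0, 0, 1, 0, 1, 0, 0, 0])
        assert intervals_C(series).intervals == (2.0, 1.0, 3.0)
        # excluding censored edge runs leaves only the interior run
        with pytest.raises(InsufficientDataError):
            intervals_C(series, include_edges=False)

    @given(bits=st.lists(st.integers(0, 1), min_size=2, max_size=300))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_run_length_encoding(self, bits):
        series = daily_series(bits)
        # oracle: split the 0/1 string on 1s and measure the zero chunks
        runs = [len(chunk) for chunk in "".join(map(str, bits)).split("1") if chunk]
        if len(runs) < 2:
            with pytest.raises(InsufficientDataError):
                intervals_C(series)
        else:
            assert list(intervals_C(series).intervals) == [float(r) for r in runs]


class TestBurstiness:
    def test_constant_intervals_give_minus_one(self):
        res = burstiness(IntervalSample(Scheme.D, (5.0, 5.0, 5.0, 5.0)))
        assert res.B == -1.0
        assert res.sigma == 0.0 and res.r == 0.0

    def test_known_hand_computation(self):
        # intervals [1,2,3]: tau=2, population sigma=sqrt(2/3)
        res = burstiness(IntervalSample(Scheme.D, (1.0, 2.0, 3.0)))
        r = math.sqrt(2.0 / 3.0) / 2.0
        assert res.B == pytest.approx((r - 1) / (r + 1), abs=1e-12)
        assert res.B == pytest.approx(-0.420, abs=5e-4)

    def test_exponential_intervals_near_zero(self, rng):
        x = rng.exponential(1.0, size=10_000)
        res = burstiness(IntervalSample(Scheme.D, tuple(x)))
        assert abs(res.B) < 0.03

    def test_all_zero_intervals_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            burstiness(IntervalSample(Scheme.D, (0.0, 0.0, 0.0)))

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientDataError):
            burstiness(IntervalSample(Scheme.D, (1.0,)))

    @given(
        intervals=st.lists(
            st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=100
        ).filter(lambda xs: max(xs) > 1e-3),
        scale=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=150, deadline=None)
    def test_range_and_scale_invariance(self, intervals, scale):
        res = burstiness(IntervalSample(Scheme.D, tuple(intervals)))
        assert -1.0 <= res.B < 1.0
        assert (res.B == -1.0) == (res.sigma == 0.0)
        scaled = burstiness(IntervalSample(Scheme.D, tuple(x * scale for x in intervals)))
        assert scaled.B == pytest.approx(res.B, abs=1e-9)

    def test_monotone_in_dispersion(self):
        # fixed tau=1, increasing sigma: B strictly increases
        bs = []
        for spread in [0.0, 0.2, 0.5, 0.9]:
            res = burstiness(IntervalSample(Scheme.D, (1 - spread, 1 + spread)))
            bs.append(res.B)
        assert bs == sorted(bs) and len(set(bs)) == len(bs)

    def test_spike_limit(self):
        assert burstiness_from_r(1e6) > 0.99999
        assert burstiness_from_r(0.0) == -1.0
        assert burstiness_from_r(1.0) == 0.0

    def test_sample_sigma_option(self):
        pop = burstiness(IntervalSample(Scheme.D, (1.0, 2.0, 3.0)), ddof=0)
        samp = burstiness(IntervalSample(Scheme.D, (1.0, 2.0, 3.0)), ddof=1)
        assert samp.sigma > pop.sigma and samp.B > pop.B

    def test_exponential_null_mean(self, rng):
        """Memoryless process: mean B over replicates is tightly around 0."""
        bs = [
            burstiness(IntervalSample(Scheme.D, tuple(rng.exponential(1, 10_000)))).B
            for _ in range(50)
        ]
        assert -0.01 < float(np.mean(bs)) < 0.01


class TestBurstinessByPhase:
    def lts(self, dates, severities):
        return [
            LabeledTransaction(d, Account.CHECKING, 0.1, s)
            for d, s in zip(dates, severities)
        ]

    def test_all_none_phase_equals_overall(self):
        dates = [date(2017, 1, 1) + timedelta(days=int(o)) for o in
                 [0, 0, 2, 3, 7, 8, 8, 12]]
        txns = self.lts(dates, [Severity.NONE] * len(dates))
        daily = daily_series([2, 0, 1, 1, 0, 0, 0, 2, 1, 0, 0, 0, 1])
        results = burstiness_by_phase(txns, daily, Scheme.D)
        by_phase = {r.phase: r for r in results}
        assert by_phase["none"].B == by_phase["overall"].B
        assert not by_phase["mild"].defined and not by_phase["moderate"].defined

    def test_merge_gives_two_phases_plus_overall(self, chart, synthetic):
        from finpheno.features import resample
        from finpheno.preprocess import preprocess_ledger

        ledger, _ = synthetic
        labeled = preprocess_ledger(ledger, chart)
        daily = resample(labeled, Grain.DAILY, chart=chart,
                         span=(date(2017, 1, 1), date(2018, 12, 31)))
        results = burstiness_by_phase(labeled, daily, Scheme.D, merge=True)
        assert [r.phase for r in results] == ["none", "symptomatic", "overall"]

    def test_phase_samples_match_brute_force_masking(self, chart, synthetic):
        from finpheno.features import resample
        from finpheno.preprocess import preprocess_ledger

        ledger, _ = synthetic
        labeled = preprocess_ledger(ledger, chart)
        daily = resample(labeled, Grain.DAILY, chart=chart,
                         span=(date(2017, 1, 1), date(2018, 12, 31)))
        results = {r.phase: r for r in burstiness_by_phase(labeled, daily, Scheme.D)}
        for phase in ("none", "mild", "moderate"):
            dates = [t.date for t in labeled if t.severity.value == phase]
            expected = burstiness(intervals_D(dates), phase=phase)
            assert results[phase].B == expected.B
            assert results[phase].n == expected.n
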