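"""Follow-up pairing, indicator arithmetic, and risk adjustment."""

import datetime as dt

import numpy as np
import pytest

import interrai_mh as m
from interrai_mh.errors import UndefinedStatisticError
from interrai_mh.quality import PairingLog, _event

from conftest import make_record


def _rec(registry, person, reason, day, level="max"):
    return make_record(
        registry,
        person_id=person,
        reason=reason,
        date=dt.date(2017, 1, 1) + dt.timedelta(days=day),
    )


def make_pair(baseline, followup, scale="positive_symptoms", scale_max=12, **cov):
    return m.QIPair(
        person_id="p",
        scale=scale,
        baseline=baseline,
        followup=followup,
        baseline_covariates=cov,
        period=2017,
        scale_max=scale_max,
    )


class TestPairFollowups:
    def test_discharge_within_window_is_used(self, registry, scale_defs):
        recs = [_rec(registry, "a", "admission", 0), _rec(registry, "a", "discharge", 30)]
        pairs, log = m.pair_followups(recs, scale_defs, ["positive_symptoms"])
        assert len(pairs) == 1 and log.paired == 1

    def test_day_90_review_beats_later_discharge(self, registry, scale_defs):
        """Admission day 0, review day 90, discharge day 120: the review pairs."""
        recs = [
            _rec(registry, "a", "admission", 0),
            _rec(registry, "a", "review", 90),
            _rec(registry, "a", "discharge", 120),
        ]
        pairs, log = m.pair_followups(recs, scale_defs, ["positive_symptoms"])
        assert len(pairs) == 1 and log.paired == 1

    def test_admission_without_followup_excluded_and_counted(self, registry, scale_defs):
        recs = [_rec(registry, "a", "admission", 0), _rec(registry, "a", "discharge", 120)]
        pairs, log = m.pair_followups(recs, scale_defs, ["positive_symptoms"])
        assert pairs == [] and log.no_followup == 1

    def test_non_monotone_dates_logged_and_skipped(self, registry, scale_defs):
        recs = [
            _rec(registry, "a", "admission", 10),
            _rec(registry, "a", "review", 5),  # dated before the admission
        ]
        pairs, log = m.pair_followups(recs, scale_defs, ["positive_symptoms"])
        assert pairs == [] and len(log.episode_errors) == 1

    def test_pair_count_matches_episode_walk_oracle(self, registry, scale_defs):
        """200 synthetic episodes with known structure vs a brute-force count."""
        rng = np.random.default_rng(40)
        recs, expected = [], 0
        for i in range(200):
            pid = f"e{i}"
            recs.append(_rec(registry, pid, "admission", 0))
            shape = rng.integers(0, 4)
            if shape == 0:
                pass  # no follow-up
            elif shape == 1:
                recs.append(_rec(registry, pid, "discharge", int(rng.integers(1, 91))))
                expected += 1
            elif shape == 2:
                recs.append(_rec(registry, pid, "review", int(rng.integers(1, 91))))
                recs.append(_rec(registry, pid, "discharge", 150))
                expected += 1
            else:
                recs.append(_rec(registry, pid, "discharge", int(rng.integers(91, 200))))
        pairs, log = m.pair_followups(recs, scale_defs, ["positive_symptoms"])
        assert len(pairs) == expected
        assert log.paired == expected

    def test_one_pair_per_admission_episode(self, registry, scale_defs):
        recs = [
            _rec(registry, "a", "admission", 0),
            _rec(registry, "a", "review", 10),
            _rec(registry, "a", "discharge", 20),
            _rec(registry, "a", "admission", 100),
            _rec(registry, "a", "discharge", 130),
        ]
        pairs, log = m.pair_followups(recs, scale_defs, ["positive_symptoms"])
        assert len(pairs) == 2


class TestComputeQi:
    def test_improvement_hand_enumeration(self):
        pairs = [make_pair(b, f) for b, f in zip([3, 0, 2, 5], [1, 0, 2, 4])]
        table = m.compute_qi(pairs, "improvement")
        row = table.iloc[0]
        # denominator: baselines > 0 -> {3, 2, 5}; events: 3->1 and 5->4
        assert row.numerator == 2 and row.denominator == 3
        assert row.rate == pytest.approx(2 / 3)

    def test_failure_hand_enumeration(self):
        pairs = [make_pair(b, f) for b, f in zip([3, 0, 2, 5], [1, 0, 2, 4])]
        table = m.compute_qi(pairs, "failure")
        row = table.iloc[0]
        # all four baselines < 12; events: 0->0 and 2->2 (followup >= baseline)
        assert row.numerator == 2 and row.denominator == 4

    def test_no_change_cohort_rates(self):
        pairs = [make_pair(b, b) for b in [1, 4, 7]]
        assert m.compute_qi(pairs, "improvement").iloc[0].rate == 0.0
        assert m.compute_qi(pairs, "failure").iloc[0].rate == 1.0

    def test_indicator_definitions_partition_interior_pairs(self):
        rng = np.random.default_rng(41)
        for _ in range(1000):
            b, f = int(rng.integers(0, 13)), int(rng.integers(0, 13))
            p = make_pair(b, f)
            imp = _event(p, "improvement")
            fail = _event(p, "failure")
            flags = [e for e in (imp, fail) if e is True]
            assert len(flags) <= 1
            if 0 < b < 12:
                assert len(flags) == 1

    def test_empty_denominator_flagged_undefined(self):
        pairs = [make_pair(0, 0)]
        table = m.compute_qi(pairs, "improvement")
        assert table.empty or bool(table.undefined.all())

    def test_mixed_scales_rejected(self):
        pairs = [make_pair(1, 0), make_pair(1, 0, scale="adl", scale_max=16)]
        with pytest.raises(m.ConfigError):
            m.compute_qi(pairs, "improvement")

    def test_strict_worsening_variant(self):
        pairs = [make_pair(2, 2), make_pair(2, 3)]
        default = m.compute_qi(pairs, "failure")
        strict = m.compute_qi(pairs, "failure", strict_worsening=True)
        assert default.iloc[0].numerator == 2
        assert strict.iloc[0].numerator == 1


class TestRiskAdjust:
    @staticmethod
    def _confounded_pairs(n, rng, stratum_effect=0.0):
        """Event driven by covariate x only; stratum composition differs on x."""
        pairs = []
        for _ in range(n):
            x = rng.random() < 0.5
            homeless = rng.random() < (0.7 if x else 0.3)
            p_event = 0.2 + 0.4 * x + stratum_effect * homeless
            improved = rng.random() < p_event
            pairs.append(
                make_pair(5, 3 if improved else 5, homeless=homeless, x=float(x))
            )
        return pairs

    def test_adjustment_removes_pure_confounding(self):
        rng = np.random.default_rng(42)
        pairs = self._confounded_pairs(20_000, rng)
        res = m.risk_adjust(pairs, "improvement", "homeless", covariates=("x",))
        res = res.set_index("stratum")
        observed_gap = abs(res.loc[True, "observed_rate"] - res.loc[False, "observed_rate"])
        adjusted_gap = abs(res.loc[True, "adjusted_rate"] - res.loc[False, "adjusted_rate"])
        assert observed_gap > 0.05  # confounding clearly visible
        assert adjusted_gap < 0.02  # removed up to Monte-Carlo error

    def test_intercept_only_model_returns_observed(self):
        rng = np.random.default_rng(43)
        pairs = self._confounded_pairs(2000, rng)
        res = m.risk_adjust(pairs, "improvement", "homeless", covariates=())
        assert np.allclose(res.observed_rate, res.adjusted_rate)
        assert bool(res.degenerate_model.all())

    def test_indirect_standardization_arithmetic(self):
        # stratum observed 0.6, expected = pooled 0.5 -> adjusted 0.6
        rng = np.random.default_rng(44)
        pairs = []
        for i in range(1000):
            homeless = i % 2 == 0
            target = 0.6 if homeless else 0.4
            improved = rng.random() < target
            pairs.append(make_pair(5, 3 if improved else 5, homeless=homeless))
        res = m.risk_adjust(pairs, "improvement", "homeless", covariates=())
        res = res.set_index("stratum")
        pooled = (res.numerator.sum()) / (res.denominator.sum())
        for stratum in (True, False):
            expected = res.loc[stratum, "observed_rate"] / pooled * pooled
            assert res.loc[stratum, "adjusted_rate"] == pytest.approx(expected)

    def test_empty_pairs_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            m.risk_adjust([make_pair(0, 0)], "improvement", "homeless")

    def test_rate_order_invariance(self):
        rng = np.random.default_rng(45)
        pairs = self._confounded_pairs(1000, rng)
        res_fwd = m.risk_adjust(pairs, "failure", "homeless", covariates=("x",))
        res_rev = m.risk_adjust(list(reversed(pairs)), "failure", "homeless", covariates=("x",))
        assert np.allclose(
            res_fwd.sort_values("stratum").adjusted_rate,
            res_rev.sort_values("stratum").adjusted_rate,
        )


class TestQiTrend:
    def test_single_period_single_row_per_stratum(self):
        rng = np.random.default_rng(46)
        pairs = TestRiskAdjust._confounded_pairs(500, rng)
        table = m.qi_trend(pairs, "improvement", "homeless", covariates=("x",))
        assert set(table.period) == {2017}
        assert len(table) == 2

    def test_identical_cohorts_identical_rates(self):
        rng = np.random.default_rng(47)
        base = TestRiskAdjust._confounded_pairs(500, rng)
        shifted = [
            m.QIPair(p.person_id, p.scale, p.baseline, p.followup, p.baseline_covariates, 2018, p.scale_max)
            for p in base
        ]
        table = m.qi_trend(base + shifted, "improvement", "homeless", covariates=("x",))
        by_year = {
            year: grp.sort_values("stratum").adjusted_rate.to_numpy()
            for year, grp in table.groupby("period")
        }
        assert np.allclose(by_year[2017], by_year[2018])

    def test_smaller_stratum_more_volatile(self, registry, scale_defs):
        """Replicate-to-replicate spread is wider for the smaller (homeless) group."""
        rates = {True: [], False: []}
        for seed in range(6):
            _, recs = m.simulate_pairs(
                m.SimConfig(n_persons=600, seed=100 + seed, p_homeless=0.15),
                registry,
                scale_defs,
            )
            pairs, _ = m.pair_followups(recs, scale_defs, ["positive_symptoms"])
            table = m.compute_qi(pairs, "improvement", "homeless").set_index("stratum")
            for s in (True, False):
                rates[s].append(table.loc[s, "rate"])
        assert np.std(rates[True]) > np.std(rates[False])
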