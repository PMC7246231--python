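"""Deviation pairing, case stratification, and agreement statistics."""

import math

import numpy as np
import pytest

from rrband import RREstimate, default_band_table
from rrband.agreement import (
    AgreementStats,
    DeviationRecord,
    agreement_stats,
    bland_altman_table,
    filter_case,
    pair_deviations,
    subgroup_stats,
)
from rrband.errors import (
    EmptyResultError,
    InsufficientDataError,
    InvalidParameterError,
)

# The five large-deviation pairs used as a worked fixture: (mean, deviation)
OUTLIER_PAIRS = [(23.0, 10.77), (19.0, 7.45), (26.0, -9.9),
                 (23.0, -9.98), (22.0, -12.1)]


def _est(minute, rr, quality="ok"):
    return RREstimate(rr_bpm=rr, rr_pass1_bpm=rr, band_index=0,
                      window_index=minute, start_s=minute * 60.0, quality=quality)


def _rec(subject, minute, dev, mean=20.0, interrupted=False, age_group=None):
    return DeviationRecord(
        subject_id=subject, minute_index=minute,
        device_rr=mean + dev / 2.0, reference_count=mean - dev / 2.0,
        interrupted=interrupted, age_group=age_group,
    )


class TestPairDeviations:
    def test_deviation_and_mean_are_exact(self):
        recs = pair_deviations([_est(0, 28.385)], [17.615])
        assert recs[0].deviation == pytest.approx(10.77)
        assert recs[0].mean_rr == pytest.approx(23.0)

    def test_equal_values_give_zero_deviation(self):
        assert pair_deviations([_est(0, 18.0)], [18.0])[0].deviation == 0.0

    def test_at_most_one_record_per_reference_minute(self):
        estimates = [_est(m, 18.0) for m in range(5)]  # 5 windows, 4 counts
        recs = pair_deviations(estimates, [18, 18, 18, 18])
        assert len(recs) == 4

    def test_unusable_minutes_dropped(self):
        estimates = [_est(0, 18.0), _est(1, float("nan"), "no_breaths"),
                     _est(2, 19.0, "corrupted")]
        recs = pair_deviations(estimates, [18, 18, 18])
        assert [r.minute_index for r in recs] == [0]

    def test_no_overlap_is_an_error(self):
        with pytest.raises(EmptyResultError):
            pair_deviations([_est(0, float("nan"), "no_breaths")], [18.0])

    def test_interrupts_and_age_carried(self):
        recs = pair_deviations([_est(0, 18.0)], [17.0], interrupts=[True], age=60.0)
        assert recs[0].interrupted is True
        assert recs[0].age_group == "ge55"


class TestFilterCase:
    @pytest.fixture
    def records_by_mode(self):
        def subject(sid, interrupted_minutes):
            return [
                _rec(sid, m, dev=0.5, interrupted=(m in interrupted_minutes))
                for m in range(4)
            ]
        by_mode = {}
        for mode in ("normal", "subbanded"):
            recs = []
            recs += subject("clean_a", set())
            recs += subject("clean_b", set())
            recs += subject("partial", {1})
            recs += subject("all_int", {0, 1, 2, 3})
            by_mode[mode] = recs
        return by_mode

    def test_exclude_interrupts_keeps_fully_clean_subjects(self, records_by_mode):
        for case, mode in ((1, "normal"), (2, "subbanded")):
            recs, got_mode = filter_case(records_by_mode, case)
            assert got_mode == mode
            assert {r.subject_id for r in recs} == {"clean_a", "clean_b"}

    def test_include_interrupts_drops_only_interrupted_minutes(self, records_by_mode):
        recs, mode = filter_case(records_by_mode, 3)
        assert mode == "normal"
        assert {r.subject_id for r in recs} == {"clean_a", "clean_b", "partial"}
        partial = [r for r in recs if r.subject_id == "partial"]
        assert [r.minute_index for r in partial] == [0, 2, 3]

    def test_case1_subset_of_case3(self, records_by_mode):
        case1, _ = filter_case(records_by_mode, 1)
        case3, _ = filter_case(records_by_mode, 3)
        assert set(map(id, [])) == set()  # sanity no-op
        key = lambda r: (r.subject_id, r.minute_index)
        assert {key(r) for r in case1} <= {key(r) for r in case3}

    def test_no_interrupts_makes_cases_coincide(self):
        by_mode = {m: [_rec("s", i, 0.1) for i in range(4)]
                   for m in ("normal", "subbanded")}
        assert filter_case(by_mode, 1)[0] == filter_case(by_mode, 3)[0]

    def test_unknown_case_rejected(self, records_by_mode):
        with pytest.raises(InvalidParameterError):
            filter_case(records_by_mode, 5)


def brute_force_stats(dev, method):
    """Independent oracle with explicit loops (no numpy reductions)."""
    n = len(dev)
    mean = sum(dev) / n
    var = sum((d - mean) ** 2 for d in dev) / (n - 1)
    std = math.sqrt(var)
    if method == "parametric_loa":
        lo, hi = mean - 1.96 * std, mean + 1.96 * std
    else:
        s = sorted(dev)
        def pct(q):
            # linear interpolation between closest ranks (numpy default)
            h = (n - 1) * q
            f = math.floor(h)
            c = min(f + 1, n - 1)
            return s[f] + (h - f) * (s[c] - s[f])
        lo, hi = pct(0.025), pct(0.975)
    return mean, std, lo, hi


class TestAgreementStats:
    def test_degenerate_all_zero(self):
        st = agreement_stats([0.0, 0.0, 0.0])
        assert (st.bias, st.std, st.interval95) == (0.0, 0.0, (0.0, 0.0))

    def test_small_example(self):
        st = agreement_stats([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert st.bias == 0.0
        assert st.std == pytest.approx(math.sqrt(2.5), abs=1e-12)

    def test_parametric_interval_formula(self):
        dev = np.random.default_rng(0).normal(0.05, 2.56, size=500)
        st = agreement_stats(dev, "parametric_loa")
        assert st.interval95[0] == pytest.approx(st.bias - 1.96 * st.std)
        assert st.interval95[1] == pytest.approx(st.bias + 1.96 * st.std)
        assert st.interval95[1] - st.interval95[0] == pytest.approx(2 * 1.96 * st.std)

    @pytest.mark.parametrize("method", ["empirical_percentile", "parametric_loa"])
    def test_matches_explicit_loop_oracle(self, method):
        rng = np.random.default_rng(123)
        for _ in range(50):
            dev = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 3),
                             size=rng.integers(5, 60))
            st = agreement_stats(dev, method)
            mean, std, lo, hi = brute_force_stats(dev.tolist(), method)
            assert st.bias == pytest.approx(mean, abs=1e-12)
            assert st.std == pytest.approx(std, abs=1e-12)
            assert st.interval95[0] == pytest.approx(lo, abs=1e-12)
            assert st.interval95[1] == pytest.approx(hi, abs=1e-12)

    def test_empirical_interval_coverage(self):
        dev = np.random.default_rng(7).normal(size=400)
        st = agreement_stats(dev, "empirical_percentile")
        below = np.sum(dev < st.interval95[0])
        above = np.sum(dev > st.interval95[1])
        assert below <= 0.025 * dev.size + 1
        assert above <= 0.025 * dev.size + 1

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            agreement_stats([1.0])

    def test_unknown_method(self):
        with pytest.raises(InvalidParameterError):
            agreement_stats([1.0, 2.0], "bootstrap")


class TestBlandAltman:
    def test_outlier_pairs_round_trip(self):
        records = []
        for i, (mean, dev) in enumerate(OUTLIER_PAIRS):
            est = _est(0, mean + dev / 2.0)
            rec = pair_deviations([est], [mean - dev / 2.0], subject_id=i)[0]
            records.append(rec)
        table, stats, edges = bland_altman_table(
            records, band_table=default_band_table()
        )
        np.testing.assert_allclose(table["mean_rr"], [p[0] for p in OUTLIER_PAIRS])
        np.testing.assert_allclose(table["deviation"], [p[1] for p in OUTLIER_PAIRS])
        assert edges == [20.0, 27.0]
        assert stats is not None and stats.n == 5

    def test_single_record_suppresses_interval(self):
        table, stats, edges = bland_altman_table([_rec("s", 0, 1.0)])
        assert len(table) == 1 and stats is None

    def test_symmetric_deviations_center_bias_at_zero(self):
        recs = [_rec("s", i, d) for i, d in enumerate([-2.0, -1.0, 1.0, 2.0])]
        _, stats, _ = bland_altman_table(recs)
        assert stats.bias == 0.0

    def test_empty_rejected(self):
        with pytest.raises(EmptyResultError):
            bland_altman_table([])


class TestSubgroups:
    def test_age_split_gives_two_rows(self):
        recs = [_rec("a", i, 0.5, age_group="lt55") for i in range(4)]
        recs += [_rec("b", i, -0.5, age_group="ge55") for i in range(4)]
        out = subgroup_stats(recs)
        assert set(out) == {"lt55", "ge55"}
        stats, box = out["lt55"]
        assert isinstance(stats, AgreementStats)
        assert box.median == pytest.approx(0.5)

    def test_single_group(self):
        recs = [_rec("a", i, 0.5, age_group="lt55") for i in range(4)]
        assert set(subgroup_stats(recs)) == {"lt55"}

    def test_identical_distributions_have_equal_bias(self):
        rng = np.random.default_rng(5)
        devs = rng.normal(0.2, 1.0, size=200)
        recs = [_rec("a", i, d, age_group="lt55") for i, d in enumerate(devs)]
        recs += [_rec("b", i, d, age_group="ge55") for i, d in enumerate(devs)]
        out = subgroup_stats(recs)
        assert out["lt55"][0].bias == pytest.approx(out["ge55"][0].bias)

    def test_tiny_group_skipped(self):
        recs = [_rec("a", i, 0.5, age_group="lt55") for i in range(4)]
        recs += [_rec("b", 0, 9.0, age_group="ge55")]
        assert set(subgroup_stats(recs)) == {"lt55"}

    def test_boxplot_whiskers_within_fences(self):
        rng = np.random.default_rng(9)
        devs = np.concatenate([rng.normal(size=100), [8.0, -9.0]])
        recs = [_rec("a", i, d, age_group="lt55") for i, d in enumerate(devs)]
        _, box = subgroup_stats(recs)["lt55"]
        iqr = box.q3 - box.q1
        assert box.whisker_low >= box.q1 - 1.5 * iqr
        assert box.whisker_high <= box.q3 + 1.5 * iqr
        assert box.whisker_high < 8.0  # outliers excluded from whiskers
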