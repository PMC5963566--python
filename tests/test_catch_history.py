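import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harvestrisk.catch_history import (
    LandedRecord,
    LossSchedule,
    ReconstructionConfig,
    RemovalsSeries,
    ReportedCatch,
    fill_missing_years,
    loss_rate,
    reconstruct,
    to_removals,
)
from harvestrisk.errors import InputError, UnfillableRangeError

from oracles import fill_by_enumeration


def doc(year, landed, source="HLG"):
    return ReportedCatch(year=year, landed=landed, documented=True, source=source)


def missing(year, source="HLG"):
    return ReportedCatch(year=year, landed=None, documented=False, source=source)


class TestReportedCatch:
    def test_documented_requires_landed(self):
        with pytest.raises(InputError):
            ReportedCatch(year=2000, landed=None, documented=True, source="HLG")

    def test_undocumented_forbids_landed(self):
        with pytest.raises(InputError):
            ReportedCatch(year=2000, landed=5, documented=False, source="HLG")

    def test_negative_landed_rejected(self):
        with pytest.raises(InputError):
            doc(2000, -1)

    def test_unknown_source_rejected(self):
        with pytest.raises(InputError):
            ReportedCatch(year=2000, landed=5, documented=True, source="hearsay")


class TestLossSchedule:
    def test_defaults(self):
        s = LossSchedule()
        assert (s.early_rate, s.late_rate, s.ramp_start, s.ramp_end) == (0.05, 0.30, 1960, 1970)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(InputError):
            LossSchedule(early_rate=0.4, late_rate=0.3)
        with pytest.raises(InputError):
            LossSchedule(ramp_start=1975, ramp_end=1970)
        with pytest.raises(InputError):
            LossSchedule(late_rate=1.0)


class TestLossRate:
    def test_early_era(self, default_schedule):
        assert loss_rate(1950, default_schedule) == 0.05

    def test_late_era(self, default_schedule):
        assert loss_rate(1980, default_schedule) == 0.30

    def test_ramp_midpoint(self, default_schedule):
        assert loss_rate(1965, default_schedule) == pytest.approx(0.175)

    def test_continuous_at_ramp_endpoints(self, default_schedule):
        assert loss_rate(1960, default_schedule) == pytest.approx(0.05)
        assert loss_rate(1970, default_schedule) == pytest.approx(0.30)

    def test_vectorised(self, default_schedule):
        years = np.array([1950, 1965, 1980])
        np.testing.assert_allclose(loss_rate(years, default_schedule), [0.05, 0.175, 0.30])

    def test_degenerate_ramp(self):
        s = LossSchedule(ramp_start=1960, ramp_end=1960)
        assert loss_rate(1959, s) == 0.05
        assert loss_rate(1960, s) == 0.30

    @given(st.integers(min_value=1900, max_value=2020))
    def test_total_and_bounded(self, year):
        s = LossSchedule()
        r = loss_rate(year, s)
        assert 0.05 <= r <= 0.30

    @given(st.integers(min_value=1900, max_value=2019))
    def test_non_decreasing_in_year(self, year):
        s = LossSchedule()
        assert loss_rate(year + 1, s) >= loss_rate(year, s)


class TestFillMissingYears:
    def test_mean_of_two_prior_values(self, default_recon):
        series = [doc(1961, 100), doc(1962, 140)]
        filled = fill_missing_years(series, default_recon, (1961, 1963))
        assert filled[-1] == LandedRecord(1963, 120.0, extrapolated=True)

    def test_constant_series_fills_constant(self, default_recon):
        series = [doc(y, 50) for y in range(1960, 1965)]
        filled = fill_missing_years(series, default_recon, (1960, 1975))
        assert all(r.landed == 50 for r in filled)
        assert [r.extrapolated for r in filled[:5]] == [False] * 5
        assert all(r.extrapolated for r in filled[5:])

    def test_documented_values_preserved(self, default_recon):
        series = [doc(1960, 10), doc(1963, 99)]
        filled = fill_missing_years(series, default_recon, (1960, 1964))
        by_year = {r.year: r for r in filled}
        assert by_year[1963].landed == 99 and not by_year[1963].extrapolated
        assert by_year[1961].extrapolated

    def test_fills_use_documented_not_extrapolated(self, default_recon):
        # 1962-1963 are filled from 1960-1961 only; fills never feed fills
        series = [doc(1960, 100), doc(1961, 200)]
        filled = fill_missing_years(series, default_recon, (1960, 1963))
        assert filled[2].landed == 150.0
        assert filled[3].landed == 150.0

    def test_window_limits_lookback(self):
        cfg = ReconstructionConfig(fill_window=2)
        series = [doc(1960, 1000), doc(1961, 10), doc(1962, 20)]
        filled = fill_missing_years(series, cfg, (1960, 1963))
        assert filled[-1].landed == 15.0

    def test_era_boundary_not_crossed(self, default_recon):
        # 1994 fill ignores pre-1993 values once a same-era year exists
        series = [doc(1990, 1000), doc(1993, 40, source="Piniarneq")]
        filled = fill_missing_years(series, default_recon, (1990, 1995))
        by_year = {r.year: r.landed for r in filled}
        assert by_year[1994] == 40.0
        assert by_year[1995] == 40.0
        # pre-1993 fills use only pre-1993 records
        assert by_year[1991] == 1000.0

    def test_era_fallback_when_era_has_no_history(self, default_recon):
        series = [doc(1990, 120)]
        filled = fill_missing_years(series, default_recon, (1993, 1994))
        assert all(r.landed == 120.0 for r in filled)

    def test_unfillable_range(self, default_recon):
        with pytest.raises(UnfillableRangeError):
            fill_missing_years([doc(1970, 5)], default_recon, (1960, 1980))

    def test_duplicate_years_rejected(self, default_recon):
        with pytest.raises(InputError):
            fill_missing_years([doc(1960, 5), doc(1960, 6)], default_recon, (1960, 1961))

    def test_matches_enumeration_oracle_window5(self, rng):
        years = range(1950, 1980)
        documented = {}
        series = []
        for y in years:
            if rng.random() < 0.6 or y == 1950:  # keep first year documented
                landed = float(rng.integers(0, 300))
                documented[y] = landed
                series.append(doc(y, landed))
            else:
                series.append(missing(y))
        cfg = ReconstructionConfig(fill_window=5)
        filled = fill_missing_years(series, cfg, (1950, 1979))
        for rec in filled:
            if rec.extrapolated:
                assert rec.landed == pytest.approx(
                    fill_by_enumeration(documented, rec.year, 5)
                )
            else:
                assert rec.landed == documented[rec.year]


class TestToRemovals:
    def test_zero_landed(self, default_schedule, default_recon):
        assert to_removals(0, 1980, default_schedule, default_recon) == 0.0

    def test_inverse_of_five_percent_loss(self, default_schedule, default_recon):
        assert to_removals(95, 1950, default_schedule, default_recon) == pytest.approx(100.0)

    def test_thirty_percent_loss_division(self, default_schedule, default_recon):
        assert to_removals(100, 1980, default_schedule, default_recon) == pytest.approx(100 / 0.70)

    def test_underreport_factor_multiplies(self, default_schedule):
        cfg = ReconstructionConfig(underreport_factor=1.5)
        base = to_removals(100, 1980, default_schedule, ReconstructionConfig())
        assert to_removals(100, 1980, default_schedule, cfg) == pytest.approx(1.5 * base)

    def test_negative_landed_rejected(self, default_schedule, default_recon):
        with pytest.raises(InputError):
            to_removals(-1, 1980, default_schedule, default_recon)

    @given(
        landed=st.floats(min_value=0, max_value=1e4),
        factor=st.floats(min_value=1.0, max_value=3.0),
        year=st.integers(min_value=1900, max_value=2020),
    )
    def test_removals_at_least_corrected_landed(self, landed, factor, year):
        cfg = ReconstructionConfig(underreport_factor=factor)
        r = to_removals(landed, year, LossSchedule(), cfg)
        assert r >= landed * factor

    @given(
        landed=st.floats(min_value=0.1, max_value=1e4),
        f1=st.floats(min_value=1.0, max_value=2.0),
        f2=st.floats(min_value=1.0, max_value=2.0),
    )
    def test_monotone_in_underreport_factor(self, landed, f1, f2):
        lo, hi = sorted([f1, f2])
        s = LossSchedule()
        assert to_removals(landed, 1980, s, ReconstructionConfig(underreport_factor=hi)) >= \
            to_removals(landed, 1980, s, ReconstructionConfig(underreport_factor=lo))

    @given(
        landed=st.floats(min_value=0.1, max_value=1e4),
        r1=st.floats(min_value=0.0, max_value=0.9),
        r2=st.floats(min_value=0.0, max_value=0.9),
    )
    def test_monotone_in_loss_rate(self, landed, r1, r2):
        lo, hi = sorted([r1, r2])
        cfg = ReconstructionConfig()
        low = to_removals(landed, 2000, LossSchedule(early_rate=lo, late_rate=lo), cfg)
        high = to_removals(landed, 2000, LossSchedule(early_rate=hi, late_rate=hi), cfg)
        assert high >= low


class TestReconstruct:
    def test_sixties_fixture(self, default_schedule, default_recon):
        # one spike year amid a flat background: the spike survives correction
        series = [doc(y, 440 if y == 1962 else 132) for y in range(1960, 1970)]
        out = reconstruct(series, default_schedule, default_recon, (1960, 1969))
        assert out.value(1962) > out.value(1961)
        assert out.value(1962) == pytest.approx(440 / (1 - loss_rate(1962, default_schedule)))

    def test_identity_with_no_losses(self):
        schedule = LossSchedule(early_rate=0.0, late_rate=0.0)
        series = [doc(y, 10 * (y - 1959)) for y in range(1960, 1970)]
        out = reconstruct(series, schedule, ReconstructionConfig(), (1960, 1969))
        np.testing.assert_allclose(out.removals, [10 * (y - 1959) for y in range(1960, 1970)])
        assert not out.extrapolated.any()

    def test_matches_component_composition(self, rng, default_schedule, default_recon):
        series = []
        for y in range(1955, 1990):
            if rng.random() < 0.7 or y == 1955:
                series.append(doc(y, float(rng.integers(0, 500))))
            else:
                series.append(missing(y))
        out = reconstruct(series, default_schedule, default_recon, (1955, 1989))
        filled = fill_missing_years(series, default_recon, (1955, 1989))
        for rec in filled:
            expected = to_removals(rec.landed, rec.year, default_schedule, default_recon)
            assert out.value(rec.year) == pytest.approx(expected)

    def test_provenance_flags_retained(self, default_schedule, default_recon):
        series = [doc(1960, 100), missing(1961), doc(1962, 200)]
        out = reconstruct(series, default_schedule, default_recon, (1960, 1962))
        assert list(out.extrapolated) == [False, True, False]


class TestRemovalsSeries:
    def test_contiguity_enforced(self):
        with pytest.raises(InputError):
            RemovalsSeries([1960, 1962], [1.0, 2.0])

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            RemovalsSeries([1960, 1961], [1.0, -2.0])

    def test_value_lookup_and_bounds(self):
        s = RemovalsSeries([1960, 1961], [1.0, 2.0])
        assert s.value(1961) == 2.0
        with pytest.raises(KeyError):
            s.value(1959)

    def test_frame_round_trip(self):
        s = RemovalsSeries([1960, 1961, 1962], [1.0, 2.0, 3.0], [False, True, False])
        assert RemovalsSeries.from_frame(s.to_frame()) == s
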