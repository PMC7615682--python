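import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import mda8_brute
from o3hia.errors import AlignmentError, CityLookupError, DataFormatError
from o3hia.exposure import (PPB_TO_UGM3, average_members, extract_city_series,
                            locate_cell, mda8_from_hourly, ppb_to_ugm3)


def hourly(values, start="2020-06-01"):
    return pd.Series(values, index=pd.date_range(start, periods=len(values), freq="h"),
                     dtype=float)


class TestPpbConversion:
    @pytest.mark.parametrize("ppb,expected", [(1.0, 1.96), (0.0, 0.0), (50.0, 98.0)])
    def test_worked_values(self, ppb, expected):
        assert ppb_to_ugm3(ppb) == pytest.approx(expected, abs=0.0)

    def test_vectorized_and_linear(self):
        a, b = np.array([1.0, 2.5]), np.array([3.0, 0.5])
        np.testing.assert_allclose(ppb_to_ugm3(a + b), ppb_to_ugm3(a) + ppb_to_ugm3(b))

    def test_negative_rejected(self):
        with pytest.raises(DataFormatError):
            ppb_to_ugm3(-1.0)


class TestMda8:
    def test_constant_series(self):
        assert mda8_from_hourly(hourly([40.0] * 24)).tolist() == [40.0]

    def test_ramp_then_zero_day(self):
        """Hours 0..23 followed by a zero day: best window starts at hour 16."""
        s = mda8_from_hourly(hourly(list(range(24)) + [0.0] * 24))
        assert s.iloc[0] == pytest.approx(19.5)
        assert s.iloc[1] == 0.0

    def test_single_spike(self):
        v = np.zeros(72)
        v[30] = 8.0
        s = mda8_from_hourly(hourly(v))
        # the spike (day 2, hour 6) is reachable from day-1 windows crossing midnight
        assert s.tolist() == [1.0, 1.0, 0.0]

    def test_bounded_by_hourly_range(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(10, 120, size=96)
        s = mda8_from_hourly(hourly(v))
        assert ((s >= v.min()) & (s <= v.max())).all()

    def test_day_omitted_when_too_sparse(self):
        v = np.full(48, np.nan)
        v[24:] = 50.0   # first day all-missing, second complete
        s = mda8_from_hourly(hourly(v))
        assert len(s) == 1 and s.iloc[0] == 50.0

    def test_non_hourly_spacing_rejected(self):
        idx = pd.date_range("2020-01-01", periods=24, freq="30min")
        with pytest.raises(DataFormatError):
            mda8_from_hourly(pd.Series(1.0, index=idx))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.one_of(st.none(), st.floats(0, 150, allow_nan=False)),
                    min_size=24, max_size=72))
    def test_matches_brute_force(self, values):
        s = hourly([np.nan if v is None else v for v in values])
        fast = mda8_from_hourly(s)
        slow = mda8_brute(s)
        assert list(fast.index) == list(slow.index)
        np.testing.assert_allclose(fast.to_numpy(), slow.to_numpy(), rtol=1e-12, atol=1e-12)


def make_field(values, lats, lons, start="2020-06-01", units="ppb"):
    time = pd.date_range(start, periods=values.shape[0], freq="h")
    da = xr.DataArray(values, dims=("time", "lat", "lon"),
                      coords={"time": time, "lat": lats, "lon": lons}, name="o3")
    da.attrs["units"] = units
    return da


class TestExtraction:
    def test_cell_boundary_goes_to_lower_cell(self):
        centers = np.array([1.0, 3.0, 5.0])
        assert locate_cell(centers, 2.0) == 0     # shared boundary -> lower index
        assert locate_cell(centers, 2.1) == 1
        assert locate_cell(centers, 0.0) == 0
        assert locate_cell(centers, 6.0) == 2
        with pytest.raises(CityLookupError):
            locate_cell(centers, 6.5)

    def test_uniform_field_and_shared_cell(self):
        field = make_field(np.full((48, 2, 2), 30.0), [40.0, 42.0], [0.0, 2.0])
        registry = pd.DataFrame({
            "city_id": ["a", "b", "c"], "country_id": ["x", "x", "x"],
            "lat": [40.0, 40.3, 42.0], "lon": [0.0, 0.4, 2.0]})
        out = extract_city_series(field, registry)
        np.testing.assert_allclose(out["o3_mda8_ugm3"], 30.0 * PPB_TO_UGM3)
        a = out[out.city_id == "a"]["o3_mda8_ugm3"].to_numpy()
        b = out[out.city_id == "b"]["o3_mda8_ugm3"].to_numpy()
        np.testing.assert_array_equal(a, b)   # same containing cell

    def test_city_outside_grid_named_in_error(self):
        field = make_field(np.zeros((24, 2, 2)), [40.0, 42.0], [0.0, 2.0])
        registry = pd.DataFrame({"city_id": ["far"], "country_id": ["x"],
                                 "lat": [70.0], "lon": [0.0]})
        with pytest.raises(CityLookupError, match="far"):
            extract_city_series(field, registry)

    def test_missing_units_rejected(self):
        field = make_field(np.zeros((24, 1, 1)), [40.0], [0.0])
        del field.attrs["units"]
        registry = pd.DataFrame({"city_id": ["a"], "country_id": ["x"],
                                 "lat": [40.0], "lon": [0.0]})
        with pytest.raises(DataFormatError):
            extract_city_series(field, registry)


class TestAverageMembers:
    @staticmethod
    def member(vals):
        return pd.DataFrame({"city_id": "a",
                             "date": pd.date_range("2020-01-01", periods=len(vals)),
                             "o3_mda8_ugm3": vals})

    def test_single_member_identity(self):
        m = self.member([60.0, 70.0])
        pd.testing.assert_frame_equal(average_members([m]), m)

    def test_two_point_mean_and_symmetry(self):
        m1, m2 = self.member([60.0, 62.0]), self.member([80.0, 78.0])
        out12 = average_members([m1, m2])
        out21 = average_members([m2, m1])
        np.testing.assert_allclose(out12["o3_mda8_ugm3"], [70.0, 70.0])
        pd.testing.assert_frame_equal(out12, out21)

    def test_mismatched_dates_rejected(self):
        m1 = self.member([60.0, 62.0])
        m2 = self.member([60.0, 62.0])
        m2.loc[1, "date"] = pd.Timestamp("2021-01-01")
        with pytest.raises(AlignmentError):
            average_members([m1, m2])
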