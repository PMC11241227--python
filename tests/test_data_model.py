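"""Containers, table I/O, water-region masking and the censoring filter."""

import numpy as np
import pandas as pd
import pytest

from mircoag.data_model import (
    DEFAULT_WATER_REGIONS,
    SampleRecord,
    Spectra,
    WavenumberAxis,
    default_axis,
    filter_noncoagulating,
    frame_to_records,
    mask_regions,
    read_spectra,
    read_traits,
    records_to_frame,
    write_spectra,
    write_traits,
)
from mircoag.synthetic import default_config, generate_dataset


class TestAxisAndSpectra:
    def test_axis_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            WavenumberAxis(np.array([1000.0, 999.0, 1001.0]))

    def test_axis_range_guard(self):
        with pytest.raises(ValueError, match="instrument range"):
            WavenumberAxis(np.array([100.0, 200.0]))

    def test_default_axis_covers_instrument_range(self):
        axis = default_axis()
        assert len(axis) == 1060
        assert axis.values[0] == 900.0 and axis.values[-1] == 5000.0

    def test_duplicate_sample_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            Spectra(default_axis(4), np.zeros((2, 4)), ["x", "x"])

    def test_select_preserves_requested_order(self, small_spectra):
        sub = small_spectra.select(["S3", "S0"])
        assert sub.sample_ids == ["S3", "S0"]
        assert np.array_equal(sub.absorbance[0], small_spectra.absorbance[3])


class TestSpectraIO:
    def test_round_trip_is_lossless(self, tmp_path, full_grid_spectra):
        path = tmp_path / "spectra.csv"
        write_spectra(full_grid_spectra, path)
        back = read_spectra(path)
        assert back.absorbance.shape == (3, 1060)
        assert back.sample_ids == full_grid_spectra.sample_ids
        assert np.abs(back.absorbance - full_grid_spectra.absorbance).max() < 1e-12
        assert np.abs(back.axis.values - full_grid_spectra.axis.values).max() < 1e-12

    def test_headers_parse_as_wavenumbers(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("sample_id,1045.0,1076.0,1157.0\nA,0.1,0.2,0.3\n")
        spectra = read_spectra(path)
        assert 1045.0 in spectra.axis.values
        assert spectra.absorbance.shape == (1, 3)

    def test_descending_file_order_is_canonicalized(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("sample_id,1200.0,1100.0,1000.0\nA,3.0,2.0,1.0\n")
        spectra = read_spectra(path)
        assert np.array_equal(spectra.axis.values, [1000.0, 1100.0, 1200.0])
        assert np.array_equal(spectra.absorbance[0], [1.0, 2.0, 3.0])

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("sample_id,1000.0,1100.0\nA,0.1,oops\nB,0.2,0.3\n")
        with pytest.raises(ValueError, match="row 0.*1100.0"):
            read_spectra(path)

    def test_duplicate_id_in_file_rejected(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("sample_id,1000.0\nA,0.1\nA,0.2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_spectra(path)


class TestTraitTable:
    def test_round_trip(self, tmp_path):
        records = [
            SampleRecord("A", rct=17.0, k20=3.2, a30=40.0, fat=7.9, protein=4.6,
                         casein=3.7, lactose=4.6, scc=150.0),
            SampleRecord("B", coagulated=False, fat=8.1),
        ]
        path = tmp_path / "traits.csv"
        write_traits(records, path)
        back = read_traits(path)
        assert back[0].rct == pytest.approx(17.0)
        assert back[1].coagulated is False and back[1].rct is None

    def test_censored_record_rejects_trait_values(self):
        with pytest.raises(ValueError, match="censored"):
            SampleRecord("A", rct=31.0, coagulated=False)

    def test_nonpositive_rct_rejected(self):
        with pytest.raises(ValueError, match="RCT"):
            SampleRecord("A", rct=0.0)

    def test_frame_round_trip_preserves_missing(self):
        records = [SampleRecord("A", rct=12.0), SampleRecord("B", coagulated=False)]
        back = frame_to_records(records_to_frame(records))
        assert back[0].rct == 12.0 and back[0].k20 is None
        assert back[1].coagulated is False


class TestMaskRegions:
    def test_empty_region_list_is_identity(self, full_grid_spectra):
        out = mask_regions(full_grid_spectra, [])
        assert out.n_points == 1060
        assert np.array_equal(out.absorbance, full_grid_spectra.absorbance)

    def test_water_regions_removed(self, full_grid_spectra):
        out = mask_regions(full_grid_spectra, DEFAULT_WATER_REGIONS)
        w = out.axis.values
        for lo, hi in DEFAULT_WATER_REGIONS:
            assert not np.any((w >= lo) & (w <= hi))

    def test_retained_count_matches_brute_force(self, full_grid_spectra):
        out = mask_regions(full_grid_spectra, DEFAULT_WATER_REGIONS)
        # direct enumeration over the grid, closed intervals
        count = 0
        for w in full_grid_spectra.axis.values:
            inside = any(lo <= w <= hi for lo, hi in DEFAULT_WATER_REGIONS)
            count += not inside
        assert out.n_points == count

    def test_idempotent(self, full_grid_spectra):
        once = mask_regions(full_grid_spectra, DEFAULT_WATER_REGIONS)
        twice = mask_regions(once, DEFAULT_WATER_REGIONS)
        assert np.array_equal(once.absorbance, twice.absorbance)
        assert np.array_equal(once.axis.values, twice.axis.values)

    def test_removing_everything_raises(self, full_grid_spectra):
        with pytest.raises(ValueError, match="every wavenumber"):
            mask_regions(full_grid_spectra, [(900.0, 5000.0)])

    def test_invalid_interval_rejected(self, full_grid_spectra):
        with pytest.raises(ValueError, match="lo < hi"):
            mask_regions(full_grid_spectra, [(2000.0, 1500.0)])


class TestCensoringFilter:
    def test_partition_property(self):
        records = [SampleRecord(f"S{i}", rct=15.0 + i) for i in range(5)]
        records += [SampleRecord(f"N{i}", coagulated=False) for i in range(3)]
        retained, removed = filter_noncoagulating(records)
        assert {r.sample_id for r in retained} | {r.sample_id for r in removed} == \
            {r.sample_id for r in records}
        assert not ({r.sample_id for r in retained} & {r.sample_id for r in removed})
        assert len(retained) == 5 and len(removed) == 3

    def test_no_censored_is_identity(self):
        records = [SampleRecord(f"S{i}", rct=15.0) for i in range(4)]
        retained, removed = filter_noncoagulating(records)
        assert retained == records and removed == []

    def test_censored_count_near_configured_rate(self):
        # binomial mean ~58.7 at n=1736, p=0.0338; 99% bounds
        dataset = generate_dataset(default_config(), seed=3)
        _, removed = filter_noncoagulating(dataset.records)
        n, p = 1736, 0.0338
        half = 2.576 * np.sqrt(n * p * (1 - p))
        assert n * p - half <= len(removed) <= n * p + half

    def test_all_censored_leaves_nothing_to_model(self):
        records = [SampleRecord(f"S{i}", coagulated=False) for i in range(10)]
        retained, removed = filter_noncoagulating(records)
        assert retained == [] and len(removed) == 10
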