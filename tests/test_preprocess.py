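"""Record validation, chronic-LOEC conversion and the preprocessing chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hssd import (
    EffectRecord,
    ExtrapolationTable,
    RecordValidationError,
    aggregate_geometric_mean,
    convert_to_chronic_loec,
    encode_predictors,
    filter_and_recategorize,
    midpoint_size,
    read_records_csv,
    write_records_csv,
)
from hssd.records import ExtrapolationLookupError, ExtrapolationRule


def rec(**kw):
    base = dict(
        species_name="Daphnia magna",
        reference_id="ref_a",
        polymer="polystyrene",
        medium="freshwater",
        size_um=1.0,
        chronic_loec=10.0,
    )
    base.update(kw)
    return EffectRecord(**base)


class TestMidpointSize:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(1, 3, 2), (5, 5, 5), (0.04, 315.0, 157.52)],
    )
    def test_arithmetic_mean(self, lo, hi, expected):
        assert midpoint_size(lo, hi) == pytest.approx(expected)

    @pytest.mark.parametrize("lo,hi", [(0, 1), (-1, 2), (3, 1)])
    def test_invalid_bounds_rejected(self, lo, hi):
        with pytest.raises(RecordValidationError):
            midpoint_size(lo, hi)

    def test_range_autofills_point_size(self):
        r = rec(size_um=None, size_min_um=1.0, size_max_um=3.0)
        assert r.size_um == 2.0


class TestConversion:
    def test_chronic_loec_passes_through_with_factor_one(self):
        table = ExtrapolationTable.default()
        r = convert_to_chronic_loec(rec(chronic_loec=50.0), table)
        assert r.chronic_loec == 50.0
        assert r.conversion_factor == 1.0

    def test_division_by_configured_factor(self):
        table = ExtrapolationTable([ExtrapolationRule("LC50", 10.0)])
        r = convert_to_chronic_loec(
            rec(effect_type="LC50", reported_value=200.0, chronic_loec=None), table
        )
        assert r.chronic_loec == pytest.approx(20.0)
        assert r.conversion_factor == 10.0

    def test_maximum_factor_thirty(self):
        table = ExtrapolationTable([ExtrapolationRule("EC50", 30.0)])
        r = convert_to_chronic_loec(
            rec(effect_type="EC50", reported_value=30.0, chronic_loec=None), table
        )
        assert r.chronic_loec == pytest.approx(1.0)

    def test_unresolvable_lookup_names_the_inputs(self):
        table = ExtrapolationTable([ExtrapolationRule("LC50", 10.0, max_days=4)])
        with pytest.raises(ExtrapolationLookupError, match="LC50"):
            convert_to_chronic_loec(
                rec(effect_type="LC50", reported_value=5.0, chronic_loec=None,
                    exposure_duration_days=28.0),
                table,
            )

    def test_factor_outside_1_30_rejected(self):
        with pytest.raises(RecordValidationError):
            ExtrapolationRule("LC50", 31.0)
        with pytest.raises(RecordValidationError):
            ExtrapolationRule("LC50", 0.5)

    def test_table_json_round_trip(self, tmp_path):
        table = ExtrapolationTable.default()
        table.to_json(tmp_path / "t.json")
        back = ExtrapolationTable.from_json(tmp_path / "t.json")
        assert back.lookup("LC50", 2.0) == table.lookup("LC50", 2.0)


class TestFilterRecategorize:
    def test_only_spheres_retained(self):
        out = filter_and_recategorize(
            [rec(shape="sphere"), rec(shape="fiber"), rec(shape="irregular")]
        )
        assert [r.shape for r in out] == ["sphere"]

    def test_brackish_override_species_becomes_freshwater(self):
        out = filter_and_recategorize(
            [rec(species_name="Hyalella azteca", medium="brackish")],
            freshwater_overrides={"hyalella azteca"},
        )
        assert out[0].medium == "freshwater"

    def test_brackish_default_becomes_marine(self):
        out = filter_and_recategorize([rec(medium="brackish")])
        assert out[0].medium == "marine"
        assert all(r.medium != "brackish" for r in out)

    def test_values_never_altered(self):
        out = filter_and_recategorize([rec(medium="brackish", chronic_loec=3.5, size_um=2.2)])
        assert out[0].chronic_loec == 3.5 and out[0].size_um == 2.2

    def test_empty_output_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = filter_and_recategorize([rec(shape="fiber")])
        assert out == []


class TestAggregateGeometricMean:
    def test_replicates_collapse_to_geometric_mean(self):
        out = aggregate_geometric_mean([rec(chronic_loec=10.0), rec(chronic_loec=1000.0)])
        assert len(out) == 1
        assert out[0].chronic_loec == pytest.approx(100.0)

    def test_singleton_identity(self):
        out = aggregate_geometric_mean([rec(chronic_loec=4.0)])
        assert out[0].chronic_loec == 4.0

    def test_two_and_eight_give_four(self):
        out = aggregate_geometric_mean([rec(chronic_loec=2.0), rec(chronic_loec=8.0)])
        assert out[0].chronic_loec == pytest.approx(4.0)

    def test_different_conditions_not_merged(self):
        out = aggregate_geometric_mean(
            [rec(chronic_loec=2.0), rec(chronic_loec=8.0, medium="marine")]
        )
        assert len(out) == 2

    def test_cross_reference_duplicates_kept_separate(self):
        out = aggregate_geometric_mean(
            [rec(reference_id="ref_a"), rec(reference_id="ref_b")]
        )
        assert len(out) == 2

    @given(
        values=st.lists(st.floats(min_value=1e-3, max_value=1e6), min_size=1, max_size=6)
    )
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, values):
        records = [rec(chronic_loec=v) for v in values]
        once = aggregate_geometric_mean(records)
        twice = aggregate_geometric_mean(once)
        assert [r.chronic_loec for r in twice] == [r.chronic_loec for r in once]


class TestEncodePredictors:
    def test_log10_size(self):
        data = encode_predictors([rec(size_um=0.1)])
        assert data.x_size[0] == pytest.approx(-1.0)

    def test_medium_dummy_marine_is_one(self):
        data = encode_predictors([rec(medium="marine"), rec(medium="freshwater")])
        assert list(data.x_media) == [1.0, 0.0]

    def test_polymer_dummy_case_insensitive(self):
        data = encode_predictors(
            [rec(polymer="Polystyrene"), rec(polymer="polyethylene"),
             rec(polymer="PS-PEI")]
        )
        assert list(data.x_polymer) == [1.0, 0.0, 1.0]

    def test_brackish_rejected_at_encoding(self):
        with pytest.raises(RecordValidationError, match="brackish"):
            encode_predictors([rec(medium="brackish")])

    def test_missing_loec_rejected(self):
        with pytest.raises(RecordValidationError, match="chronic_loec"):
            encode_predictors([rec(chronic_loec=None)])

    def test_ref_index_by_first_appearance(self):
        data = encode_predictors(
            [rec(reference_id="b"), rec(reference_id="a"), rec(reference_id="b")]
        )
        assert list(data.ref_index) == [0, 1, 0]
        assert data.ref_ids == ("b", "a")
        assert data.n_refs == 2

    def test_response_is_log10_loec(self):
        data = encode_predictors([rec(chronic_loec=1000.0)])
        assert data.y[0] == pytest.approx(3.0)


def test_record_csv_round_trip_preserves_encoding(tmp_path):
    records = [
        rec(species_name="A", medium="marine", size_um=0.5, chronic_loec=3.0,
            reference_id="r1"),
        rec(species_name="B", polymer="polyethylene", size_um=20.0,
            chronic_loec=700.0, reference_id="r2"),
        rec(species_name="C", size_um=315.0, chronic_loec=0.04, reference_id="r1"),
    ]
    before = encode_predictors(records)
    path = tmp_path / "records.csv"
    write_records_csv(records, path)
    after = encode_predictors(read_records_csv(path))
    np.testing.assert_array_equal(before.y, after.y)
    np.testing.assert_array_equal(before.x_size, after.x_size)
    np.testing.assert_array_equal(before.x_media, after.x_media)
    np.testing.assert_array_equal(before.x_polymer, after.x_polymer)
    np.testing.assert_array_equal(before.ref_index, after.ref_index)


def test_prepared_dataset_csv_round_trip(tmp_path, paper_scale_data):
    data, _ = paper_scale_data
    path = tmp_path / "prepared.csv"
    data.to_csv(path)
    from hssd import PreparedDataset

    back = PreparedDataset.read_csv(path)
    np.testing.assert_allclose(back.y, data.y)
    np.testing.assert_array_equal(back.ref_index, data.ref_index)
    assert back.ref_ids == data.ref_ids
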