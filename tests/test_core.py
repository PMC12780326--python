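"""Record validation, dialect-driven CSV ingest and round-trip identity."""

import math

import pytest
from hypothesis import given, strategies as st

from wheatflux.core import (
    ConfigurationError,
    GasExchangeRecord,
    ParseError,
    PlantLedger,
    Treatment,
    ValidationError,
    read_gasx_table,
    records_to_frame,
    write_gasx_table,
)


def _write(tmp_path, text, name="t.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestValidation:
    def test_treatment_nominal_vpd_defaults_per_regime(self):
        assert Treatment(vpd_regime="ambient").canopy_vpd_kpa == 1.43
        assert Treatment(vpd_regime="heatwave").canopy_vpd_kpa == 3.14

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"co2_ppm": -1},
            {"vpd_regime": "tropical"},
            {"n_level": "N9"},
            {"watering": "misted"},
        ],
    )
    def test_treatment_rejects_bad_levels(self, kwargs):
        with pytest.raises(ValidationError):
            Treatment(**kwargs)

    def test_negative_single_surface_gsw_is_flagged_not_dropped(self):
        rec = GasExchangeRecord(plant_id="p", surface="abaxial", gsw=-0.01, E=0.1)
        assert rec.flagged

    def test_negative_combined_E_rejected(self):
        with pytest.raises(ValidationError):
            GasExchangeRecord(plant_id="p", surface="combined", gsw=0.2, E=-1.0)

    def test_ci_must_stay_below_ca_when_assimilating(self):
        with pytest.raises(ValidationError):
            GasExchangeRecord(
                plant_id="p", surface="combined", gsw=0.2, E=1.0,
                A=10.0, Ca=450.0, Ci=460.0,
            )

    def test_ledger_rejects_negative_masses(self):
        with pytest.raises(ValidationError):
            PlantLedger(plant_id="p", water_applied_l=5.0, ear_weight_g=-1.0)


class TestReader:
    def test_three_row_fixture_maps_surfaces(self, tmp_path):
        path = _write(
            tmp_path,
            "plant_id,surface,gsw,E\np1,abaxial,0.05,0.6\n"
            "p1,adaxial,0.30,3.4\np2,combined,0.35,4.0\n",
        )
        recs = read_gasx_table(path)
        assert [r.surface for r in recs] == ["abaxial", "adaxial", "combined"]

    def test_vendor_dialect_renames_and_converts_units(self, tmp_path):
        # LI-600-style export: E in mol m-2 s-1, surface coded ab/ad
        path = _write(
            tmp_path,
            "plant,side,gsw_mol,E_mol\np1,ab,0.05,0.0006\np1,ad,0.30,0.0034\n",
        )
        dialect = {
            "columns": {"plant_id": "plant", "surface": "side",
                        "gsw": "gsw_mol", "E": "E_mol"},
            "units": {"E": 1000.0},
        }
        recs = read_gasx_table(path, dialect)
        assert recs[0].E == pytest.approx(0.6)
        assert recs[1].surface == "adaxial"

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = _write(tmp_path, "plant_id,surface,gsw\np1,abaxial,0.05\n")
        with pytest.raises(ConfigurationError, match="'E'"):
            read_gasx_table(path)

    def test_non_numeric_cell_reports_row_and_column(self, tmp_path):
        path = _write(
            tmp_path, "plant_id,surface,gsw,E\np1,abaxial,abc,0.6\n"
        )
        with pytest.raises(ParseError, match="row 0"):
            read_gasx_table(path)

    def test_out_of_range_rh_lists_offending_row(self, tmp_path):
        path = _write(
            tmp_path,
            "plant_id,surface,gsw,E,RH\np1,abaxial,0.05,0.6,55\n"
            "p2,abaxial,0.05,0.6,112\n",
        )
        with pytest.raises(ValidationError) as err:
            read_gasx_table(path)
        assert err.value.rows == [1]

    def test_unmappable_surface_labels_rejected_with_rows(self, tmp_path):
        path = _write(
            tmp_path,
            "plant_id,surface,gsw,E\np1,abaxial,0.05,0.6\np2,sideways,0.1,1\n",
        )
        with pytest.raises(ValidationError) as err:
            read_gasx_table(path)
        assert err.value.rows == [1]


class TestRoundTrip:
    def test_empty_collection_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_gasx_table([], path)
        assert path.read_text().strip().count("\n") == 0
        assert read_gasx_table(path) == []

    def test_absent_fields_round_trip_as_absent(self, tmp_path):
        rec = GasExchangeRecord(plant_id="p", surface="abaxial", gsw=0.05, E=0.6)
        path = tmp_path / "na.csv"
        write_gasx_table([rec], path)
        back = read_gasx_table(path)[0]
        assert back.A is None and back.Ci is None
        assert back == rec

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["abaxial", "adaxial", "combined"]),
                st.floats(0.001, 1.0),
                st.floats(0.0, 12.0),
                st.floats(0.1, 5.0),
                st.booleans(),
            ),
            min_size=1,
            max_size=10,
        )
    )
    def test_round_trip_identity_on_arbitrary_valid_records(
        self, tmp_path_factory, rows
    ):
        recs = [
            GasExchangeRecord(
                plant_id=f"p{i}", surface=surf, gsw=gsw, E=e, D=d,
                A=12.0 if with_a else None,
                Ca=450.0 if with_a else None,
                Ci=300.0 if with_a else None,
                treatment=Treatment(co2_ppm=720.0, vpd_regime="heatwave",
                                    n_level="N3"),
            )
            for i, (surf, gsw, e, d, with_a) in enumerate(rows)
        ]
        path = tmp_path_factory.mktemp("rt") / "rt.csv"
        write_gasx_table(recs, path)
        assert read_gasx_table(path) == recs

    def test_generator_output_count_matches_configured_n(
        self, tmp_path, default_generator, steady_records
    ):
        cfg = default_generator.config
        expected = (
            len(cfg.co2_levels) * len(cfg.vpd_regimes) * len(cfg.n_levels)
            * cfg.n_plants_per_n * 2  # two surfaces per plant
        )
        assert len(steady_records) == expected
        path = tmp_path / "gen.csv"
        write_gasx_table(steady_records, path)
        assert len(read_gasx_table(path)) == expected

    def test_unit_canonicalisation_is_idempotent(self, tmp_path):
        rec = GasExchangeRecord(plant_id="p", surface="combined", gsw=0.3, E=4.0)
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        write_gasx_table([rec], p1)
        write_gasx_table(read_gasx_table(p1), p2)
        assert p1.read_text() == p2.read_text()
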