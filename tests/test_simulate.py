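"""Generator contracts: determinism, factorial structure, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from wheatflux.core import records_to_frame
from wheatflux.kinetics import summarise_kinetics
from wheatflux.optimality import fit_optimality
from wheatflux.simulate import ScenarioConfig, ScenarioGenerator


class TestDeterminism:
    def test_same_seed_same_output(self):
        a = ScenarioGenerator(ScenarioConfig(seed=9)).generate_steady_state()
        b = ScenarioGenerator(ScenarioConfig(seed=9)).generate_steady_state()
        assert a == b

    def test_different_seed_differs(self):
        a = ScenarioGenerator(ScenarioConfig(seed=9)).generate_steady_state()
        b = ScenarioGenerator(ScenarioConfig(seed=10)).generate_steady_state()
        assert a != b

    def test_stage_rngs_are_independent(self, default_generator):
        before = default_generator.generate_aci()
        default_generator.generate_kinetics()  # interleave another stage
        after = default_generator.generate_aci()
        pd.testing.assert_frame_equal(before[0].points, after[0].points)


class TestFactorialStructure:
    def test_cell_counts_match_design(self, steady_records):
        df = records_to_frame(steady_records)
        cells = df.groupby(["co2_ppm", "vpd_regime", "n_level"])[
            "plant_id"
        ].nunique()
        assert len(cells) == 16
        assert (cells == 32).all()

    def test_every_record_passes_validation(self, steady_records):
        for rec in steady_records:
            rec.validate()  # raises on violation

    def test_drought_split_is_16_16(self, default_generator):
        _, _, ledgers = default_generator.generate_drought_series()
        df = pd.DataFrame(
            {
                "cell": [f"{l.treatment.co2_ppm}-{l.treatment.vpd_regime}-"
                         f"{l.treatment.n_level}" for l in ledgers],
                "watering": [l.treatment.watering for l in ledgers],
            }
        )
        counts = df.groupby(["cell", "watering"]).size().unstack()
        assert (counts["drought"] == 16).all()
        assert (counts["watered"] == 16).all()


class TestSteadyStateRecovery:
    def test_noise_free_output_recovers_configured_k_and_g1(
        self, noise_free_generator
    ):
        cfg = noise_free_generator.config
        df = records_to_frame(noise_free_generator.generate_steady_state())
        combined = (
            df.groupby(["plant_id", "co2_ppm", "vpd_regime"])
            .agg(gsw=("gsw", "sum"), E=("E", "sum"), A=("A", "first"),
                 Ca=("Ca", "first"), Ci=("Ci", "first"), D=("D", "first"))
            .reset_index()
        )
        sub = combined[(combined.co2_ppm == 450.0)
                       & (combined.vpd_regime == "ambient")]
        fits, best_k = fit_optimality(sub)
        assert best_k == cfg.k_exponent
        assert fits[best_k].g1 == pytest.approx(
            cfg.g1_by_regime["ambient"], abs=1e-9
        )
        assert fits[best_k].rmse == pytest.approx(0.0, abs=1e-12)

    def test_abaxial_share_recovers_within_two_se(self, steady_records):
        cfg = ScenarioConfig()
        df = records_to_frame(steady_records)
        total = df.groupby(["plant_id", "vpd_regime"])["E"].sum()
        ab = df[df.surface == "abaxial"].set_index(["plant_id", "vpd_regime"])["E"]
        share = (ab / total).reset_index(name="share")
        for regime, target in cfg.abaxial_share.items():
            s = share[share.vpd_regime == regime]["share"]
            se = s.std() / np.sqrt(len(s))
            assert abs(s.mean() - target) < 2 * se


class TestKineticsRecovery:
    def test_closure_fraction_recovered_within_two_se(self, default_generator):
        cfg = default_generator.config
        rows = {}
        for t in default_generator.generate_kinetics():
            s = summarise_kinetics(t)
            rows.setdefault(t.treatment.vpd_regime, []).append(s.pct_closure)
        for regime, vals in rows.items():
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            target = 100.0 * cfg.closure_fraction[regime]
            assert abs(vals.mean() - target) < max(2 * se, 1.0)

    def test_ambient_closes_more_than_heatwave_every_replicate(
        self, default_generator
    ):
        closures = {}
        for t in default_generator.generate_kinetics():
            s = summarise_kinetics(t)
            closures.setdefault(t.treatment.vpd_regime, []).append(s.pct_closure)
        assert min(closures["ambient"]) > max(closures["heatwave"])

    def test_steady_phase_is_flat(self, default_generator):
        t = default_generator.generate_kinetics()[0]
        steady = t.samples[t.samples.t_min <= 5.0]
        slope = np.polyfit(steady.t_min, steady.gsw, 1)[0]
        assert slope == pytest.approx(0.0, abs=5e-3)


@pytest.fixture(scope="module")
def drought(default_generator):
    return default_generator.generate_drought_series()


class TestDroughtSeries:

    def test_droughted_plants_decline_by_day_12(self, drought):
        records, _, _ = drought
        df = records_to_frame(records)
        df["day"] = df["time_min"] / 1440.0
        wide = df.pivot_table(index="plant_id", columns="day", values="E")
        droughted = df[df.watering == "drought"]["plant_id"].unique()
        sub = wide.loc[droughted]
        assert (sub[12.0] < sub[0.0]).all()

    def test_ledger_freeze_for_droughted(self, drought):
        _, _, ledgers = drought
        by_cell = {}
        for l in ledgers:
            key = (l.treatment.co2_ppm, l.treatment.vpd_regime,
                   l.treatment.n_level)
            by_cell.setdefault(key, {}).setdefault(
                l.treatment.watering, []
            ).append(l.water_applied_l)
        cfg = ScenarioConfig()
        for key, groups in by_cell.items():
            watered = np.mean(groups["watered"])
            frozen = np.mean(groups["drought"])
            assert frozen == pytest.approx(
                cfg.drought_onset_frac * watered, rel=1e-9
            )

    def test_wue_ledgers_recover_configured_ml_per_g(self, drought):
        from wheatflux.phenotypes import wue_ledger

        _, _, ledgers = drought
        cfg = ScenarioConfig()
        vals = {}
        for l in ledgers:
            if l.treatment.watering != "watered":
                continue
            key = (l.treatment.co2_ppm, l.treatment.vpd_regime)
            vals.setdefault(key, []).append(wue_ledger(l)["ml_per_g"])
        for key, target in cfg.ml_per_g.items():
            got = np.median(vals[key])
            assert got == pytest.approx(target, rel=0.10)

    def test_droughted_mtci_declines(self, drought):
        _, mtci_df, _ = drought
        wide = mtci_df[mtci_df.watering == "drought"].pivot_table(
            index="plant_id", columns="day", values="mtci"
        )
        assert (wide[12] < wide[0]).all()
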