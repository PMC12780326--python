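"""End-to-end orchestration: simulate -> ingest -> analyse -> summarise.

``run_pipeline`` executes the stages in a fixed order on one output
directory, writing per-stage CSV/JSON artefacts plus a run manifest that
records the seed, a hash of the configuration and a content hash of every
output file.  Deterministic stages are pure functions of their inputs, so
two runs with the same config produce identical manifest hashes.

Group comparisons are reduced to descriptive mean +- s.e. tables;
inferential testing (ANOVA/GLM machinery) is delegated to standard
statistics tooling outside this package.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, farquhar, kinetics as kin, optimality, phenotypes, surfaces
from .core import GasExchangeRecord, Treatment
from .simulate import ScenarioConfig, ScenarioGenerator

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

ALL_STAGES = ("simulate", "optimality", "aci", "partition", "kinetics", "ledger",
              "summary")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str | Path = "wheatflux_run"
    seed: int = 0
    stages: tuple = ALL_STAGES
    scenario: ScenarioConfig | None = None

    def scenario_config(self) -> ScenarioConfig:
        if self.scenario is not None:
            cfg = self.scenario
            cfg.seed = self.seed
            return cfg
        return ScenarioConfig(seed=self.seed)


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: ScenarioConfig) -> str:
    # repr-based: config dicts carry tuple keys that JSON cannot encode
    payload = repr(sorted(dataclasses.asdict(cfg).items())).encode()
    return hashlib.sha256(payload).hexdigest()


def _group_stats(df: pd.DataFrame, by: list[str], value: str) -> pd.DataFrame:
    g = df.groupby(by, sort=True)[value]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["se"] = out["std"] / np.sqrt(out["count"])
    return out


def _curves_to_frame(curves) -> pd.DataFrame:
    rows = []
    for c in curves:
        p = c.points.copy()
        p.insert(0, "plant_id", c.plant_id)
        p["t_leaf"] = c.t_leaf
        p["co2_ppm"] = c.treatment.co2_ppm
        p["vpd_regime"] = c.treatment.vpd_regime
        p["n_level"] = c.treatment.n_level
        rows.append(p)
    return pd.concat(rows, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages in DAG order; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scen = config.scenario_config()
    gen = ScenarioGenerator(scen)
    outputs: dict[str, list[str]] = {}
    state: dict = {}

    def emit(stage: str, name: str, obj) -> Path:
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        else:
            path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                                       default=str))
        outputs.setdefault(stage, []).append(name)
        return path

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            if stage == "simulate":
                steady = gen.generate_steady_state()
                core.write_gasx_table(steady, outdir / "steady_state.csv")
                outputs.setdefault(stage, []).append("steady_state.csv")
                curves = gen.generate_aci()
                emit(stage, "aci_curves.csv", _curves_to_frame(curves))
                traces = gen.generate_kinetics()
                trows = []
                for t in traces:
                    s = t.samples.copy()
                    s.insert(0, "plant_id", t.plant_id)
                    s["co2_ppm"] = t.treatment.co2_ppm
                    s["vpd_regime"] = t.treatment.vpd_regime
                    trows.append(s)
                emit(stage, "kinetics_traces.csv", pd.concat(trows,
                                                             ignore_index=True))
                drought, mtci_df, ledgers = gen.generate_drought_series()
                core.write_gasx_table(drought, outdir / "drought_series.csv")
                outputs.setdefault(stage, []).append("drought_series.csv")
                emit(stage, "mtci_series.csv", mtci_df)
                emit(stage, "ledgers.csv", core.ledgers_to_frame(ledgers))
                state.update(steady=steady, curves=curves, traces=traces,
                             ledgers=ledgers)

            elif stage == "optimality":
                df = core.records_to_frame(state["steady"])
                # whole-leaf values: sum the two surfaces of each plant
                combined = (
                    df.groupby(["plant_id", "co2_ppm", "vpd_regime", "n_level"],
                               sort=True)
                    .agg(gsw=("gsw", "sum"), E=("E", "sum"), A=("A", "first"),
                         Ca=("Ca", "first"), Ci=("Ci", "first"), D=("D", "first"))
                    .reset_index()
                )
                report = {}
                for (co2, regime), sub in combined.groupby(
                    ["co2_ppm", "vpd_regime"], sort=True
                ):
                    fits, best_k = optimality.fit_optimality(sub)
                    report[f"{int(co2)}ppm_{regime}"] = {
                        "best_k": best_k,
                        "fits": {str(k): f.to_dict() for k, f in fits.items()},
                    }
                emit(stage, "optimality_fits.json", report)
                state["optimality"] = report

            elif stage == "aci":
                rows = []
                for c in state["curves"]:
                    params = farquhar.fit_aci(c)
                    rows.append({
                        "plant_id": c.plant_id, "t_leaf": c.t_leaf,
                        "co2_ppm": c.treatment.co2_ppm,
                        "vpd_regime": c.treatment.vpd_regime,
                        "vcmax": params.vcmax, "jmax": params.jmax,
                        "rd": params.rd,
                        "rmse": params.fit["rmse"],
                    })
                emit(stage, "fvcb_params.csv", pd.DataFrame(rows))

            elif stage == "partition":
                by_plant: dict[str, dict] = {}
                for rec in state["steady"]:
                    by_plant.setdefault(rec.plant_id, {})[rec.surface] = rec
                rows = []
                for pid, pair in by_plant.items():
                    if {"abaxial", "adaxial"} - set(pair):
                        continue
                    sp = surfaces.SurfacePair(ab=pair["abaxial"],
                                              ad=pair["adaxial"])
                    frac_e = surfaces.abaxial_fraction(sp, "E")
                    frac_g = surfaces.abaxial_fraction(sp, "gsw")
                    flagged = sp.ab.flagged or sp.ad.flagged
                    rows.append({
                        "plant_id": pid,
                        "co2_ppm": sp.ab.treatment.co2_ppm,
                        "vpd_regime": sp.ab.treatment.vpd_regime,
                        "n_level": sp.ab.treatment.n_level,
                        "abaxial_pct_E": frac_e,
                        "abaxial_pct_gsw": frac_g,
                        "asin_sqrt_E": (
                            surfaces.arcsine_sqrt(frac_e / 100.0)
                            if frac_e is not None and not flagged else None
                        ),
                        "flagged": flagged,
                    })
                part = pd.DataFrame(rows)
                emit(stage, "surface_partition.csv", part)
                emit(stage, "abaxial_share_means.csv",
                     _group_stats(part.dropna(subset=["abaxial_pct_E"]),
                                  ["co2_ppm", "vpd_regime"], "abaxial_pct_E"))
                state["partition"] = part

            elif stage == "kinetics":
                rows = []
                for t in state["traces"]:
                    s = kin.summarise_kinetics(t)
                    rows.append({
                        "plant_id": t.plant_id,
                        "co2_ppm": t.treatment.co2_ppm,
                        "vpd_regime": t.treatment.vpd_regime,
                        "g0": s.g0, "rate_close": s.rate_close,
                        "rate_open": s.rate_open,
                        "g_dark_end": s.g_dark_end,
                        "g_light_end": s.g_light_end,
                        "pct_closure": s.pct_closure,
                    })
                emit(stage, "kinetics_summaries.csv", pd.DataFrame(rows))
                brows = []
                for c in state["curves"]:
                    b = kin.co2_blindness_slope(c)
                    brows.append({
                        "plant_id": c.plant_id,
                        "co2_ppm": c.treatment.co2_ppm,
                        "vpd_regime": c.treatment.vpd_regime,
                        "slope": b["slope"], "label": b["label"],
                    })
                emit(stage, "co2_blindness.csv", pd.DataFrame(brows))

            elif stage == "ledger":
                rows = []
                for led in state["ledgers"]:
                    w = phenotypes.wue_ledger(led)
                    rows.append({
                        "plant_id": led.plant_id,
                        "co2_ppm": led.treatment.co2_ppm,
                        "vpd_regime": led.treatment.vpd_regime,
                        "n_level": led.treatment.n_level,
                        "watering": led.treatment.watering,
                        "water_applied_l": led.water_applied_l,
                        "ear_weight_g": led.ear_weight_g,
                        "wue_g_per_l": w["wue_g_per_l"],
                        "ml_per_g": w["ml_per_g"],
                    })
                wue = pd.DataFrame(rows)
                emit(stage, "wue_ledgers.csv", wue)
                watered = wue[wue["watering"] == "watered"]
                means = _group_stats(watered, ["co2_ppm", "vpd_regime"],
                                     "water_applied_l")
                emit(stage, "water_use_means.csv", means)
                state["wue"] = wue

            elif stage == "summary":
                df = core.records_to_frame(state["steady"])
                combined_e = (
                    df.groupby(["plant_id", "co2_ppm", "vpd_regime", "n_level"])
                    ["E"].sum().reset_index()
                )
                summary = {
                    "E_group_means": _group_stats(
                        combined_e, ["co2_ppm", "vpd_regime", "n_level"], "E"
                    ).to_dict(orient="records"),
                }
                if "optimality" in state:
                    summary["optimality"] = state["optimality"]
                emit(stage, "summary.json", summary)

        except Exception as exc:  # halt; keep partial outputs on disk
            raise PipelineStageError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "config_hash": _config_hash(scen),
        "outputs": {
            stage: {name: _sha256(outdir / name) for name in names}
            for stage, names in outputs.items()
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
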