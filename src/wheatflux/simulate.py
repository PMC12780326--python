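"""Seeded synthetic-data generator for the factorial growth experiment.

Emulates the study design end-to-end so every analysis stage is testable
without instrument data: 2 growth CO2 levels (450 / 720 ppm) x 2 canopy
VPD regimes (ambient 27 degC / 60% RH, heatwave 37 degC / 50% RH) x 4
nitrogen levels with 32 plants per N treatment, per-surface porometer
readings, A/Ci curves along the two printed CO2-reference sequences,
light-shift kinetics traces, a 12-day drought time-course sampled every
3 days, red-edge reflectance spectra and seasonal water/harvest ledgers.

The generator is the study's forward model: steady-state conductance obeys
the stomatal-optimality model with regime-dependent (k, g1); assimilation
comes from the FvCB model with N-dependent Vcmax; the heatwave regime
holds gsw flat across supra-ambient CO2 steps ("CO2 blindness") and closes
stomata in darkness only by a configured fraction.  Tests built on it
recover *generator parameters* — a self-consistency exercise, not a
reproduction of field measurements.

All randomness flows from one integer seed through ``numpy.random
.default_rng``; a fixed seed gives identical output across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    GasExchangeRecord,
    PlantLedger,
    Treatment,
)
from .farquhar import (
    ACiCurve,
    CO2_REF_SEQUENCE_450,
    CO2_REF_SEQUENCE_720,
    FvCBParams,
    fvcb_assimilation,
    temperature_adjust,
)
from .kinetics import KineticsTrace, PHASE_PLAN
from .optimality import air_vpd, predict_gs
from .phenotypes import SpectralRecord

__all__ = ["ScenarioConfig", "ScenarioGenerator"]

ATM_PRESSURE_KPA = 101.325


@dataclass
class ScenarioConfig:
    """Study conditions and named effect sizes of the generator.

    Defaults encode the factorial design and the qualitative response
    pattern of the study: higher g1 (more water spent per carbon) under
    heatwave VPD, a CO2-induced g1 reduction under ambient VPD only, an
    abaxial flux share of ~9% (ambient) vs ~45% (heatwave), dark closure
    of ~80% (ambient) vs 37.5% (heatwave), and faster drought decay under
    heatwave demand.
    """

    seed: int = 0
    n_plants_per_n: int = 32
    co2_levels: tuple = (450.0, 720.0)
    n_levels: tuple = ("N1", "N2", "N3", "N4")
    #: regime -> (air temperature degC, RH %)
    vpd_regimes: dict = field(
        default_factory=lambda: {"ambient": (27.0, 60.0), "heatwave": (37.0, 50.0)}
    )

    # --- stomatal optimality ---
    k_exponent: float = 0.8
    g1_by_regime: dict = field(
        default_factory=lambda: {"ambient": 2.5, "heatwave": 5.0}
    )
    #: multiplier on g1 for elevated-CO2 plants, per regime (the ambient-VPD
    #: reduction is the classic high-CO2 water saving; it vanishes under
    #: heatwave where stomatal CO2 responses are attenuated)
    g1_co2_factor: dict = field(
        default_factory=lambda: {"ambient": 0.7, "heatwave": 1.0}
    )
    d_jitter: float = 0.15  # uniform +-15% leaf-to-leaf spread of D

    # --- photosynthesis (25 degC basis, Arrhenius-scaled to the regime) ---
    vcmax25_by_n: dict = field(
        default_factory=lambda: {"N1": 60.0, "N2": 75.0, "N3": 85.0, "N4": 95.0}
    )
    jmax_vcmax_ratio: float = 1.8
    rd25: float = 1.0

    # --- surface partitioning ---
    abaxial_share: dict = field(
        default_factory=lambda: {"ambient": 0.09, "heatwave": 0.45}
    )
    abaxial_share_sd: float = 0.03
    gsw_surface_noise_sd: float = 0.002  # absolute, can flag tiny negatives

    # --- kinetics ---
    closure_fraction: dict = field(
        default_factory=lambda: {"ambient": 0.80, "heatwave": 0.375}
    )
    tau_close_min: float = 15.0
    tau_open_min: float = 20.0
    n_kinetics_plants: int = 4

    # --- noise (Gaussian; set to 0 for exact forward-model output) ---
    noise_sd_gsw_rel: float = 0.05  # relative, steady-state gsw
    noise_sd_aci_a: float = 0.5    # umol m-2 s-1 on A/Ci assimilation
    noise_sd_aci_gsw: float = 0.005
    noise_sd_kinetics_gsw: float = 0.002
    n_aci_plants: int = 4

    # --- drought / season ---
    drought_days: tuple = (0, 3, 6, 9, 12)
    drought_half_life_d: dict = field(
        default_factory=lambda: {"ambient": 6.0, "heatwave": 3.0}
    )
    drought_fraction: float = 0.5  # 16 of 32 plants per N treatment
    season_days: int = 148
    drought_onset_frac: float = 0.8  # fraction of season water already applied
    #: per-plant season water totals (litres) by (co2, regime); the printed
    #: whole-season means motivate the nonheatwave pair
    water_total_l: dict = field(
        default_factory=lambda: {
            (450.0, "ambient"): 12.6,
            (720.0, "ambient"): 6.09,
            (450.0, "heatwave"): 13.5,
            (720.0, "heatwave"): 12.8,
        }
    )
    #: target whole-cycle ml water per g ear by (co2, regime)
    ml_per_g: dict = field(
        default_factory=lambda: {
            (450.0, "ambient"): 501.0,
            (720.0, "ambient"): 286.0,
            (450.0, "heatwave"): 867.0,
            (720.0, "heatwave"): 676.0,
        }
    )
    n_water_multiplier: dict = field(
        default_factory=lambda: {"N1": 0.85, "N2": 0.95, "N3": 1.0, "N4": 1.05}
    )
    ledger_noise_rel: float = 0.08

    # --- spectra / chlorophyll ---
    chl_by_n: dict = field(
        default_factory=lambda: {"N1": 6.0, "N2": 10.0, "N3": 13.0, "N4": 15.0}
    )
    chl_noise_rel: float = 0.10
    mtci_per_chl: float = 0.35
    spectral_step_nm: float = 5.0

    def scenarios(self):
        for co2 in self.co2_levels:
            for regime in self.vpd_regimes:
                yield co2, regime

    def canopy_vpd(self, regime: str) -> float:
        t, rh = self.vpd_regimes[regime]
        return air_vpd(t, rh)


class ScenarioGenerator:
    """Deterministic generator over one :class:`ScenarioConfig`.

    Each ``generate_*`` method derives an independent child RNG from the
    config seed, so the outputs of one stage do not shift when another
    stage is re-run or re-ordered.
    """

    def __init__(self, config: ScenarioConfig | None = None, seed: int | None = None):
        self.config = config or ScenarioConfig()
        if seed is not None:
            self.config.seed = seed

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.config.seed) % (2**31), stream])

    # -- forward model pieces ---------------------------------------------
    def _fvcb_params(self, n_level: str, regime: str) -> FvCBParams:
        cfg = self.config
        t_leaf = cfg.vpd_regimes[regime][0]
        base = FvCBParams(
            vcmax=cfg.vcmax25_by_n[n_level],
            jmax=cfg.jmax_vcmax_ratio * cfg.vcmax25_by_n[n_level],
            rd=cfg.rd25,
        )
        return temperature_adjust(base, t_leaf)

    def _g1(self, co2: float, regime: str) -> float:
        factor = self.config.g1_co2_factor[regime] if co2 > 500 else 1.0
        return self.config.g1_by_regime[regime] * factor

    # -- steady state ------------------------------------------------------
    def generate_steady_state(self) -> list[GasExchangeRecord]:
        """Per-surface porometer-style records at saturating light.

        gsw obeys the optimality model at the regime's (k, g1); A comes
        from FvCB at the consistent Ci; E = gsw * D / P * 1000.  The
        whole-leaf fluxes are split into abaxial/adaxial surface pairs by
        the regime's abaxial share.
        """
        cfg = self.config
        rng = self._rng(1)
        records: list[GasExchangeRecord] = []
        for co2, regime in cfg.scenarios():
            t_air, rh = cfg.vpd_regimes[regime]
            d_nominal = cfg.canopy_vpd(regime)
            g1 = self._g1(co2, regime)
            k = cfg.k_exponent
            for n_level in cfg.n_levels:
                params = self._fvcb_params(n_level, regime)
                for i in range(cfg.n_plants_per_n):
                    plant = f"{int(co2)}-{regime}-{n_level}-P{i:02d}"
                    treatment = Treatment(co2_ppm=co2, vpd_regime=regime,
                                          n_level=n_level)
                    d = d_nominal * rng.uniform(1 - cfg.d_jitter, 1 + cfg.d_jitter)
                    r = g1 / (g1 + d**k)  # Ci/Ca from the optimality closure
                    ci = r * co2
                    a = fvcb_assimilation(ci, params)
                    gsw = predict_gs(a, co2, d, g1, k)
                    if cfg.noise_sd_gsw_rel > 0:
                        gsw *= 1.0 + cfg.noise_sd_gsw_rel * rng.standard_normal()
                    e = gsw * d / ATM_PRESSURE_KPA * 1000.0
                    share = float(np.clip(
                        rng.normal(cfg.abaxial_share[regime], cfg.abaxial_share_sd),
                        0.01, 0.95,
                    ))
                    gsw_ab = share * gsw + rng.normal(0, cfg.gsw_surface_noise_sd)
                    common = dict(
                        treatment=treatment, A=a, Ca=co2, Ci=ci, D=d,
                        T_leaf=t_air - 0.5, T_air=t_air, RH=rh,
                    )
                    records.append(GasExchangeRecord(
                        plant_id=plant, surface="abaxial",
                        gsw=gsw_ab, E=share * e, **common,
                    ))
                    records.append(GasExchangeRecord(
                        plant_id=plant, surface="adaxial",
                        gsw=gsw - gsw_ab, E=(1 - share) * e, **common,
                    ))
        return records

    # -- A/Ci curves -------------------------------------------------------
    def generate_aci(self) -> list[ACiCurve]:
        """CO2-response curves along the printed reference sequences.

        Ambient-VPD curves let gsw track the optimality model point by
        point (stomata close as reference CO2 rises); heatwave curves hold
        gsw flat at its growth-Ca value (the blindness mode).
        """
        cfg = self.config
        rng = self._rng(2)
        curves: list[ACiCurve] = []
        for co2, regime in cfg.scenarios():
            sequence = CO2_REF_SEQUENCE_450 if co2 == 450 else CO2_REF_SEQUENCE_720
            t_leaf = cfg.vpd_regimes[regime][0]
            d = cfg.canopy_vpd(regime)
            g1 = self._g1(co2, regime)
            k = cfg.k_exponent
            params = self._fvcb_params("N4", regime)
            r = g1 / (g1 + d**k)
            for i in range(cfg.n_aci_plants):
                rows = []
                gsw_growth = None
                for ca_ref in sequence:
                    ci = r * ca_ref
                    a = fvcb_assimilation(ci, params)
                    a += rng.normal(0, cfg.noise_sd_aci_a)
                    if a > 0:
                        gsw = predict_gs(max(a, 1e-6), ca_ref, d, g1, k)
                    else:
                        gsw = 0.05
                    if gsw_growth is None and ca_ref == co2:
                        gsw_growth = gsw
                    if regime == "heatwave":
                        gsw = gsw_growth if gsw_growth is not None else gsw
                    gsw += rng.normal(0, cfg.noise_sd_aci_gsw)
                    e = max(gsw, 0.0) * d / ATM_PRESSURE_KPA * 1000.0
                    rows.append({"ca_ref": float(ca_ref), "a": a, "ci": ci,
                                 "gsw": gsw, "e": e})
                curves.append(ACiCurve(
                    plant_id=f"{int(co2)}-{regime}-N4-ACI{i}",
                    points=pd.DataFrame(rows), t_leaf=t_leaf,
                    treatment=Treatment(co2_ppm=co2, vpd_regime=regime,
                                        n_level="N4"),
                ))
        return curves

    # -- kinetics ----------------------------------------------------------
    def generate_kinetics(self) -> list[KineticsTrace]:
        """Light-shift traces (steady 5 min, dark 60 min, relight 60 min).

        Exponential closure toward a regime-dependent asymptote chosen so
        the fractional closure at the end of the dark hour equals the
        configured closure fraction; exponential reopening toward the
        initial conductance.
        """
        cfg = self.config
        rng = self._rng(3)
        traces: list[KineticsTrace] = []
        t_grid = np.arange(0.0, 125.0 + 0.5, 1.0)
        (_, s1, _), (_, d0, d1), (_, r0, r1) = (
            (p[0], p[1], p[2]) for p in PHASE_PLAN
        )
        dark_len = d1 - d0
        for co2, regime in cfg.scenarios():
            d_kpa = cfg.canopy_vpd(regime)
            g1 = self._g1(co2, regime)
            k = cfg.k_exponent
            params = self._fvcb_params("N4", regime)
            r = g1 / (g1 + d_kpa**k)
            a0 = fvcb_assimilation(r * co2, params)
            g0 = predict_gs(a0, co2, d_kpa, g1, k)
            frac = cfg.closure_fraction[regime]
            # asymptote such that closure at t = dark end equals frac
            amp = frac * g0 / (1.0 - np.exp(-dark_len / cfg.tau_close_min))
            g_inf = g0 - amp
            for i in range(cfg.n_kinetics_plants):
                gsw = np.empty_like(t_grid)
                for j, t in enumerate(t_grid):
                    if t <= d0:
                        g = g0
                    elif t <= d1:
                        g = g_inf + amp * np.exp(-(t - d0) / cfg.tau_close_min)
                    else:
                        g_dark = g_inf + amp * np.exp(-dark_len / cfg.tau_close_min)
                        g = g0 - (g0 - g_dark) * np.exp(-(t - r0) / cfg.tau_open_min)
                    gsw[j] = g
                gsw = gsw + rng.normal(0, cfg.noise_sd_kinetics_gsw, gsw.shape)
                a_trace = np.where(t_grid <= d0, a0,
                                   np.where(t_grid <= d1, 0.5, a0 * 0.9))
                traces.append(KineticsTrace(
                    plant_id=f"{int(co2)}-{regime}-N4-K{i}",
                    samples=pd.DataFrame(
                        {"t_min": t_grid, "gsw": gsw, "a": a_trace}
                    ),
                    treatment=Treatment(co2_ppm=co2, vpd_regime=regime,
                                        n_level="N4"),
                ))
        return traces

    # -- drought time-course, spectra and ledgers --------------------------
    def generate_drought_series(self):
        """12-day drought: combined-leaf E records every 3 days, an MTCI
        series, and seasonal water/harvest ledgers.

        Droughted plants' E and MTCI decay exponentially with a
        regime-dependent half-life; watered plants are stationary.
        Ledgers accumulate the configured season water for watered plants
        and freeze at drought onset for droughted plants.
        """
        cfg = self.config
        rng = self._rng(4)
        records: list[GasExchangeRecord] = []
        mtci_rows = []
        ledgers: list[PlantLedger] = []
        n_drought = int(round(cfg.drought_fraction * cfg.n_plants_per_n))
        for co2, regime in cfg.scenarios():
            t_air, rh = cfg.vpd_regimes[regime]
            d = cfg.canopy_vpd(regime)
            g1 = self._g1(co2, regime)
            k = cfg.k_exponent
            half_life = cfg.drought_half_life_d[regime]
            for n_level in cfg.n_levels:
                params = self._fvcb_params(n_level, regime)
                r = g1 / (g1 + d**k)
                a0 = fvcb_assimilation(r * co2, params)
                gsw0 = predict_gs(a0, co2, d, g1, k)
                e0 = gsw0 * d / ATM_PRESSURE_KPA * 1000.0
                mtci0 = cfg.mtci_per_chl * cfg.chl_by_n[n_level]
                water_full = (cfg.water_total_l[(co2, regime)]
                              * cfg.n_water_multiplier[n_level])
                for i in range(cfg.n_plants_per_n):
                    droughted = i < n_drought
                    watering = "drought" if droughted else "watered"
                    plant = f"{int(co2)}-{regime}-{n_level}-D{i:02d}"
                    treatment = Treatment(co2_ppm=co2, vpd_regime=regime,
                                          n_level=n_level, watering=watering)
                    for day in cfg.drought_days:
                        decay = 0.5 ** (day / half_life) if droughted else 1.0
                        e_day = e0 * decay * (
                            1 + 0.05 * rng.standard_normal()
                        )
                        gsw_day = gsw0 * decay * (
                            1 + 0.05 * rng.standard_normal()
                        )
                        records.append(GasExchangeRecord(
                            plant_id=plant, surface="combined",
                            gsw=gsw_day, E=max(e_day, 0.0),
                            treatment=treatment, D=d, T_air=t_air, RH=rh,
                            time_min=day * 1440.0,
                        ))
                        mtci_decay = 0.5 ** (day / (2 * half_life)) if droughted else 1.0
                        mtci_rows.append({
                            "plant_id": plant, "day": day,
                            "co2_ppm": co2, "vpd_regime": regime,
                            "n_level": n_level, "watering": watering,
                            "mtci": mtci0 * mtci_decay
                            * (1 + 0.03 * rng.standard_normal()),
                        })
                    water = water_full * (
                        cfg.drought_onset_frac if droughted else 1.0
                    )
                    ear = (1000.0 * water / cfg.ml_per_g[(co2, regime)]
                           * (1 + cfg.ledger_noise_rel * rng.standard_normal()))
                    ear = max(ear, 0.1)
                    if droughted:
                        ear *= 0.8
                    ledgers.append(PlantLedger(
                        plant_id=plant, treatment=treatment,
                        water_applied_l=water, ear_weight_g=ear,
                        biomass_g=ear * 2.2,
                    ))
        return records, pd.DataFrame(mtci_rows), ledgers

    # -- reflectance spectra ----------------------------------------------
    def generate_spectra(self, n_per_level: int = 8):
        """Red-edge reflectance spectra with known chlorophyll.

        Built so that MTCI is (up to noise) proportional to the configured
        chlorophyll: the 709-nm shoulder sits at a fraction 1/(1 + c*chl)
        of the 681->754 rise.  Returns ``(spectra, chl_values)``.
        """
        cfg = self.config
        rng = self._rng(5)
        grid = np.arange(350.0, 2500.0 + 1e-9, cfg.spectral_step_nm)
        spectra: list[SpectralRecord] = []
        chl_values: list[float] = []
        for n_level in cfg.n_levels:
            for i in range(n_per_level):
                chl = cfg.chl_by_n[n_level] * (
                    1 + cfg.chl_noise_rel * rng.standard_normal()
                )
                chl = max(chl, 0.5)
                r681 = 0.04 + 0.01 * rng.random()
                r754 = 0.45 + 0.04 * rng.random()
                u = 1.0 / (1.0 + cfg.mtci_per_chl * chl)
                r709 = r681 + u * (r754 - r681)
                anchors_nm = [350, 500, 670, 681, 709, 754, 900, 1300,
                              1900, 2500]
                anchors_r = [0.05, 0.08, 0.05, r681, r709, r754,
                             r754 * 0.98, 0.42, 0.18, 0.06]
                refl = np.interp(grid, anchors_nm, anchors_r)
                spectra.append(SpectralRecord(
                    wavelengths=grid, reflectance=refl,
                    plant_id=f"{n_level}-S{i}",
                ))
                chl_values.append(chl)
        return spectra, chl_values
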