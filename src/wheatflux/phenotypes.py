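"""Leaf phenotype calculators: stomatal density/size, chlorophyll from DMF
absorbance, the MTCI red-edge index, fertiliser dosing and seasonal
water-use-efficiency ledgers.

Stomatal traits come from micrograph counts over a fixed imaged area
(two fields of view per surface, 1.2049 mm2 total) with five guard-cell
lengths per field.  Chlorophyll is extracted in N,N-dimethylformamide and
quantified from absorbance at 663.8, 646.8 and 480 nm with the Wellburn
coefficient set.  MTCI = (R754 - R709)/(R709 - R681) proxies chlorophyll
from leaf reflectance.  Whole-cycle WUE is total ear mass over total water
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import PlantLedger

__all__ = [
    "TOTAL_FOV_AREA_MM2",
    "StomatalCounts",
    "SpectralRecord",
    "WELLBURN_DMF",
    "stomatal_density",
    "stomatal_size",
    "chlorophyll_dmf",
    "mtci",
    "fertiliser_per_plant",
    "wue_ledger",
    "water_saving_percent",
]

#: total micrograph area counted across the two fields of view (mm2)
TOTAL_FOV_AREA_MM2 = 1.2049

#: Wellburn (DMF) pigment coefficients, ug ml-1 from absorbance:
#: chl_a = a1*A663.8 - a2*A646.8 ; chl_b = b1*A646.8 - b2*A663.8 ;
#: carotenoids = (1000*A480 - c1*chl_a - c2*chl_b) / c3
WELLBURN_DMF = {
    "a1": 12.00, "a2": 3.11,
    "b1": 20.78, "b2": 4.88,
    "c1": 1.12, "c2": 34.07, "c3": 245.0,
}


@dataclass
class StomatalCounts:
    """Counts and guard-cell lengths for one surface of one replicate:
    exactly two fields of view, five guard-cell lengths each."""

    plant_id: str
    surface: str
    fov_counts: tuple  # stomata per FOV, len 2
    gc_lengths_um: tuple  # two tuples of 5 lengths (um)
    fov_area_mm2: float = TOTAL_FOV_AREA_MM2  # total area of both FOVs

    def __post_init__(self):
        if self.surface not in ("abaxial", "adaxial"):
            raise ValueError(f"surface must be abaxial/adaxial, got {self.surface!r}")
        if len(self.fov_counts) != 2:
            raise ValueError("exactly 2 fields of view are required")
        if any(c < 0 for c in self.fov_counts):
            raise ValueError("stomatal counts must be >= 0")
        if len(self.gc_lengths_um) != 2 or any(
            len(f) != 5 for f in self.gc_lengths_um
        ):
            raise ValueError("5 guard-cell lengths per FOV are required")


def stomatal_density(counts: StomatalCounts) -> float:
    """Stomatal density SD (stomata mm-2): total stomata across both FOVs
    divided by the total counted area."""
    if counts.fov_area_mm2 <= 0:
        raise ValueError("counted area must be positive")
    return sum(counts.fov_counts) / counts.fov_area_mm2


def stomatal_size(counts: StomatalCounts) -> float:
    """Stomatal size SS (um): mean of the five guard-cell lengths per FOV,
    then mean of the two FOV values."""
    fov_means = [float(np.mean(f)) for f in counts.gc_lengths_um]
    return float(np.mean(fov_means))


def chlorophyll_dmf(
    a663_8: float,
    a646_8: float,
    a480: float = 0.0,
    extract_ml: float = 5.0,
    disc_mass_mg: float | None = None,
    dw_fw_ratio: float | None = None,
    coefficients: dict = WELLBURN_DMF,
) -> dict:
    """Pigments from DMF-extract absorbance (Wellburn coefficients).

    Returns concentrations in ug ml-1 (``chl_a``, ``chl_b``, ``chl_total``,
    ``carotenoids``), per-extract amounts in ug (``*_ug``, scaled by
    ``extract_ml``), and — when ``disc_mass_mg`` and ``dw_fw_ratio`` are
    supplied — chlorophyll per unit estimated dry mass (``chl_per_dw_ug_mg``,
    ug per mg dry mass, the dry mass estimated as dw/fw ratio x disc fresh
    mass).  Negative computed pigments are clipped to zero with a warning.
    """
    if min(a663_8, a646_8, a480) < 0:
        raise ValueError("absorbances must be >= 0")
    if extract_ml <= 0:
        raise ValueError("extract volume must be positive")
    c = coefficients
    chl_a = c["a1"] * a663_8 - c["a2"] * a646_8
    chl_b = c["b1"] * a646_8 - c["b2"] * a663_8
    # carotenoids only when the 480-nm reading was actually taken
    car = (
        (1000.0 * a480 - c["c1"] * chl_a - c["c2"] * chl_b) / c["c3"]
        if a480 > 0
        else 0.0
    )
    clipped = {}
    for name, val in (("chl_a", chl_a), ("chl_b", chl_b), ("carotenoids", car)):
        if val < 0:
            warnings.warn(f"computed {name} was negative ({val:.3g}); clipped to 0")
            val = 0.0
        clipped[name] = val
    out = dict(clipped)
    out["chl_total"] = clipped["chl_a"] + clipped["chl_b"]
    for name in ("chl_a", "chl_b", "chl_total", "carotenoids"):
        out[f"{name}_ug"] = out[name] * extract_ml
    if disc_mass_mg is not None and dw_fw_ratio is not None:
        if disc_mass_mg <= 0 or dw_fw_ratio <= 0:
            raise ValueError("disc mass and dw/fw ratio must be positive")
        dry_mass_mg = dw_fw_ratio * disc_mass_mg
        out["dry_mass_mg"] = dry_mass_mg
        out["chl_per_dw_ug_mg"] = out["chl_total_ug"] / dry_mass_mg
    return out


@dataclass
class SpectralRecord:
    """Leaf reflectance spectrum on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    plant_id: str = ""

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelength and reflectance grids differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.reflectance < 0) or np.any(self.reflectance > 1):
            raise ValueError("reflectance must lie in [0, 1]")

    def band(self, nm: float, method: str = "interp") -> float:
        """Reflectance at ``nm`` by linear interpolation (default) or the
        nearest grid band."""
        w, r = self.wavelengths, self.reflectance
        if not w[0] <= nm <= w[-1]:
            raise ValueError(f"{nm} nm outside the measured grid")
        if method == "nearest":
            return float(r[np.argmin(np.abs(w - nm))])
        return float(np.interp(nm, w, r))


def mtci(spec: SpectralRecord, method: str = "interp",
         denom_tol: float = 1e-9) -> float | None:
    """MERIS terrestrial chlorophyll index (R754 - R709)/(R709 - R681).

    Returns None (undefined) when the red-edge denominator is below
    ``denom_tol``, e.g. for a flat spectrum.
    """
    r754 = spec.band(754.0, method)
    r709 = spec.band(709.0, method)
    r681 = spec.band(681.0, method)
    denom = r709 - r681
    if abs(denom) < denom_tol:
        return None
    return (r754 - r709) / denom


def fertiliser_per_plant(weekly_total_g: float, n_plants: int = 32) -> float:
    """Per-plant weekly fertiliser dose (g) from a treatment-group total."""
    if weekly_total_g <= 0 or n_plants <= 0:
        raise ValueError("weekly total and plant count must be positive")
    return weekly_total_g / n_plants


def wue_ledger(ledger: PlantLedger) -> dict:
    """Whole-cycle water-use efficiency of one plant.

    ``wue_g_per_l`` = total ear mass / total water applied;
    ``ml_per_g`` = 1000 * water / ear mass (undefined for zero ear mass).
    The two satisfy wue * ml_per_g = 1000 exactly.
    """
    if ledger.water_applied_l <= 0:
        raise ValueError("water applied must be positive")
    wue = ledger.ear_weight_g / ledger.water_applied_l
    ml_per_g = (
        1000.0 * ledger.water_applied_l / ledger.ear_weight_g
        if ledger.ear_weight_g > 0
        else None
    )
    return {"wue_g_per_l": wue, "ml_per_g": ml_per_g,
            "undefined": ml_per_g is None}


def water_saving_percent(water_a_l: float, water_b_l: float) -> float:
    """Percentage water saving of regime A relative to regime B:
    100*(B - A)/B."""
    if water_b_l <= 0:
        raise ValueError("reference water total must be positive")
    return 100.0 * (water_b_l - water_a_l) / water_b_l
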