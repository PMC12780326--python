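"""Amphistomatous flux partitioning and thermal-offset regressions.

Wheat leaves carry stomata on both surfaces; per-surface porometer readings
are combined by arithmetic summation of the fluxes, and the abaxial (lower)
surface share of whole-leaf E or gsw is reported as a percentage.  The
paper-level analysis variance-stabilises those proportions with the
arcsine-square-root transform, and relates treatment-mean fluxes to the
canopy thermal offset dT = T_leaf - T_reference (negative = leaf cooler
than the dry reference, i.e. stronger evaporative cooling).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .core import GasExchangeRecord, Treatment, ValidationError

__all__ = [
    "SurfacePair",
    "ThermalReading",
    "PairingError",
    "combine_surfaces",
    "abaxial_fraction",
    "arcsine_sqrt",
    "flux_vs_deltaT",
]


class PairingError(ValueError):
    """The two records of a surface pair do not belong together."""


@dataclass
class SurfacePair:
    """Matched abaxial/adaxial readings of one leaf."""

    ab: GasExchangeRecord
    ad: GasExchangeRecord

    def __post_init__(self):
        if self.ab.surface != "abaxial" or self.ad.surface != "adaxial":
            raise PairingError(
                f"surfaces mislabelled: ab={self.ab.surface!r}, ad={self.ad.surface!r}"
            )
        if self.ab.plant_id != self.ad.plant_id:
            raise PairingError(
                f"plant ids differ: {self.ab.plant_id!r} vs {self.ad.plant_id!r}"
            )


@dataclass
class ThermalReading:
    """Radiometric leaf temperature against a dry reference surface."""

    plant_id: str
    t_leaf: float
    t_ref: float
    treatment: Treatment = field(default_factory=Treatment)

    @property
    def delta_t(self) -> float:
        """T_leaf - T_ref (degC); negative means the leaf is cooler."""
        return self.t_leaf - self.t_ref


def combine_surfaces(pair: SurfacePair) -> GasExchangeRecord:
    """Whole-leaf record: E and gsw are the sums of the two surfaces;
    other fields are carried from the adaxial record.  Quality flags
    propagate."""
    ad = pair.ad
    combined = dataclasses.replace(
        ad,
        surface="combined",
        gsw=pair.ab.gsw + ad.gsw,
        E=pair.ab.E + ad.E,
    )
    combined.flagged = pair.ab.flagged or ad.flagged
    return combined


def abaxial_fraction(pair: SurfacePair, flux: str = "E") -> float | None:
    """Abaxial percentage share of a whole-leaf flux: 100*ab/(ab+ad).

    ``flux`` is "E" or "gsw".  Returns None (undefined) when the combined
    flux is not positive.
    """
    if flux not in ("E", "gsw"):
        raise ValueError(f"flux must be 'E' or 'gsw', got {flux!r}")
    ab = getattr(pair.ab, flux)
    ad = getattr(pair.ad, flux)
    total = ab + ad
    if total <= 0:
        return None
    return 100.0 * ab / total


def arcsine_sqrt(p) -> float | np.ndarray:
    """Variance-stabilising transform asin(sqrt(p)) (radians) for a
    proportion p in [0, 1].

    Negative proportions (from flagged negative porometer readings) cannot
    be transformed; such source rows are excluded upstream, and out-of-range
    input raises.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(
            "proportion outside [0, 1]; flagged negative-flux rows must be "
            "removed from the analysis before transforming"
        )
    out = np.arcsin(np.sqrt(arr))
    return float(out) if out.ndim == 0 else out


def flux_vs_deltaT(flux_means, delta_t_means, order: int = 1) -> dict:
    """Polynomial regression of treatment-mean flux on treatment-mean dT.

    Operates on treatment means (one point per factorial cell), not raw
    records.  ``order`` is 1 (linear, used for E) or 3 (cubic, used for
    gsw).  Returns coefficients (highest degree first) and r2.
    """
    x = np.asarray(delta_t_means, dtype=float)
    y = np.asarray(flux_means, dtype=float)
    if len(x) < order + 2:
        raise ValueError(
            f"order-{order} regression needs >= {order + 2} mean points, got {len(x)}"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, order)
    pred = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"coefficients": coeffs[::-1].tolist(), "r2": r2, "order": order,
            "n": len(x)}
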