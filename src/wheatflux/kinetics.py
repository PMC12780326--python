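"""Stomatal kinetics under light shifts and CO2-response insensitivity.

Light-shift assays follow a fixed phase plan — ~5 min of steady-state
saturating light, 60 min of darkness, 60 min of re-applied light — and are
summarised by initial opening/closing rates (OLS slope of gsw over the
first 20 min of each shift), endpoint conductances at 65 and 125 min, and
the percentage closure attained over the dark hour.

Separately, stomata normally close as the CO2 reference concentration is
stepped above growth levels during an A/Ci curve; loss of that response
("CO2 blindness") is diagnosed from the gsw-vs-Ca slope over the
supra-ambient steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Treatment
from .farquhar import ACiCurve

__all__ = [
    "PHASE_PLAN",
    "KineticsTrace",
    "KineticsSummary",
    "CoverageError",
    "summarise_kinetics",
    "co2_blindness_slope",
    "BLINDNESS_SLOPE_THRESHOLD",
]

#: default phase plan (label, start min, end min)
PHASE_PLAN = (("steady", 0.0, 5.0), ("dark", 5.0, 65.0), ("relight", 65.0, 125.0))

#: |slope| (mol m-2 s-1 per umol mol-1) below which the gsw-vs-Ca response
#: is labelled "blind"; an artifact threshold, exposed in config, because
#: the phenomenon is reported qualitatively.
BLINDNESS_SLOPE_THRESHOLD = 2e-5


class CoverageError(ValueError):
    """Samples do not cover a required analysis window."""


@dataclass
class KineticsTrace:
    """Time-stamped (t_min, a, gsw) samples through the light-shift phases."""

    plant_id: str
    samples: pd.DataFrame  # columns: t_min, gsw, optionally a
    phases: tuple = PHASE_PLAN
    treatment: Treatment = field(default_factory=Treatment)

    def __post_init__(self):
        if not {"t_min", "gsw"}.issubset(self.samples.columns):
            raise ValueError("samples need columns t_min and gsw")
        starts = [p[1] for p in self.phases]
        ends = [p[2] for p in self.phases]
        if any(e <= s for s, e in zip(starts, ends)) or any(
            abs(ends[i] - starts[i + 1]) > 1e-9 for i in range(len(self.phases) - 1)
        ):
            raise ValueError("phases must be contiguous and non-overlapping")

    def phase(self, label: str) -> tuple[float, float]:
        for name, start, end in self.phases:
            if name == label:
                return start, end
        raise KeyError(label)


@dataclass
class KineticsSummary:
    """Responsiveness metrics of one light-shift trace."""

    g0: float              # mean gsw over the steady phase (mol m-2 s-1)
    rate_close: float      # initial gsw slope in dark (mol m-2 s-1 min-1)
    rate_open: float       # initial gsw slope on relight
    g_dark_end: float      # gsw at end of dark (65 min by default)
    g_light_end: float     # gsw at end of relight (125 min)
    pct_closure: float     # 100*(g0 - g_dark_end)/g0


def _window_slope(df: pd.DataFrame, start: float, end: float,
                  mode: str = "ols") -> float:
    w = df[(df["t_min"] >= start - 1e-9) & (df["t_min"] <= end + 1e-9)]
    if len(w) < 2:
        raise CoverageError(f"window [{start}, {end}] min has <2 samples")
    gaps = np.diff(np.sort(w["t_min"].values))
    if len(gaps) and gaps.max() > 5.0:
        raise CoverageError(
            f"sampling gap {gaps.max():.1f} min > 5 min inside window "
            f"[{start}, {end}]"
        )
    t = w["t_min"].values
    g = w["gsw"].values
    if mode == "two_point":
        return float((g[-1] - g[0]) / (t[-1] - t[0]))
    return float(np.polyfit(t, g, 1)[0])


def _nearest(df: pd.DataFrame, t: float, tol_min: float = 1.0) -> float:
    i = (df["t_min"] - t).abs().idxmin()
    if abs(df.loc[i, "t_min"] - t) > tol_min:
        raise CoverageError(f"no sample within {tol_min} min of t={t} min")
    return float(df.loc[i, "gsw"])


def summarise_kinetics(
    trace: KineticsTrace, window_min: float = 20.0, rate_mode: str = "ols"
) -> KineticsSummary:
    """Compute the light-shift responsiveness metrics of one trace.

    Rates are OLS slopes of gsw on time within the first ``window_min``
    minutes of the dark and relight phases (``rate_mode="two_point"``
    switches to an endpoint difference); endpoint conductances use the
    nearest sample within 1 min.  Physiologically a closing rate should be
    <= 0 and an opening rate >= 0; violations warn rather than raise.
    """
    df = trace.samples.sort_values("t_min")
    s0, s1 = trace.phase("steady")
    d0, d1 = trace.phase("dark")
    r0, r1 = trace.phase("relight")

    steady = df[(df["t_min"] >= s0 - 1e-9) & (df["t_min"] <= s1 + 1e-9)]
    if steady.empty:
        raise CoverageError("no samples in the steady phase")
    g0 = float(steady["gsw"].mean())

    rate_close = _window_slope(df, d0, d0 + window_min, rate_mode)
    rate_open = _window_slope(df, r0, r0 + window_min, rate_mode)
    g_dark_end = _nearest(df, d1)
    g_light_end = _nearest(df, r1)
    pct_closure = 100.0 * (g0 - g_dark_end) / g0 if g0 > 0 else float("nan")

    if rate_close > 1e-12 or rate_open < -1e-12:
        warnings.warn(
            f"non-physiological trace: rate_close={rate_close:.3g}, "
            f"rate_open={rate_open:.3g}"
        )
    return KineticsSummary(
        g0=g0, rate_close=rate_close, rate_open=rate_open,
        g_dark_end=g_dark_end, g_light_end=g_light_end,
        pct_closure=pct_closure,
    )


def co2_blindness_slope(
    curve: ACiCurve,
    growth_ca: float | None = None,
    threshold: float = BLINDNESS_SLOPE_THRESHOLD,
) -> dict:
    """Slope of gsw vs CO2 reference over the supra-ambient steps.

    ``growth_ca`` defaults to the curve's treatment CO2.  Requires >= 4
    steps strictly above growth Ca.  Returns the OLS slope and a label:
    "blind" when |slope| < ``threshold``, else "responsive".
    """
    if "gsw" not in curve.points.columns:
        raise ValueError("curve points carry no gsw column")
    ca0 = growth_ca if growth_ca is not None else curve.treatment.co2_ppm
    supra = curve.points[curve.points["ca_ref"] > ca0]
    if len(supra) < 4:
        raise ValueError(
            f"need >= 4 supra-ambient steps above Ca={ca0}, got {len(supra)}"
        )
    slope = float(np.polyfit(supra["ca_ref"].values.astype(float),
                             supra["gsw"].values.astype(float), 1)[0])
    label = "blind" if abs(slope) < threshold else "responsive"
    return {"slope": slope, "label": label, "n_steps": len(supra),
            "threshold": threshold}
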