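"""Stomatal optimality (Medlyn) modelling with a generalized VPD exponent.

The unified stomatal-optimality model approximates the conductance that
minimises water spent per unit carbon gained:

    gs = 1.6 * (1 + g1 / D**k) * A / Ca                               (model)

with the slope parameter recovered per observation by algebraic inversion

    g1 = (Ci/Ca) * D**k / (1 - Ci/Ca)                                 (inverse)

where D is leaf-to-air VPD (kPa), A net assimilation (umol m-2 s-1), Ca/Ci
ambient/intercellular CO2 (umol mol-1) and k the VPD exponent.  The classic
model uses k = 0.5 (sqrt(D)); k is generalized here and selected from a
candidate set {0.2, 0.5, 0.8} by predictive RMSE against observed gsw.
g1 carries units kPa**k, so fits at different k are compared only through
RMSE / R2, never through g1 magnitude.

The exact identity  predict_gs(estimate_g1(...)) == 1.6*A/(Ca-Ci)  holds for
any k and is the module's principal self-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import GasExchangeRecord

__all__ = [
    "TETENS",
    "saturation_vapour_pressure",
    "air_vpd",
    "estimate_g1",
    "predict_gs",
    "MedlynOptimality",
    "OptimalityFit",
    "fit_optimality",
    "WueSummary",
    "wue_summary",
    "UndefinedOptimumError",
]

#: Tetens saturation-vapour-pressure constants (kPa, dimensionless, degC).
TETENS = (0.61078, 17.27, 237.3)

DEFAULT_K_CANDIDATES = (0.2, 0.5, 0.8)


class UndefinedOptimumError(ValueError):
    """Ci >= Ca: stomatal closure implies a negative or infinite g1."""


def saturation_vapour_pressure(t_c, constants=TETENS):
    """Saturation vapour pressure (kPa) of air at ``t_c`` degC, Tetens form.

    es = a * exp(b*T / (T + c)).  Valid for -20 <= T <= 60 degC.
    """
    t = np.asarray(t_c, dtype=float)
    if np.any(t < -20) or np.any(t > 60):
        raise ValueError(f"temperature outside [-20, 60] degC: {t_c}")
    a, b, c = constants
    out = a * np.exp(b * t / (t + c))
    return float(out) if np.isscalar(t_c) else out

def air_vpd(t_c, rh_percent, constants=TETENS):
    """Air vapour pressure deficit D (kPa) from temperature and RH.

    D = es(T) * (1 - RH/100).  The study's two canopy regimes evaluate to
    1.43 kPa (27 degC, 60% RH) and 3.14 kPa (37 degC, 50% RH).
    """
    rh = np.asarray(rh_percent, dtype=float)
    if np.any(rh < 0) or np.any(rh > 100):
        raise ValueError(f"RH outside [0, 100]%: {rh_percent}")
    out = saturation_vapour_pressure(t_c, constants) * (1.0 - rh / 100.0)
    return float(out) if np.isscalar(rh_percent) else out


def estimate_g1(ci, ca, d, k=0.5):
    """Per-observation g1 (kPa**k) by inversion of the optimality model."""
    ci, ca, d = (np.asarray(x, dtype=float) for x in (ci, ca, d))
    if np.any(d <= 0):
        raise ValueError("D must be positive")
    if not 0 < k <= 1:
        raise ValueError(f"VPD exponent k must lie in (0, 1], got {k}")
    if np.any(ci <= 0):
        raise ValueError("Ci must be positive")
    if np.any(ci >= ca):
        raise UndefinedOptimumError(
            "Ci >= Ca: the optimality closure implies negative/infinite g1"
        )
    r = ci / ca
    out = r * d**k / (1.0 - r)
    return float(out) if out.ndim == 0 else out


def predict_gs(a, ca, d, g1, k=0.5):
    """Optimality-model stomatal conductance (mol m-2 s-1)."""
    a_, ca_, d_ = (np.asarray(x, dtype=float) for x in (a, ca, d))
    if np.any(a_ <= 0) or np.any(ca_ <= 0) or np.any(d_ <= 0):
        raise ValueError("A, Ca and D must all be positive")
    out = 1.6 * (1.0 + g1 / d_**k) * a_ / ca_
    return float(out) if out.ndim == 0 else out


@dataclass
class OptimalityFit:
    """Fit of the optimality model at one VPD exponent."""

    k: float
    g1: float
    per_obs_g1: np.ndarray
    r2: float
    rmse: float
    n: int

    def to_dict(self) -> dict:
        return {
            "k": self.k, "g1": self.g1, "r2": self.r2,
            "rmse": self.rmse, "n": self.n,
        }


class MedlynOptimality(BaseEstimator):
    """Stomatal-optimality model with VPD-exponent selection.

    scikit-learn style estimator: ``fit`` consumes a DataFrame with columns
    ``A, gsw, Ca, Ci, D`` (e.g. from ``core.records_to_frame``); ``predict``
    returns modelled gsw at the selected exponent.

    Parameters
    ----------
    k : float | "auto"
        VPD exponent; "auto" selects from ``k_candidates`` by RMSE of
        predicted vs observed gsw.
    k_candidates : sequence of float
        Candidate exponents, default (0.2, 0.5, 0.8).
    g1_method : {"median", "mean", "regression"}
        Aggregation of per-observation g1 values.  "regression" fits gsw
        against 1.6*A/(Ca*D**k) through the origin on top of the diffusive
        floor 1.6*A/Ca.

    Attributes
    ----------
    k_ : selected exponent
    g1_ : aggregated slope (kPa**k_)
    fits_ : dict of per-candidate :class:`OptimalityFit`
    r2_, rmse_, n_ : diagnostics of the selected fit
    """

    def __init__(self, k="auto", k_candidates=DEFAULT_K_CANDIDATES,
                 g1_method="median"):
        self.k = k
        self.k_candidates = k_candidates
        self.g1_method = g1_method

    # -- internals ---------------------------------------------------------
    def _fit_one(self, df: pd.DataFrame, k: float) -> OptimalityFit:
        per_obs = estimate_g1(df["Ci"].values, df["Ca"].values, df["D"].values, k)
        per_obs = np.atleast_1d(per_obs)
        if self.g1_method == "median":
            g1 = float(np.median(per_obs))
        elif self.g1_method == "mean":
            g1 = float(np.mean(per_obs))
        elif self.g1_method == "regression":
            # gsw - 1.6 A/Ca = g1 * 1.6 A/(Ca D^k): origin regression for g1
            x = 1.6 * df["A"].values / (df["Ca"].values * df["D"].values ** k)
            y = df["gsw"].values - 1.6 * df["A"].values / df["Ca"].values
            g1 = float(np.dot(x, y) / np.dot(x, x))
        else:
            raise ValueError(f"unknown g1_method {self.g1_method!r}")
        pred = predict_gs(df["A"].values, df["Ca"].values, df["D"].values, g1, k)
        obs = df["gsw"].values
        resid = obs - pred
        rmse = float(np.sqrt(np.mean(resid**2)))
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        return OptimalityFit(k=k, g1=g1, per_obs_g1=per_obs, r2=r2,
                             rmse=rmse, n=len(df))

    @staticmethod
    def _clean(X: pd.DataFrame) -> tuple[pd.DataFrame, list]:
        required = ["A", "gsw", "Ca", "Ci", "D"]
        missing = [c for c in required if c not in X.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = X[required].astype(float)
        ok = (
            (df["A"] > 0) & (df["Ca"] > 0) & (df["D"] > 0)
            & (df["Ci"] > 0) & (df["Ci"] < df["Ca"]) & (df["gsw"] > 0)
        )
        excluded = list(df.index[~ok])
        return df[ok], excluded

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        df, excluded = self._clean(X)
        if excluded:
            warnings.warn(
                f"{len(excluded)} record(s) failed optimality preconditions "
                f"and were excluded: {excluded}"
            )
        self.excluded_ = excluded
        if len(df) < 4:
            raise ValueError(f"need at least 4 usable records, got {len(df)}")
        candidates = (
            list(self.k_candidates) if self.k == "auto" else [float(self.k)]
        )
        self.fits_ = {k: self._fit_one(df, k) for k in candidates}
        best = min(self.fits_.values(), key=lambda f: f.rmse)
        self.k_ = best.k
        self.g1_ = best.g1
        self.per_obs_g1_ = best.per_obs_g1
        self.r2_ = best.r2
        self.rmse_ = best.rmse
        self.n_ = best.n
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.atleast_1d(predict_gs(
            X["A"].values.astype(float), X["Ca"].values.astype(float),
            X["D"].values.astype(float), self.g1_, self.k_,
        ))


def fit_optimality(
    records, candidates=DEFAULT_K_CANDIDATES, g1_method="median"
) -> tuple[dict[float, OptimalityFit], float]:
    """Fit the optimality model at each candidate exponent.

    Accepts records or a canonical DataFrame; returns ``(fits, best_k)``
    where ``fits`` maps each k to its :class:`OptimalityFit` and ``best_k``
    minimises RMSE of predicted vs observed gsw.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        from .core import records_to_frame

        df = records_to_frame(records)
    est = MedlynOptimality(k="auto", k_candidates=candidates,
                           g1_method=g1_method).fit(df)
    return est.fits_, est.k_


@dataclass
class WueSummary:
    """Water-use-efficiency indices of one reading."""

    iwue: float | None          # intrinsic, A/gsw (umol mol-1)
    instantaneous_wue: float | None  # A/E (umol mmol-1)
    ci_ca: float | None = None  # dimensionless
    undefined: bool = False


def wue_summary(record: GasExchangeRecord) -> WueSummary:
    """A/gsw, A/E and Ci/Ca for one reading; zero denominators flag the
    result as undefined instead of raising."""
    a = record.A if record.A is not None else 0.0
    undefined = record.gsw <= 0 or record.E <= 0
    iwue = a / record.gsw if record.gsw > 0 else None
    inst = a / record.E if record.E > 0 else None
    ci_ca = None
    if record.Ci is not None and record.Ca:
        ci_ca = record.Ci / record.Ca
    return WueSummary(iwue=iwue, instantaneous_wue=inst, ci_ca=ci_ca,
                      undefined=undefined)
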