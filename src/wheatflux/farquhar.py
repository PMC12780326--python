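"""FvCB photosynthesis model: A/Ci fitting, temperature response and the
supply-function operating point.

The Farquhar–von Caemmerer–Berry model describes net assimilation as the
minimum of a rubisco-limited and a RuBP-regeneration-limited rate:

    Ac = Vcmax * (Ci - G*) / (Ci + Kc*(1 + O/Ko))
    Aj = J * (Ci - G*) / (4*Ci + 8*G*)         (J = Jmax at saturating light)
    A  = min(Ac, Aj) - Rd

with G* the photorespiratory CO2 compensation point, Kc/Ko Michaelis
constants and Rd day respiration.  Curves are fitted on a Ci basis
(mesophyll conductance assumed infinite) with the hard minimum rule, so
each point gets an unambiguous limitation label.

Kinetic constants default to the Bernacchi tobacco determination at 25 degC
and are Arrhenius-scaled to the measurement leaf temperature; the constant
set is a named, swappable config.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

from .core import Treatment

__all__ = [
    "KineticConstants",
    "BERNACCHI_25",
    "CONSTANT_SETS",
    "FvCBParams",
    "ACiCurve",
    "CO2_REF_SEQUENCE_450",
    "CO2_REF_SEQUENCE_720",
    "fvcb_assimilation",
    "limitation_labels",
    "FvCBModel",
    "fit_aci",
    "temperature_adjust",
    "supply_intersection",
    "FitNonConvergence",
]

#: Printed CO2-reference step sequences (umol mol-1) for the two growth CO2
#: concentrations; repeated recovery steps at growth Ca are intentional.
CO2_REF_SEQUENCE_450 = (450, 325, 200, 150, 100, 75, 50, 25,
                        450, 450, 450, 450, 585, 720, 860, 1000, 1250, 1500, 1800)
CO2_REF_SEQUENCE_720 = (720, 585, 450, 325, 200, 150, 100, 75, 50, 25,
                        720, 720, 720, 720, 860, 1000, 1250, 1500, 1800)

R_GAS = 8.314e-3  # kJ mol-1 K-1


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetic constants at 25 degC plus activation energies (kJ mol-1).

    kc in umol mol-1, ko in mmol mol-1, gamma_star in umol mol-1, o in
    mmol mol-1.  ``dhd_jmax``/``ds_jmax`` parametrise the peaked Arrhenius
    decline of Jmax at high temperature.
    """

    name: str = "bernacchi"
    kc: float = 404.9
    ko: float = 278.4
    gamma_star: float = 42.75
    o: float = 210.0
    ea_kc: float = 79.43
    ea_ko: float = 36.38
    ea_gamma_star: float = 37.83
    ea_vcmax: float = 65.33
    ea_rd: float = 46.39
    ea_jmax: float = 43.54
    dhd_jmax: float = 200.0
    ds_jmax: float = 0.635


BERNACCHI_25 = KineticConstants()
CONSTANT_SETS = {"bernacchi": BERNACCHI_25}


def get_constants(name_or_set) -> KineticConstants:
    if isinstance(name_or_set, KineticConstants):
        return name_or_set
    try:
        return CONSTANT_SETS[name_or_set]
    except KeyError:
        raise ValueError(
            f"unknown kinetic-constant set {name_or_set!r}; "
            f"known: {sorted(CONSTANT_SETS)}"
        ) from None


@dataclass
class FvCBParams:
    """Fitted (or assumed) FvCB parameters at a given leaf temperature."""

    vcmax: float
    jmax: float
    rd: float
    gamma_star: float = BERNACCHI_25.gamma_star
    kc: float = BERNACCHI_25.kc
    ko: float = BERNACCHI_25.ko
    o: float = BERNACCHI_25.o
    t_leaf: float = 25.0
    limitation: list = field(default_factory=list)

    def __post_init__(self):
        if min(self.vcmax, self.jmax, self.rd) <= 0:
            raise ValueError("vcmax, jmax and rd must all be positive")
        ratio = self.jmax / self.vcmax
        if not 1.0 <= ratio <= 3.0:
            warnings.warn(
                f"jmax/vcmax = {ratio:.2f} outside the typical [1, 3] range"
            )

    @property
    def km(self) -> float:
        """Effective Michaelis constant Kc*(1 + O/Ko), umol mol-1."""
        return self.kc * (1.0 + self.o / self.ko)


@dataclass
class ACiCurve:
    """One CO2-response curve: ordered steps of (ca_ref, a, ci, gsw, e)."""

    plant_id: str
    points: pd.DataFrame  # columns ca_ref, a, ci, gsw, e
    t_leaf: float = 27.0
    treatment: Treatment = field(default_factory=Treatment)

    def __post_init__(self):
        required = {"ca_ref", "a", "ci"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"curve points need columns {sorted(required)}")
        if len(self.points) < 8:
            raise ValueError(
                f"A/Ci curve needs >= 8 points, got {len(self.points)}"
            )
        if (self.points["ca_ref"] <= 0).any():
            raise ValueError("ca_ref values must be positive")


def fvcb_assimilation(ci, params: FvCBParams, smoothing: float | None = None):
    """Net assimilation A (umol m-2 s-1) at intercellular CO2 ``ci``.

    Hard minimum of the rubisco and RuBP branches by default; pass a
    ``smoothing`` curvature theta in (0, 1) for a hyperbolic-minimum
    variant.  ``ci`` below the compensation point yields negative net A,
    returned as-is.
    """
    ci_arr = np.asarray(ci, dtype=float)
    ac = params.vcmax * (ci_arr - params.gamma_star) / (ci_arr + params.km)
    aj = params.jmax * (ci_arr - params.gamma_star) / (4 * ci_arr + 8 * params.gamma_star)
    if smoothing is None:
        gross = np.minimum(ac, aj)
    else:
        th = smoothing
        gross = (ac + aj - np.sqrt((ac + aj) ** 2 - 4 * th * ac * aj)) / (2 * th)
    out = gross - params.rd
    return float(out) if out.ndim == 0 else out


def limitation_labels(ci, params: FvCBParams) -> list[str]:
    """Per-point labels: 'rubisco' where Ac < Aj, 'RuBP' where Aj < Ac,
    'transition' at (numerical) equality."""
    ci_arr = np.atleast_1d(np.asarray(ci, dtype=float))
    ac = params.vcmax * (ci_arr - params.gamma_star) / (ci_arr + params.km)
    aj = params.jmax * (ci_arr - params.gamma_star) / (4 * ci_arr + 8 * params.gamma_star)
    labels = []
    for a_c, a_j in zip(ac, aj):
        if math.isclose(a_c, a_j, rel_tol=1e-6, abs_tol=1e-9):
            labels.append("transition")
        else:
            labels.append("rubisco" if a_c < a_j else "RuBP")
    return labels


class FitNonConvergence(RuntimeError):
    """Fit failed to converge; carries the best-so-far parameters."""

    def __init__(self, message, best_params=None, diagnostics=None):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics


class FvCBModel(BaseEstimator):
    """Least-squares FvCB fit of an A/Ci curve.

    scikit-learn style estimator over 2-D ``X`` holding Ci in its first
    column (or a DataFrame with a ``ci`` column) and target ``y`` = net A.

    Parameters
    ----------
    constants : str | KineticConstants
        Named kinetic-constant set, Arrhenius-scaled to ``t_leaf``.
    t_leaf : float
        Leaf temperature of the curve (degC).
    fit_rd : bool
        Fit day respiration (default) or pin it at ``rd_init``.
    smoothing : float | None
        Optional hyperbolic-minimum curvature; None = hard minimum rule.

    Attributes
    ----------
    params_ : :class:`FvCBParams` with per-point limitation labels
    vcmax_, jmax_, rd_ : fitted values (umol m-2 s-1) at ``t_leaf``
    rmse_ : root-mean-square residual (umol m-2 s-1)
    stderr_ : dict of per-parameter standard errors (None if unavailable)
    """

    def __init__(self, constants="bernacchi", t_leaf=25.0, fit_rd=True,
                 rd_init=1.0, smoothing=None):
        self.constants = constants
        self.t_leaf = t_leaf
        self.fit_rd = fit_rd
        self.rd_init = rd_init
        self.smoothing = smoothing

    def _scaled_constants(self) -> FvCBParams:
        """Kinetic constants at t_leaf (vcmax/jmax placeholders of 1)."""
        base = FvCBParams(
            vcmax=1.0, jmax=2.0, rd=self.rd_init,
            gamma_star=get_constants(self.constants).gamma_star,
            kc=get_constants(self.constants).kc,
            ko=get_constants(self.constants).ko,
            o=get_constants(self.constants).o, t_leaf=25.0,
        )
        return temperature_adjust(base, self.t_leaf, self.constants)

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            ci = X["ci"].values.astype(float)
        else:
            ci = np.asarray(X, dtype=float)
            if ci.ndim == 2:
                ci = ci[:, 0]
        a_obs = np.asarray(y, dtype=float)
        const = self._scaled_constants()
        gamma_star, kc, ko, o = const.gamma_star, const.kc, const.ko, const.o
        km = kc * (1.0 + o / ko)

        low = ci < 250.0
        if low.sum() < 3:
            warnings.warn("fewer than 3 points below the inflection: "
                          "vcmax weakly constrained")
        # deterministic initial values from linearised branches
        rd0 = self.rd_init
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slice
            vc0 = np.nanmedian(
                np.where(
                    low & (ci > gamma_star + 5),
                    (a_obs + rd0) * (ci + km) / (ci - gamma_star),
                    np.nan,
                )
            )
        if not np.isfinite(vc0) or vc0 <= 0:
            vc0 = 80.0
        i_hi = int(np.argmax(ci))
        j0 = (a_obs[i_hi] + rd0) * (4 * ci[i_hi] + 8 * gamma_star) / (
            ci[i_hi] - gamma_star
        )
        if not np.isfinite(j0) or j0 <= 0:
            j0 = 1.8 * vc0

        pars = lmfit.Parameters()
        pars.add("vcmax", value=float(vc0), min=1e-3)
        pars.add("jmax", value=float(max(j0, 1e-2)), min=1e-3)
        pars.add("rd", value=float(rd0), min=1e-6, vary=self.fit_rd)

        def residual(p):
            trial = FvCBParams(
                vcmax=p["vcmax"].value, jmax=p["jmax"].value, rd=p["rd"].value,
                gamma_star=gamma_star, kc=kc, ko=ko, o=o, t_leaf=self.t_leaf,
            )
            return fvcb_assimilation(ci, trial, self.smoothing) - a_obs

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # transient jmax/vcmax ratio warns
            result = lmfit.minimize(residual, pars, method="leastsq")
        if not result.success:
            raise FitNonConvergence(
                f"A/Ci fit did not converge: {result.message}",
                best_params=result.params, diagnostics=result,
            )
        p = result.params
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitted = FvCBParams(
                vcmax=p["vcmax"].value, jmax=p["jmax"].value, rd=p["rd"].value,
                gamma_star=gamma_star, kc=kc, ko=ko, o=o, t_leaf=self.t_leaf,
            )
        fitted.limitation = limitation_labels(ci, fitted)
        self.params_ = fitted
        self.vcmax_, self.jmax_, self.rd_ = fitted.vcmax, fitted.jmax, fitted.rd
        self.rmse_ = float(np.sqrt(np.mean(result.residual**2)))
        self.stderr_ = {
            name: (p[name].stderr if p[name].stderr is not None else None)
            for name in ("vcmax", "jmax", "rd")
        }
        self.result_ = result
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            ci = X["ci"].values.astype(float)
        else:
            ci = np.asarray(X, dtype=float)
            if ci.ndim == 2:
                ci = ci[:, 0]
        return np.atleast_1d(fvcb_assimilation(ci, self.params_, self.smoothing))


def fit_aci(curve: ACiCurve, constants="bernacchi", **kwargs) -> FvCBParams:
    """Fit an :class:`ACiCurve`, returning :class:`FvCBParams` with
    limitation labels and a ``fit`` diagnostics attribute."""
    model = FvCBModel(constants=constants, t_leaf=curve.t_leaf, **kwargs)
    model.fit(curve.points, curve.points["a"].values)
    params = model.params_
    params.fit = {"rmse": model.rmse_, "stderr": model.stderr_}  # type: ignore[attr-defined]
    return params


def _arrhenius(k25: float, ea: float, t_c: float) -> float:
    tk = t_c + 273.15
    return k25 * math.exp(ea * (tk - 298.15) / (298.15 * R_GAS * tk))


def _peaked_arrhenius(k25, ea, dhd, ds, t_c):
    tk = t_c + 273.15
    num = 1.0 + math.exp((298.15 * ds - dhd) / (298.15 * R_GAS))
    den = 1.0 + math.exp((tk * ds - dhd) / (tk * R_GAS))
    return _arrhenius(k25, ea, t_c) * num / den


def temperature_adjust(
    params_25: FvCBParams, t_leaf: float, constants="bernacchi"
) -> FvCBParams:
    """Scale 25-degC FvCB parameters to ``t_leaf``.

    Arrhenius scaling for kc, ko, gamma_star, vcmax and rd; peaked
    Arrhenius for jmax.  ``t_leaf`` = 25 is the identity.
    """
    if not 0.0 <= t_leaf <= 50.0:
        raise ValueError(f"t_leaf outside [0, 50] degC: {t_leaf}")
    c = get_constants(constants)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = replace(
            params_25,
            vcmax=_arrhenius(params_25.vcmax, c.ea_vcmax, t_leaf),
            jmax=_peaked_arrhenius(params_25.jmax, c.ea_jmax, c.dhd_jmax,
                                   c.ds_jmax, t_leaf),
            rd=_arrhenius(params_25.rd, c.ea_rd, t_leaf),
            kc=_arrhenius(params_25.kc, c.ea_kc, t_leaf),
            ko=_arrhenius(params_25.ko, c.ea_ko, t_leaf),
            gamma_star=_arrhenius(params_25.gamma_star, c.ea_gamma_star, t_leaf),
            t_leaf=t_leaf,
        )
    return out


def supply_intersection(
    ca_ref: float, gsw: float, params: FvCBParams
) -> dict:
    """Operating point where the CO2 supply line meets the FvCB demand curve.

    Supply: A = (Ca - Ci) * gc with gc = gsw / 1.6 (CO2 basis).  Returns
    ``{"ci", "a", "limitation_l", "degenerate"}`` where ``limitation_l``
    is the relative stomatal limitation (A(Ci=Ca) - A*) / A(Ci=Ca).
    """
    if gsw <= 0:
        raise ValueError("gsw must be positive")
    gc = gsw / 1.6

    def f(ci):
        return fvcb_assimilation(ci, params) - (ca_ref - ci) * gc

    lo, hi = params.gamma_star, ca_ref
    a_open = fvcb_assimilation(ca_ref, params)
    if f(lo) * f(hi) > 0:
        return {"ci": None, "a": None, "limitation_l": None, "degenerate": True}
    ci_star = brentq(f, lo, hi, xtol=1e-10)
    a_star = fvcb_assimilation(ci_star, params)
    lim = (a_open - a_star) / a_open if a_open > 0 else None
    return {"ci": float(ci_star), "a": float(a_star),
            "limitation_l": lim, "degenerate": False}
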