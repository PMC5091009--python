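"""Two-state equilibrium chemical denaturation by the linear extrapolation method.

The folded fraction at denaturant concentration D follows

    f_F(D) = 1 / (1 + exp(-(dG0 - m*D) / RT))

with dG0 the apparent unfolding free energy at zero denaturant (kcal/mol),
m the cooperativity (kcal/mol/M) and Cm = dG0/m the midpoint.  The observed
signal is a population-weighted sum of two sloping linear baselines:

    S(D) = (aN + bN*D) * f_F + (aU + bU*D) * (1 - f_F)

Folding and unfolding arms are fit separately, so hysteresis (non-coincident
arms, common in detergent-micelle refolding of beta-barrels) shows up as a
difference in midpoints rather than being averaged away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

from .io import R_KCAL, Arm, FitError, TitrationCurve, ValidationError

__all__ = ["EquilibriumFit", "fit_two_state_lem", "fraction_folded_profile",
           "hysteresis_report", "two_state_signal", "fraction_folded"]


@dataclass
class EquilibriumFit:
    """Result of a two-state linear-extrapolation fit of one titration arm."""

    dG0: float                       # kcal/mol
    m: float                         # kcal/mol/M
    Cm: float                        # M, = dG0/m
    baseline_native: tuple[float, float]
    baseline_unfolded: tuple[float, float]
    arm: Arm
    temperature: float               # K
    standard_errors: dict[str, float]
    residual_norm: float
    converged: bool
    n_points: int

    def __post_init__(self):
        if self.converged:
            if not self.m > 0:
                raise ValidationError("converged fit requires m > 0")
            if abs(self.Cm - self.dG0 / self.m) > 1e-6 * max(abs(self.Cm), 1.0):
                raise ValidationError("Cm must equal dG0/m")


def fraction_folded(D, dG0: float, m: float, temperature: float):
    """Two-state folded fraction at denaturant D (LEM free energy dG0 - m*D)."""
    rt = R_KCAL * temperature
    x = np.clip(-(dG0 - m * np.asarray(D, float)) / rt, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(x))


def two_state_signal(D, dG0, m, aN, bN, aU, bU, temperature):
    D = np.asarray(D, float)
    fF = fraction_folded(D, dG0, m, temperature)
    return (aN + bN * D) * fF + (aU + bU * D) * (1.0 - fF)


def _initial_guess(curve: TitrationCurve, temperature: float) -> dict[str, float]:
    """Baselines from the outer 15% of points by D; Cm from the steepest point
    of a lightly smoothed signal; m from the apparent transition width."""
    D, S = curve.denaturant, curve.signal
    n = len(D)
    k = max(2, int(round(0.15 * n)))
    aN = float(np.polyfit(D[:k], S[:k], 1)[1]) if k >= 2 else float(S[0])
    bN = float(np.polyfit(D[:k], S[:k], 1)[0]) if k >= 2 else 0.0
    aU = float(np.polyfit(D[-k:], S[-k:], 1)[1]) if k >= 2 else float(S[-1])
    bU = float(np.polyfit(D[-k:], S[-k:], 1)[0]) if k >= 2 else 0.0
    from .thermal import _midpoint_crossing
    Cm0 = _midpoint_crossing(D, S, (aN, bN), (aU, bU))
    # 10-90% transition width ~ ln(81)*RT/m
    width = max((D[-1] - D[0]) / 4.0, 1e-3)
    m0 = np.log(81.0) * R_KCAL * temperature / width
    return {"dG0": m0 * Cm0, "m": m0, "Cm": Cm0, "aN": aN, "bN": bN, "aU": aU, "bU": bU}


def fit_two_state_lem(curve: TitrationCurve, temperature: float = 298.15,
                      init: dict[str, float] | None = None,
                      float_baselines: bool = True,
                      parametrization: str = "dG0",
                      mask: np.ndarray | None = None) -> EquilibriumFit:
    """Fit one titration arm to the two-state LEM signal model.

    Parameters
    ----------
    curve : TitrationCurve with >= 6 points spanning baselines and transition.
    temperature : experiment temperature in K (default 298.15, i.e. 25 C).
    init : optional overrides for initial parameter values.
    float_baselines : fix baseline slopes/intercepts at their initial values
        when False (floated by default).
    parametrization : "dG0" fits (dG0, m); "Cm" fits (Cm, m) with dG0 = m*Cm.
        Both produce identical predicted curves.
    mask : optional boolean array; True points are excluded (e.g. aggregated
        low-denaturant points after long incubation).
    """
    D, S = curve.denaturant, curve.signal
    if mask is not None:
        keep = ~np.asarray(mask, bool)
        D, S = D[keep], S[keep]
    if D.size < 6:
        raise ValidationError("need >= 6 points for a two-state LEM fit")
    if np.ptp(S) == 0:
        raise FitError("no transition detectable: signal is constant")

    guess = _initial_guess(TitrationCurve(D, S, arm=curve.arm,
                                          signal_kind=curve.signal_kind), temperature)
    if init:
        guess.update(init)
        if "dG0" in init and "m" in init and "Cm" not in init:
            guess["Cm"] = init["dG0"] / init["m"]

    params = lmfit.Parameters()
    if parametrization == "dG0":
        params.add("dG0", value=guess["dG0"], min=1e-6)
        params.add("m", value=guess["m"], min=1e-6)
        params.add("Cm", expr="dG0/m")
    elif parametrization == "Cm":
        params.add("Cm", value=guess["Cm"], min=1e-6)
        params.add("m", value=guess["m"], min=1e-6)
        params.add("dG0", expr="m*Cm")
    else:
        raise ValueError(f"unknown parametrization {parametrization!r}")
    for name in ("aN", "bN", "aU", "bU"):
        params.add(name, value=guess[name], vary=float_baselines or name in ("aN", "aU"))
        if not float_baselines and name in ("bN", "bU"):
            params[name].vary = False

    def model(p):
        return two_state_signal(D, p["dG0"], p["m"], p["aN"], p["bN"],
                                p["aU"], p["bU"], temperature)

    resid = lambda p: model(p) - S
    result = lmfit.minimize(resid, params, method="leastsq")
    # polish with a 3-point-jacobian trust-region pass so the optimum is located
    # to ~1e-10 regardless of the parametrization used
    with warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        result = lmfit.minimize(resid, result.params, method="least_squares",
                                jac="3-point", ftol=1e-15, gtol=1e-15, xtol=None)
    p = result.params

    # transition amplitude at the fitted midpoint, vs residual scale
    Cm = float(p["Cm"].value)
    amp = abs((p["aN"].value + p["bN"].value * Cm) - (p["aU"].value + p["bU"].value * Cm))
    resid_scale = float(np.sqrt(np.mean(result.residual ** 2)))
    if amp < max(3.0 * resid_scale, 1e-12 * max(np.ptp(S), 1.0)):
        raise FitError(
            "no transition detectable: fitted transition amplitude is indistinguishable "
            "from the residual noise (monotone or flat signal)")

    converged = bool(result.success)
    m_val = float(p["m"].value)
    if m_val <= 2e-6:  # pinned at the positivity bound
        converged = False
        warnings.warn("m pinned at its lower bound; fit flagged non-converged")

    errs = {name: (float(p[name].stderr) if p[name].stderr is not None else float("nan"))
            for name in ("dG0", "m", "Cm", "aN", "bN", "aU", "bU")}
    return EquilibriumFit(
        dG0=float(p["dG0"].value), m=m_val, Cm=Cm,
        baseline_native=(float(p["aN"].value), float(p["bN"].value)),
        baseline_unfolded=(float(p["aU"].value), float(p["bU"].value)),
        arm=curve.arm, temperature=temperature, standard_errors=errs,
        residual_norm=float(np.linalg.norm(result.residual)),
        converged=converged, n_points=int(D.size))


def fraction_folded_profile(fit: EquilibriumFit, denaturant) -> np.ndarray:
    """Folded-fraction profile of a converged fit over a denaturant series.

    Monotone non-increasing in D and exactly 0.5 at D = Cm.
    """
    if not fit.converged:
        raise ValidationError("fit did not converge; no population profile available")
    D = np.asarray(denaturant, float)
    if np.any(D < 0):
        raise ValidationError("denaturant concentrations must be non-negative")
    return fraction_folded(D, fit.dG0, fit.m, fit.temperature)


def hysteresis_report(unfold: EquilibriumFit, fold: EquilibriumFit,
                      cm_threshold: float = 0.1) -> dict:
    """Signed folding-minus-unfolding differences of the two arms.

    Returns {dCm, ddG0, dm, hysteresis} where hysteresis is flagged when
    |dCm| exceeds ``cm_threshold`` (default 0.1 M).
    """
    if not (unfold.converged and fold.converged):
        raise ValidationError("both fits must have converged")
    if unfold.temperature != fold.temperature:
        raise ValidationError(
            f"temperature mismatch: {fold.temperature} K vs {unfold.temperature} K")
    d_cm = fold.Cm - unfold.Cm
    return {
        "dCm": d_cm,
        "ddG0": fold.dG0 - unfold.dG0,
        "dm": fold.m - unfold.m,
        "hysteresis": bool(abs(d_cm) > cm_threshold),
    }
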