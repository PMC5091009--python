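"""CD wavelength-scan summaries and two-state van't Hoff thermal melts.

Secondary-structure content of a folded beta-barrel is summarized as the mean
molar ellipticity over 214-216 nm (a beta-sheet band average that damps
point noise).  Thermal melts monitored at 215 nm are fit to a two-state
transition with the van't Hoff free energy

    dG(T) = dH_app * (1 - T/Tm)        (dCp fixed at 0)
    f_U(T) = 1 / (1 + exp(dG(T) / RT))

between sloping linear baselines.  Melting of these barrels is followed by
aggregation and is not reversible, so Tm and dH_app are apparent quantities;
dH_app doubles as a transition-width (cooperativity) readout.  The onset
temperature Tm_start is where f_U first reaches a small threshold (default
5% unfolded).
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.optimize import brentq

from .io import R_KCAL, FitError, MeltCurve, ValidationError, WavelengthScan

__all__ = ["ThermalFit", "SpectrumSummary", "mean_ellipticity_band",
           "fit_thermal_two_state", "tm_start", "fraction_unfolded_thermal"]


@dataclass
class SpectrumSummary:
    ME_214_216: float
    band: tuple[float, float]

    def __post_init__(self):
        if not self.band[0] < self.band[1]:
            raise ValidationError("band low must be < band high")


@dataclass
class ThermalFit:
    Tm: float                 # K
    dH_app: float             # kcal/mol
    Tm_start: float           # K
    baseline_folded: tuple[float, float]
    baseline_unfolded: tuple[float, float]
    fraction_threshold: float
    standard_errors: dict[str, float]
    residual_norm: float
    converged: bool
    n_points: int

    def __post_init__(self):
        if self.converged:
            if not self.Tm_start < self.Tm:
                raise ValidationError("Tm_start must lie below Tm")
            if not self.dH_app > 0:
                raise ValidationError("dH_app must be positive for an unfolding transition")


def mean_ellipticity_band(scan: WavelengthScan,
                          band: tuple[float, float] = (214.0, 216.0)) -> SpectrumSummary:
    """Arithmetic mean of molar ellipticity over a closed wavelength band."""
    low, high = band
    if not low < high:
        raise ValidationError("band low must be < band high")
    inside = (scan.wavelength >= low) & (scan.wavelength <= high)
    if not np.any(inside):
        raise ValidationError(f"scan has no points inside the {low}-{high} nm band")
    return SpectrumSummary(ME_214_216=float(np.mean(scan.ellipticity[inside])), band=band)


def fraction_unfolded_thermal(T, Tm: float, dH_app: float):
    """van't Hoff unfolded fraction with dCp = 0 (0.5 exactly at T = Tm)."""
    T = np.asarray(T, float)
    dG = dH_app * (1.0 - T / Tm)
    x = np.clip(dG / (R_KCAL * T), -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(x))


def _midpoint_crossing(x: np.ndarray, y: np.ndarray,
                       base_lo: tuple[float, float],
                       base_hi: tuple[float, float]) -> float:
    """Initial transition-midpoint guess: where the baseline-normalized signal
    crosses 1/2.  Robust to noise and sampling density (unlike a local
    derivative maximum)."""
    lo = base_lo[0] + base_lo[1] * x
    hi = base_hi[0] + base_hi[1] * x
    denom = hi - lo
    denom = np.where(np.abs(denom) < 1e-30, 1e-30, denom)
    frac = (y - lo) / denom
    win = max(3, x.size // 25) | 1
    frac = np.convolve(frac, np.ones(win) / win, mode="same")
    idx = int(np.argmin(np.abs(frac - 0.5)))
    idx = min(max(idx, 1), x.size - 2)
    return float(x[idx])


def _melt_signal(T, Tm, dH, aF, bF, aU, bU):
    fU = fraction_unfolded_thermal(T, Tm, dH)
    return (aF + bF * T) * (1.0 - fU) + (aU + bU * T) * fU


def fit_thermal_two_state(melt: MeltCurve, onset_threshold: float = 0.05) -> ThermalFit:
    """Fit a 215-nm melt to the two-state van't Hoff model with linear baselines."""
    T, S = melt.temperature, melt.ellipticity
    if melt.span < 30.0:
        raise ValidationError("melt must span >= 30 K for fitting")
    if np.ptp(S) == 0:
        raise FitError("no sigmoidal transition: ellipticity is constant")

    k = max(2, int(round(0.15 * T.size)))
    aF, bF = np.polyfit(T[:k], S[:k], 1)[::-1]
    aU, bU = np.polyfit(T[-k:], S[-k:], 1)[::-1]
    Tm0 = _midpoint_crossing(T, S, (aF, bF), (aU, bU))

    params = lmfit.Parameters()
    params.add("Tm", value=Tm0, min=T[0], max=T[-1] + 50.0)
    params.add("dH", value=50.0, min=1e-3)
    for name, val in (("aF", aF), ("bF", bF), ("aU", aU), ("bU", bU)):
        params.add(name, value=val)

    def resid(p):
        return _melt_signal(T, p["Tm"], p["dH"], p["aF"], p["bF"], p["aU"], p["bU"]) - S

    result = lmfit.minimize(resid, params, method="leastsq")
    p = result.params
    Tm = float(p["Tm"].value)
    amp = abs((p["aF"].value + p["bF"].value * Tm) - (p["aU"].value + p["bU"].value * Tm))
    resid_scale = float(np.sqrt(np.mean(result.residual ** 2)))
    if amp < max(3.0 * resid_scale, 1e-12 * np.ptp(S)):
        raise FitError("no sigmoidal transition detected in the melt")

    errs = {name: (float(p[name].stderr) if p[name].stderr is not None else float("nan"))
            for name in ("Tm", "dH", "aF", "bF", "aU", "bU")}
    dH = float(p["dH"].value)
    return ThermalFit(
        Tm=Tm, dH_app=dH, Tm_start=_onset_temperature(Tm, dH, onset_threshold),
        baseline_folded=(float(p["aF"].value), float(p["bF"].value)),
        baseline_unfolded=(float(p["aU"].value), float(p["bU"].value)),
        fraction_threshold=onset_threshold, standard_errors=errs,
        residual_norm=float(np.linalg.norm(result.residual)),
        converged=bool(result.success), n_points=int(T.size))


def _onset_temperature(Tm: float, dH: float, threshold: float) -> float:
    if not 0.0 < threshold <= 0.5:
        raise ValidationError("onset threshold must lie in (0, 0.5]")
    if threshold == 0.5:
        return Tm

    def f(T):
        return fraction_unfolded_thermal(T, Tm, dH) - threshold

    lo = Tm / 10.0
    while f(lo) > 0:  # pragma: no cover - pathological tiny dH
        lo /= 2.0
        if lo < 1.0:
            raise FitError("cannot bracket the onset temperature")
    return float(brentq(f, lo, Tm, xtol=1e-3))


def tm_start(fit: ThermalFit, threshold: float = 0.05) -> float:
    """Temperature at which the fitted unfolded fraction reaches ``threshold``.

    Solved numerically (bisection via brentq to 1e-3 K); ``threshold`` = 0.5
    returns Tm by the midpoint definition.  Valid thresholds lie in (0, 0.5].
    """
    return _onset_temperature(fit.Tm, fit.dH_app, threshold)
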