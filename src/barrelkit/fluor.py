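"""Fluorescence-probe analyses: inner-filter correction, Stern-Volmer
quenching, and TCSPC lifetime fitting.

Steady-state intensities are corrected for absorbance at the excitation and
emission wavelengths with F_corr = F_obs * 10^((A_ex + A_em)/2).  Dynamic
quenching of an accessible tryptophan follows the Stern-Volmer law
F0/F = 1 + K_SV [Q] (identically tau0/tau for purely dynamic quenching), so
K_SV reports quencher accessibility of the indole.  TCSPC decays are fit on
their tail to background + sum_i alpha_i exp(-t / tau_i) (up to three
components, Poisson-weighted); the average lifetime is reported either
amplitude-weighted, sum(a t)/sum(a), or intensity-weighted,
sum(a t^2)/sum(a t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .io import FitError, PhotonDecay, QuenchSeries, ResponseKind, ValidationError

__all__ = ["QuenchFit", "LifetimeFit", "inner_filter_correct", "stern_volmer",
           "fit_decay_multiexp", "avg_lifetime"]


@dataclass
class QuenchFit:
    K_SV: float               # M^-1
    intercept: float          # dimensionless, expected ~1
    mode: ResponseKind
    standard_errors: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")
    n_points: int = 0


@dataclass
class LifetimeFit:
    """Multi-exponential TCSPC fit; components sorted by ascending lifetime."""

    components: list[tuple[float, float]]   # (amplitude alpha_i, lifetime tau_i ns)
    background: float
    avg_tau: float                          # ns, amplitude-weighted by default
    tail_start: float
    standard_errors: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")
    converged: bool = True
    n_points: int = 0

    def __post_init__(self):
        self.components = sorted(self.components, key=lambda c: c[1])
        if any(tau <= 0 for _, tau in self.components):
            raise ValidationError("lifetimes must be positive")
        if not sum(a for a, _ in self.components) > 0:
            raise ValidationError("total amplitude must be positive")


def inner_filter_correct(F_obs, A_ex, A_em):
    """Inner-filter corrected intensity F_obs * 10^((A_ex + A_em)/2)."""
    A_ex = np.asarray(A_ex, float)
    A_em = np.asarray(A_em, float)
    if np.any(A_ex < 0) or np.any(A_em < 0):
        raise ValidationError("absorbances must be non-negative")
    return np.asarray(F_obs, float) * 10.0 ** ((A_ex + A_em) / 2.0)


def stern_volmer(series: QuenchSeries) -> QuenchFit:
    """Linear Stern-Volmer fit of F0/F (or tau0/tau) against quencher.

    Inner-filter correction is applied first when both absorbance series are
    present (steady-state mode).  The slope is K_SV; a negative slope only
    warns (static shielding or anomalous photophysics).
    """
    if series.quencher.size < 4:
        raise ValidationError("need >= 4 quencher concentrations")
    response = series.response
    if (series.response_kind == ResponseKind.STEADY_STATE
            and series.absorbance_ex is not None and series.absorbance_em is not None):
        response = inner_filter_correct(response, series.absorbance_ex, series.absorbance_em)
    zero = series.quencher == 0
    F0 = float(np.mean(response[zero]))
    ratio = F0 / response
    X = np.column_stack([np.ones_like(series.quencher), series.quencher])
    b, _, _, _ = np.linalg.lstsq(X, ratio, rcond=None)
    resid = ratio - X @ b
    dof = max(ratio.size - 2, 1)
    cov = (float(resid @ resid) / dof) * np.linalg.inv(X.T @ X)
    if b[1] < 0:
        warnings.warn("negative Stern-Volmer slope: static shielding or anomaly")
    return QuenchFit(K_SV=float(b[1]), intercept=float(b[0]),
                     mode=series.response_kind,
                     standard_errors={"intercept": float(np.sqrt(cov[0, 0])),
                                      "K_SV": float(np.sqrt(cov[1, 1]))},
                     residual_norm=float(np.linalg.norm(resid)),
                     n_points=int(ratio.size))


def fit_decay_multiexp(decay: PhotonDecay, n_components: int = 3,
                       tail_start: float | None = None) -> LifetimeFit:
    """Tail-fit a TCSPC histogram to background + sum alpha_i exp(-t/tau_i).

    ``tail_start`` defaults to the time of peak counts + 0.2 ns (no IRF
    deconvolution is attempted).  Residuals are Poisson-weighted by
    1/sqrt(max(counts, 1)).  Components with lifetime ratio < 1.5 trigger a
    degeneracy warning.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    t, c = decay.time, decay.counts
    if tail_start is None:
        tail_start = float(t[np.argmax(c)]) + 0.2
    sel = t >= tail_start
    if sel.sum() < 10 * n_components:
        raise ValidationError(
            f"decay tail (t >= {tail_start:g} ns) has {int(sel.sum())} points; "
            f">= {10 * n_components} required")
    tt, cc = t[sel], c[sel]
    t0 = tt[0]
    peak = float(cc[0])
    span = tt[-1] - t0

    params = lmfit.Parameters()
    params.add("bg", value=float(np.mean(cc[-max(3, cc.size // 20):])), min=0.0)
    # spread initial lifetimes logarithmically across the tail span
    taus0 = np.geomspace(span / 30.0, span / 2.0, n_components)
    for i, tau0 in enumerate(taus0, start=1):
        params.add(f"tau{i}", value=float(tau0), min=1e-4)
        params.add(f"a{i}", value=peak / n_components, min=0.0)

    w = 1.0 / np.sqrt(np.maximum(cc, 1.0))

    def resid(p):
        model = np.full_like(tt, float(p["bg"]))
        for i in range(1, n_components + 1):
            model = model + p[f"a{i}"] * np.exp(-(tt - t0) / p[f"tau{i}"])
        return (model - cc) * w

    result = lmfit.minimize(resid, params, method="leastsq")
    p = result.params
    comps = []
    for i in range(1, n_components + 1):
        tau = float(p[f"tau{i}"].value)
        # report amplitude at t = 0 (extrapolated back through the tail offset)
        a = float(p[f"a{i}"].value) * float(np.exp(t0 / tau))
        comps.append((a, tau))
    taus = sorted(tau for _, tau in comps)
    for lo, hi in zip(taus, taus[1:]):
        if hi / lo < 1.5:
            warnings.warn("lifetime components nearly collapsed (ratio < 1.5)")
            break
    errs = {name: (float(p[name].stderr) if p[name].stderr is not None else float("nan"))
            for name in p}
    fit = LifetimeFit(components=comps, background=float(p["bg"].value),
                      avg_tau=float("nan"), tail_start=float(tail_start),
                      standard_errors=errs,
                      residual_norm=float(np.linalg.norm(result.residual)),
                      converged=bool(result.success), n_points=int(cc.size))
    fit.avg_tau = avg_lifetime(fit, "amplitude")
    return fit


def avg_lifetime(fit: LifetimeFit, weighting: str = "amplitude") -> float:
    """Average lifetime <tau> of a multi-exponential fit.

    amplitude weighting: sum(a_i tau_i) / sum(a_i);
    intensity weighting: sum(a_i tau_i^2) / sum(a_i tau_i).
    """
    a = np.array([c[0] for c in fit.components])
    tau = np.array([c[1] for c in fit.components])
    if not np.sum(a) > 0:
        raise ValidationError("all amplitudes are zero")
    if weighting == "amplitude":
        return float(np.sum(a * tau) / np.sum(a))
    if weighting == "intensity":
        return float(np.sum(a * tau ** 2) / np.sum(a * tau))
    raise ValueError(f"unknown weighting {weighting!r}")
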