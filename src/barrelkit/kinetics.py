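"""Folding/unfolding kinetics: trace normalization, exponential fits, chevrons.

Anisotropy traces are normalized to folded fraction with

    f_F = (r - r_U) / (r_F - r_U)

and kinetic traces are fit to offset + sum_i A_i exp(-k_i t).  Observed rates
against denaturant concentration D form the chevron plot, whose linear zones
obey

    ln k_f = ln k_f^H2O + m_F_kin * D / (R T)
    ln k_u = ln k_u^H2O + m_U_kin * D / (R T)   [+ m_U1_kin * D^2]

with R in kcal/(mol K), kinetic m-values in kcal/mol/M (m_F_kin < 0,
m_U_kin > 0 for a canonical chevron), and an optional quadratic term
(units M^-2, deliberately outside the RT scaling) absorbing unfolding-arm
rollover.  From the intercepts and slopes:

    dG0_kin = -R T ln(k_f^H2O / k_u^H2O)
    beta_T  = -m_F_kin / (m_U_kin - m_F_kin)

beta_T positions the transition state between unfolded (0) and folded (1)
in denaturant-sensitivity terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.stats import f as f_dist

from .io import R_KCAL, Arm, FitError, KineticTrace, SignalKind, ValidationError

__all__ = ["AnisotropyEndpoints", "ExponentialFit", "ChevronDataset", "ChevronFit",
           "normalize_anisotropy", "fit_exponential", "compare_exponential_models",
           "assemble_chevron", "fit_chevron", "dg_kin", "tanford_beta",
           "chevron_minimum"]


@dataclass(frozen=True)
class AnisotropyEndpoints:
    """Folded- and unfolded-state anisotropy limits used for normalization."""

    r_F: float
    r_U: float

    def __post_init__(self):
        if self.r_F == self.r_U:
            raise ValidationError("r_F and r_U must differ to normalize")


@dataclass
class ExponentialFit:
    """Multi-exponential fit; phases sorted fast -> slow (descending rate)."""

    phases: list[tuple[float, float]]       # (rate s^-1, amplitude)
    offset: float
    n_phases: int
    standard_errors: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")
    converged: bool = True
    n_points: int = 0

    def __post_init__(self):
        self.phases = sorted(self.phases, key=lambda ph: -ph[0])
        if any(k <= 0 for k, _ in self.phases):
            raise ValidationError("all rates must be positive")

    @property
    def rates(self) -> list[float]:
        return [k for k, _ in self.phases]

    def dominant_rate(self, rule: str = "dominant_amplitude") -> float:
        if rule == "dominant_amplitude":
            return max(self.phases, key=lambda ph: abs(ph[1]))[0]
        if rule == "fastest":
            return self.phases[0][0]
        if rule == "slowest":
            return self.phases[-1][0]
        raise ValueError(f"unknown phase rule {rule!r}")


@dataclass
class ChevronDataset:
    """Observed rates vs denaturant for both arms; provenance in phase_index."""

    points: list[tuple[float, float, int, Arm]]  # (D, rate, phase_index, arm)

    def __post_init__(self):
        if any(rate <= 0 for _, rate, _, _ in self.points):
            raise ValidationError("all rates must be positive")
        self.points = [(float(d), float(r), int(i), Arm(a)) for d, r, i, a in self.points]

    def arm(self, arm: Arm) -> tuple[np.ndarray, np.ndarray]:
        sel = [(d, r) for d, r, _, a in self.points if a == Arm(arm)]
        if not sel:
            raise ValidationError(f"no points in the {Arm(arm).value} arm")
        d, r = zip(*sel)
        return np.asarray(d), np.asarray(r)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ChevronFit:
    ln_kf_H2O: float
    ln_ku_H2O: float
    mF_kin: float                 # kcal/mol/M, < 0 canonical
    mU_kin: float                 # kcal/mol/M, > 0 canonical
    mU1_kin: float                # M^-2, 0 for linear model
    dG0_kin: float                # kcal/mol, = -RT ln(kf/ku), sign as printed
    beta_T: float
    temperature: float
    model: str                    # "linear" | "quadratic_unfolding"
    standard_errors: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")
    sign_convention: str = ("dG0_kin = -RT*ln(kf_H2O/ku_H2O); negative when "
                            "folding is faster than unfolding")


# --- trace handling --------------------------------------------------------

def normalize_anisotropy(trace: KineticTrace, endpoints: AnisotropyEndpoints) -> KineticTrace:
    """Convert an anisotropy trace to folded fraction, pointwise.

    Noise can push values transiently outside [0, 1]; they are not clipped.
    """
    if trace.signal_kind != SignalKind.ANISOTROPY:
        raise ValidationError("normalize_anisotropy requires an anisotropy trace")
    fF = (trace.signal - endpoints.r_U) / (endpoints.r_F - endpoints.r_U)
    return KineticTrace(time=trace.time, signal=fF,
                        signal_kind=SignalKind.ANISOTROPY,
                        dead_time=trace.dead_time, denaturant=trace.denaturant)


def fit_exponential(trace: KineticTrace, n_phases: int = 1) -> ExponentialFit:
    """Least-squares fit of offset + sum A_i exp(-k_i t).

    Phases are returned fast -> slow with standard errors.  A span shorter
    than ~3/k for the slowest fitted phase triggers a warning; two phases
    with rate ratio < 2 trigger a degeneracy warning.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = trace.time, trace.signal
    if t.size < 10:
        raise ValidationError("need >= 10 points for an exponential fit")

    if np.ptp(y) == 0:
        warnings.warn("constant trace: zero-amplitude degenerate fit")
        k0 = 1.0 / max(t[-1] - t[0], 1.0)
        phases = [(k0 * (2.0 ** i), 0.0) for i in range(n_phases)]
        return ExponentialFit(phases=phases, offset=float(y[0]), n_phases=n_phases,
                              converged=True, residual_norm=0.0, n_points=int(t.size))

    span = t[-1] - t[0]
    amp0 = y[0] - y[-1]
    params = lmfit.Parameters()
    params.add("offset", value=float(y[-1]))
    if n_phases == 1:
        params.add("k1", value=3.0 / span, min=1e-12)
        params.add("A1", value=float(amp0))
    else:
        params.add("k1", value=10.0 / span, min=1e-12)
        params.add("k2", value=1.0 / span, min=1e-12)
        params.add("A1", value=float(amp0) / 2.0)
        params.add("A2", value=float(amp0) / 2.0)

    def resid(p):
        model = np.full_like(t, float(p["offset"]))
        for i in range(1, n_phases + 1):
            model = model + p[f"A{i}"] * np.exp(-p[f"k{i}"] * (t - t[0]))
        return model - y

    result = lmfit.minimize(resid, params, method="leastsq")
    p = result.params
    # amplitudes are reported at t = 0 (extrapolated through any dead time)
    phases = []
    for i in range(1, n_phases + 1):
        k = float(p[f"k{i}"].value)
        A = float(p[f"A{i}"].value) * float(np.exp(k * t[0]))
        phases.append((k, A))

    rates = sorted(k for k, _ in phases)
    if rates[0] * span < 3.0:
        warnings.warn("trace span is < 3/k for the slowest phase; rate poorly constrained")
    if n_phases == 2 and rates[1] / rates[0] < 2.0:
        warnings.warn("two-phase fit is degenerate: rate ratio < 2")

    errs = {}
    for name in p:
        errs[name] = float(p[name].stderr) if p[name].stderr is not None else float("nan")
    return ExponentialFit(phases=phases, offset=float(p["offset"].value),
                          n_phases=n_phases, standard_errors=errs,
                          residual_norm=float(np.linalg.norm(result.residual)),
                          converged=bool(result.success), n_points=int(t.size))


def compare_exponential_models(trace: KineticTrace, alpha: float = 0.01
                               ) -> tuple[int, float]:
    """F-test comparison of single vs double exponential fits.

    Returns (chosen n_phases, p-value of the extra-parameters F-test); the
    double-exponential model is chosen when p < alpha.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit1 = fit_exponential(trace, 1)
        fit2 = fit_exponential(trace, 2)
    rss1, rss2 = fit1.residual_norm ** 2, fit2.residual_norm ** 2
    n = len(trace)
    df1, df2 = 2, n - 5
    if rss2 <= 0 or df2 <= 0:
        return 2, 0.0
    F = ((rss1 - rss2) / df1) / (rss2 / df2)
    pval = float(f_dist.sf(max(F, 0.0), df1, df2))
    return (2 if pval < alpha else 1), pval


# --- chevron assembly and fitting -----------------------------------------

def assemble_chevron(fits: list[tuple[float, ExponentialFit, Arm]],
                     phase_rule: str = "dominant_amplitude") -> ChevronDataset:
    """Select one observed rate per (D, arm) according to ``phase_rule``.

    phase_rule is one of dominant_amplitude (default), fastest, slowest.
    Duplicate denaturant values within an arm are retained and flagged with
    a warning.
    """
    by_arm: dict[Arm, list[float]] = {}
    points = []
    for D, fit, arm in fits:
        arm = Arm(arm)
        rate = fit.dominant_rate(phase_rule)
        phase_index = fit.rates.index(rate)
        points.append((float(D), rate, phase_index, arm))
        by_arm.setdefault(arm, []).append(float(D))
    for arm, ds in by_arm.items():
        if len(ds) < 3:
            raise ValidationError(f"{arm.value} arm needs >= 3 points, got {len(ds)}")
        if len(set(ds)) != len(ds):
            warnings.warn(f"duplicate denaturant values in the {arm.value} arm; all retained")
    if not by_arm:
        raise ValidationError("no fits supplied")
    return ChevronDataset(points=points)


def _window(D: np.ndarray, rates: np.ndarray, window: tuple[float, float],
            arm_name: str) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    sel = (D >= lo) & (D <= hi)
    if sel.sum() < 3:
        raise ValidationError(
            f"{arm_name} window [{lo}, {hi}] M contains {int(sel.sum())} points; >= 3 required")
    return D[sel], rates[sel]


def _linfit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Unweighted least squares y = X b; returns (b, stderr(b), residual norm)."""
    b, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ b
    resid = y - fitted
    dof = max(y.size - X.shape[1], 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    return b, np.sqrt(np.diag(cov)), float(np.linalg.norm(resid))


def fit_chevron(dataset: ChevronDataset, temperature: float = 298.15,
                folding_window: tuple[float, float] = (0.8, 1.68),
                unfolding_window: tuple[float, float] = (1.72, 3.0),
                model: str = "linear") -> ChevronFit:
    """Fit the chevron's linear zones in ln-rate space.

    Default windows match typical acquisition ranges for GdnHCl refolding
    (folding 0.8-1.68 M by manual mixing, unfolding 1.72-3.0 M by stopped
    flow); both are configurable.  ``model`` is "linear" or
    "quadratic_unfolding" (adds the m_U1_kin * D^2 rollover term to the
    unfolding arm only).
    """
    if model not in ("linear", "quadratic_unfolding"):
        raise ValueError(f"unknown chevron model {model!r}")
    rt = R_KCAL * temperature

    Df, kf = _window(*dataset.arm(Arm.FOLDING), folding_window, "folding")
    Du, ku = _window(*dataset.arm(Arm.UNFOLDING), unfolding_window, "unfolding")

    Xf = np.column_stack([np.ones_like(Df), Df])
    bf, ef, rn_f = _linfit(Xf, np.log(kf))
    ln_kf0, mF = float(bf[0]), float(bf[1]) * rt
    if mF > 0:
        warnings.warn("non-canonical chevron: folding arm has a positive slope")

    if model == "linear":
        Xu = np.column_stack([np.ones_like(Du), Du])
        bu, eu, rn_u = _linfit(Xu, np.log(ku))
        ln_ku0, mU, mU1 = float(bu[0]), float(bu[1]) * rt, 0.0
        eu = np.append(eu, 0.0)
    else:
        Xu = np.column_stack([np.ones_like(Du), Du, Du ** 2])
        bu, eu, rn_u = _linfit(Xu, np.log(ku))
        ln_ku0, mU, mU1 = float(bu[0]), float(bu[1]) * rt, float(bu[2])

    errs = {
        "ln_kf_H2O": float(ef[0]), "mF_kin": float(ef[1]) * rt,
        "ln_ku_H2O": float(eu[0]), "mU_kin": float(eu[1]) * rt,
        "mU1_kin": float(eu[2]) if model != "linear" else 0.0,
    }
    fit = ChevronFit(
        ln_kf_H2O=ln_kf0, ln_ku_H2O=ln_ku0, mF_kin=mF, mU_kin=mU, mU1_kin=mU1,
        dG0_kin=float("nan"), beta_T=float("nan"),
        temperature=temperature, model=model, standard_errors=errs,
        residual_norm=float(np.hypot(rn_f, rn_u)))
    fit.dG0_kin = dg_kin(fit)
    fit.beta_T = tanford_beta(fit)
    return fit


def dg_kin(fit: ChevronFit) -> float:
    """Kinetic free energy dG0_kin = -RT ln(kf_H2O / ku_H2O), kcal/mol.

    Computed verbatim from the fitted intercepts: negative when folding in
    water is faster than unfolding (sign convention recorded on the fit).
    """
    if not (np.isfinite(fit.ln_kf_H2O) and np.isfinite(fit.ln_ku_H2O)):
        raise ValidationError("non-finite rate intercepts")
    return -R_KCAL * fit.temperature * (fit.ln_kf_H2O - fit.ln_ku_H2O)


def tanford_beta(fit: ChevronFit) -> float:
    """Tanford beta_T = -mF_kin / (mU_kin - mF_kin); in (0, 1) for canonical arms."""
    if fit.mU_kin == fit.mF_kin:
        raise ZeroDivisionError("mU_kin equals mF_kin; beta_T undefined")
    return -fit.mF_kin / (fit.mU_kin - fit.mF_kin)


def chevron_minimum(fit: ChevronFit) -> float:
    """Denaturant concentration where the linear arms intersect (chevron minimum)."""
    rt = R_KCAL * fit.temperature
    return -rt * (fit.ln_kf_H2O - fit.ln_ku_H2O) / (fit.mF_kin - fit.mU_kin)
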