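"""Voltage-gating energetics of a channel in a planar bilayer.

A multichannel membrane subjected to a triangular voltage ramp yields
conductance vs voltage; normalizing by the maximal (open-state) conductance
near 0 mV gives G/G_max per voltage branch.  Each branch is fit to a
two-state Boltzmann closure

    G/G_max(V) = g_min + (1 - g_min) / (1 + exp(n F (|V| - V0) / (R T)))

where n is the effective gating charge, V0 the half-closure voltage (mV,
branch sign retained), g_min the residual closed-state conductance fraction,
and F = 96485 C/mol.  The open-closed energy gap is

    n F V0  ->  n * 96485 * |V0 mV| / 1e6   kJ/mol.

Single-channel insertion steps at low holding voltage populate two
conductance classes (a ~4 nS open state and a ~2 nS subconductance state),
separated here with a deterministic two-component Gaussian mixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np

from .io import FARADAY, R_J, FitError, GatingRamp, InsertionEvents, ValidationError

__all__ = ["GatingFit", "GatingEnergy", "ConductanceClasses",
           "normalize_ramp", "fit_boltzmann", "gating_energy", "classify_insertions",
           "boltzmann_gg"]


@dataclass
class GatingFit:
    n: float                   # effective gating charge
    V0: float                  # mV, sign of branch retained
    branch: str                # "positive" | "negative"
    G_max: float | None        # nS, None when fit on pre-normalized data
    G_min_frac: float
    standard_errors: dict[str, float]
    residual_norm: float
    converged: bool
    n_points: int

    def __post_init__(self):
        if self.converged:
            if not self.n > 0:
                raise ValidationError("gating charge n must be positive")
            if not abs(self.V0) > 0:
                raise ValidationError("V0 must be non-zero")
            if not 0.0 <= self.G_min_frac < 1.0:
                raise ValidationError("G_min_frac must lie in [0, 1)")


@dataclass(frozen=True)
class GatingEnergy:
    nFV0: float  # kJ/mol, uses |V0|

    def __post_init__(self):
        if self.nFV0 < 0:
            raise ValidationError("nFV0 must be non-negative")


@dataclass
class ConductanceClasses:
    means: tuple[float, float]      # (low nS, high nS)
    sds: tuple[float, float]
    assignments: np.ndarray         # 0 = low class, 1 = high class
    counts: tuple[int, int]

    def __post_init__(self):
        if not self.means[0] < self.means[1]:
            raise ValidationError("class means must be ordered low < high")
        if sum(self.counts) != len(self.assignments):
            raise ValidationError("class counts must sum to the event count")


def normalize_ramp(ramp: GatingRamp,
                   reference_window: tuple[float, float] = (-10.0, 10.0)
                   ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-branch G/G_max from a two-sided voltage ramp.

    G_max is the mean conductance inside the (closed) reference window around
    0 mV, where the channels sit fully open.  Returns
    ``{"positive": (V, G/G_max), "negative": (V, G/G_max)}``.
    """
    V, G = ramp.voltage, ramp.conductance
    lo, hi = reference_window
    ref = (V >= lo) & (V <= hi)
    if not np.any(ref):
        raise ValidationError(f"no ramp points inside the reference window [{lo}, {hi}] mV")
    for branch, sel in (("positive", V > 0), ("negative", V < 0)):
        if not np.any(sel):
            raise ValidationError(f"ramp has no {branch}-voltage branch")
    g_max = float(np.mean(G[ref]))
    if g_max <= 0:
        raise ValidationError("reference-window conductance must be positive")
    out = {}
    for branch, sel in (("positive", V > 0), ("negative", V < 0)):
        order = np.argsort(V[sel])
        out[branch] = (V[sel][order], (G[sel] / g_max)[order])
    out["G_max"] = g_max
    return out


def boltzmann_gg(V, n, V0, g_min, temperature=298.15):
    """Two-state Boltzmann G/G_max; V and V0 in mV (absolute values used)."""
    V = np.asarray(V, float)
    x = n * FARADAY * (np.abs(V) - abs(V0)) * 1e-3 / (R_J * temperature)
    return g_min + (1.0 - g_min) / (1.0 + np.exp(np.clip(x, -700.0, 700.0)))


def fit_boltzmann(branch_curve: tuple[np.ndarray, np.ndarray],
                  temperature: float = 298.15) -> GatingFit:
    """Fit one branch's (V mV, G/G_max) series to the Boltzmann closure model."""
    V, g = (np.asarray(a, float) for a in branch_curve)
    if V.size < 8:
        raise ValidationError("need >= 8 points spanning the transition")
    if np.ptp(g) < 1e-9:
        raise FitError("no voltage dependence: G/G_max is flat")

    branch = "positive" if np.mean(V) > 0 else "negative"
    g_min0 = max(float(np.min(g)), 0.0)
    # half-closure voltage guess: |V| where g crosses midway between 1 and g_min
    half = (1.0 + g_min0) / 2.0
    absV = np.abs(V)
    order = np.argsort(absV)
    V0_0 = float(np.interp(-half, -g[order], absV[order]))
    V0_0 = min(max(V0_0, absV.min() + 1e-3), absV.max())

    params = lmfit.Parameters()
    params.add("n", value=2.5, min=1e-3)
    params.add("V0", value=V0_0, min=1e-3)
    params.add("g_min", value=min(g_min0, 0.98), min=0.0, max=0.999)

    def resid(p):
        return boltzmann_gg(V, p["n"], p["V0"], p["g_min"], temperature) - g

    result = lmfit.minimize(resid, params, method="leastsq")
    p = result.params
    if 1.0 - float(p["g_min"].value) < 1e-3:
        raise FitError("no closure detected: residual fraction g_min ~ 1")
    errs = {name: (float(p[name].stderr) if p[name].stderr is not None else float("nan"))
            for name in ("n", "V0", "g_min")}
    V0 = float(p["V0"].value)
    return GatingFit(
        n=float(p["n"].value), V0=V0 if branch == "positive" else -V0,
        branch=branch, G_max=None, G_min_frac=float(p["g_min"].value),
        standard_errors=errs, residual_norm=float(np.linalg.norm(result.residual)),
        converged=bool(result.success), n_points=int(V.size))


def gating_energy(n: float, V0: float) -> GatingEnergy:
    """Open-closed energy gap nFV0 = n * 96485 * |V0| / 1e6 kJ/mol (V0 in mV)."""
    if not n > 0:
        raise ValidationError("gating charge n must be positive")
    return GatingEnergy(nFV0=n * FARADAY * abs(V0) * 1e-6)


def classify_insertions(events: InsertionEvents, k: int = 2,
                        seed: int = 0) -> ConductanceClasses:
    """Split insertion conductance steps into open/subconductance classes.

    A two-component 1-D Gaussian mixture fit by EM, initialized
    deterministically from the 25%/75% quantiles of the events, so repeated
    runs classify identically.
    """
    if k != 2:
        raise ValueError("only k = 2 conductance classes are supported")
    x = events.steps
    if x.size < 4:
        raise ValidationError("need >= 4 insertion events")
    if np.ptp(x) == 0:
        raise FitError("degenerate mixture: all insertion events identical")

    from sklearn.mixture import GaussianMixture

    means_init = np.quantile(x, [0.25, 0.75]).reshape(-1, 1)
    var0 = max(float(np.var(x)) / 4.0, 1e-4)
    gmm = GaussianMixture(n_components=2, covariance_type="full", n_init=1,
                          means_init=means_init,
                          weights_init=np.array([0.5, 0.5]),
                          precisions_init=np.full((2, 1, 1), 1.0 / var0),
                          random_state=seed, reg_covar=1e-6)
    labels = gmm.fit_predict(x.reshape(-1, 1))
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    order = np.argsort(means)
    remap = np.empty(2, dtype=int)
    remap[order] = [0, 1]
    labels = remap[labels]
    means, sds = means[order], sds[order]
    counts = (int(np.sum(labels == 0)), int(np.sum(labels == 1)))
    return ConductanceClasses(means=(float(means[0]), float(means[1])),
                              sds=(float(sds[0]), float(sds[1])),
                              assignments=labels, counts=counts)
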