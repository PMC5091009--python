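"""Seeded forward simulators with known ground truth for every pipeline stage.

Each generator simulates exactly the model its stage fits, so every fit in
the package is testable by parameter recovery (generate at zero noise ->
fit -> recover truth to solver tolerance).  Defaults sit in the regimes
typical of a beta-barrel refolded in DDM micelles: chemical midpoints in the
1.5-2.5 M GdnHCl transition zone, half-closure voltages of 20-29 mV with
gating charges of 2-3, insertion conductances near 2.4 and 4 nS, tryptophan
lifetimes averaging 2-3 ns, and a ~110 A cubic box holding one protein in
an 80-molecule detergent micelle.

Noise is ``magnitude * unit_draw`` with the unit draw fixed by the seed, so
at constant seed the realized noise scales linearly with magnitude (fitted
standard errors then grow monotonically with magnitude by construction).
Anisotropy kinetic traces discard the first 25 s, mirroring the mixing dead
time of a manual-mixing fluorimeter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibrium import two_state_signal
from .gating import boltzmann_gg
from .io import (Arm, GatingRamp, InsertionEvents, KineticTrace, MeltCurve,
                 PhotonDecay, QuenchSeries, SignalKind, TitrationCurve,
                 TrajectoryEnsemble, ValidationError)
from .kinetics import ChevronDataset
from .thermal import _melt_signal

__all__ = ["GeneratorSpec", "generate", "generate_micelle_system", "STAGE_DEFAULTS"]

ANISOTROPY_DEAD_TIME_S = 25.0

STAGE_DEFAULTS: dict[str, dict] = {
    "equilibrium": dict(dG0=6.4, m=3.2, aN=1.0, bN=-0.02, aU=0.15, bU=0.01,
                        temperature=298.15, D_max=None),
    "melt": dict(Tm=330.0, dH_app=60.0, aF=-6000.0, bF=5.0, aU=-1500.0, bU=2.0,
                 T_min=277.15, T_max=368.15),
    "kinetics": dict(phases=[(0.005, -0.08)], offset=0.25, t_max=1500.0,
                     signal_kind="anisotropy", denaturant=0.5),
    "chevron": dict(ln_kf_H2O=0.0, mF_kin=-1.5, ln_ku_H2O=-6.0, mU_kin=1.5,
                    mU1_kin=0.0, temperature=298.15,
                    folding_window=(0.8, 1.68), unfolding_window=(1.72, 3.0)),
    "gating": dict(n_pos=3.12, V0_pos=28.63, n_neg=3.07, V0_neg=25.00,
                   g_min=0.4, G_max=50.0, temperature=298.15, V_max=60.0),
    "insertions": dict(means=(2.43, 3.98), sds=(0.58, 0.50), counts=(6, 12)),
    "quench": dict(K_SV=5.0, F0=100.0, Q_max=0.4, mode="steady_state"),
    "decay": dict(amplitudes=(1.0, 1.0, 1.0), lifetimes=(0.5, 2.0, 6.0),
                  peak_counts=1e4, background=10.0, t_max=30.0),
    "micelle_system": dict(n_detergent=80, n_water=200, box_edge=110.4, n_frames=5),
}


@dataclass
class GeneratorSpec:
    """Specification for one synthetic dataset: stage, truth, noise, size, seed."""

    stage: str
    truth: dict = field(default_factory=dict)
    noise: float = 0.0          # Gaussian sd as a fraction of signal range
    n_points: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.stage not in STAGE_DEFAULTS:
            raise ValidationError(
                f"unknown stage {self.stage!r}; known: {sorted(STAGE_DEFAULTS)}")
        if self.noise < 0:
            raise ValidationError("noise magnitude must be >= 0")
        merged = dict(STAGE_DEFAULTS[self.stage])
        merged.update(self.truth)
        self.truth = merged


def _noise(rng: np.random.Generator, n: int, magnitude: float, scale: float) -> np.ndarray:
    # unit draw first, then scale: same seed => noise strictly proportional to magnitude
    return magnitude * scale * rng.standard_normal(n)


def _titration_design(dG0: float, m: float, D_max: float | None, n: int) -> np.ndarray:
    """Denaturant grid for an equilibrium titration: half the points uniform
    over the full range, half packed across the transition (within one 10-90%
    width of Cm), the way an m-value titration is actually planned."""
    from .io import R_KCAL
    Cm = dG0 / m
    width = np.log(81.0) * R_KCAL * 298.15 / m      # 10-90% width
    if D_max is None:
        D_max = max(Cm + max(1.5, 2.0 * width), 2.0)
    n_fine = n // 2
    lo, hi = max(Cm - width, 0.0), min(Cm + width, D_max)
    D = np.concatenate([np.linspace(0.0, D_max, n - n_fine),
                        np.linspace(lo, hi, n_fine)])
    D = np.unique(np.round(np.sort(D), 9))
    while D.size < n:                                # resolve grid collisions
        D = np.sort(np.append(D, D[-1] + 0.05))
    return D


def generate(spec: GeneratorSpec):
    """Forward-simulate one stage; returns (typed record, truth sidecar dict).

    The sidecar holds every truth parameter plus the seed and noise level so
    a downstream fit can be checked against it.
    """
    rng = np.random.default_rng(spec.seed)
    t = spec.truth
    sidecar = {"stage": spec.stage, "seed": spec.seed, "noise": spec.noise, **t}

    if spec.stage == "equilibrium":
        if not t["m"] > 0:
            raise ValidationError("m must be positive")
        n = spec.n_points or 24
        D = _titration_design(t["dG0"], t["m"], t.get("D_max"), n)
        S = two_state_signal(D, t["dG0"], t["m"], t["aN"], t["bN"],
                             t["aU"], t["bU"], t["temperature"])
        S = S + _noise(rng, n, spec.noise, np.ptp(S))
        rec = TitrationCurve(denaturant=D, signal=S, arm=Arm.UNFOLDING)
        sidecar["Cm"] = t["dG0"] / t["m"]
        return rec, sidecar

    if spec.stage == "melt":
        if not t["dH_app"] > 0:
            raise ValidationError("dH_app must be positive")
        # 0.2 K data pitch over 4-95 C, the usual continuous T-scan sampling
        n = spec.n_points or 456
        T = np.linspace(t["T_min"], t["T_max"], n)
        S = _melt_signal(T, t["Tm"], t["dH_app"], t["aF"], t["bF"], t["aU"], t["bU"])
        S = S + _noise(rng, n, spec.noise, np.ptp(S))
        return MeltCurve(temperature=T, ellipticity=S), sidecar

    if spec.stage == "kinetics":
        n = spec.n_points or 96
        time = np.linspace(0.0, t["t_max"], n)
        kind = SignalKind(t["signal_kind"])
        dead = ANISOTROPY_DEAD_TIME_S if kind == SignalKind.ANISOTROPY else 0.0
        signal = np.full_like(time, float(t["offset"]))
        for k, A in t["phases"]:
            if k <= 0:
                raise ValidationError("phase rates must be positive")
            signal = signal + A * np.exp(-k * time)
        signal = signal + _noise(rng, n, spec.noise, np.ptp(signal))
        keep = time >= dead
        return KineticTrace(time=time[keep], signal=signal[keep], signal_kind=kind,
                            dead_time=dead, denaturant=t["denaturant"]), sidecar

    if spec.stage == "chevron":
        from .io import R_KCAL
        n_per_arm = spec.n_points or 7
        rt = R_KCAL * t["temperature"]
        points = []
        Df = np.linspace(*t["folding_window"], n_per_arm)
        ln_kf = t["ln_kf_H2O"] + t["mF_kin"] * Df / rt
        ln_kf = ln_kf + _noise(rng, n_per_arm, spec.noise, 1.0)
        points += [(d, float(np.exp(lk)), 0, Arm.FOLDING) for d, lk in zip(Df, ln_kf)]
        Du = np.linspace(*t["unfolding_window"], n_per_arm)
        ln_ku = (t["ln_ku_H2O"] + t["mU_kin"] * Du / rt + t["mU1_kin"] * Du ** 2)
        ln_ku = ln_ku + _noise(rng, n_per_arm, spec.noise, 1.0)
        points += [(d, float(np.exp(lk)), 0, Arm.UNFOLDING) for d, lk in zip(Du, ln_ku)]
        return ChevronDataset(points=points), sidecar

    if spec.stage == "gating":
        n = spec.n_points or 121
        V = np.linspace(-t["V_max"], t["V_max"], n)
        g = np.where(
            V >= 0,
            boltzmann_gg(V, t["n_pos"], t["V0_pos"], t["g_min"], t["temperature"]),
            boltzmann_gg(V, t["n_neg"], t["V0_neg"], t["g_min"], t["temperature"]))
        G = t["G_max"] * (g + _noise(rng, n, spec.noise, np.ptp(g)))
        return GatingRamp(voltage=V, conductance=np.clip(G, 0.0, None),
                          ramp_rate=3.0), sidecar

    if spec.stage == "insertions":
        steps = []
        for mean, sd, count in zip(t["means"], t["sds"], t["counts"]):
            draws = rng.normal(mean, sd, size=count)
            while np.any(draws <= 0):  # redraw non-physical negatives
                bad = draws <= 0
                draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
            steps.append(draws)
        return InsertionEvents(steps=np.concatenate(steps)), sidecar

    if spec.stage == "quench":
        n = spec.n_points or 9
        Q = np.linspace(0.0, t["Q_max"], n)
        F = t["F0"] / (1.0 + t["K_SV"] * Q)
        F = F + _noise(rng, n, spec.noise, np.ptp(F))
        kind = "lifetime" if t["mode"] == "lifetime" else "steady_state"
        return QuenchSeries(quencher=Q, response=F, response_kind=kind), sidecar

    if spec.stage == "decay":
        n = spec.n_points or 600
        time = np.linspace(0.0, t["t_max"], n)
        model = np.full_like(time, float(t["background"]))
        norm = sum(t["amplitudes"])
        for a, tau in zip(t["amplitudes"], t["lifetimes"]):
            if tau <= 0:
                raise ValidationError("lifetimes must be positive")
            model = model + t["peak_counts"] * (a / norm) * np.exp(-time / tau)
        if spec.noise > 0:
            counts = rng.poisson(model).astype(float)
        else:
            counts = np.round(model)
        return PhotonDecay(time=time, counts=counts), sidecar

    # micelle_system
    traj, probes = generate_micelle_system(
        n_detergent=t["n_detergent"], n_water=t["n_water"],
        box_edge=t["box_edge"], n_frames=t["n_frames"], seed=spec.seed)
    sidecar.update(probes)
    return traj, sidecar


def generate_micelle_system(n_detergent: int = 80, n_water: int = 200,
                            box_edge: float = 110.4, n_frames: int = 5,
                            probe_layout: str = "default",
                            seed: int = 0) -> tuple[TrajectoryEnsemble, dict]:
    """Toy protein-in-micelle trajectory with constructed solvation contrasts.

    A barrel-like cage of 24 one-atom residues sits at the box center: a
    20-residue mid-plane ring (radius 12 A) wrapped by a detergent belt
    (``n_detergent`` 3-atom molecules at radii 15-20 A, |z| <= 5 A) and a
    4-residue solvent-exposed cap at z = +18 A bathed by waters (slabs at
    |z| >= 14 A).  By construction the buried probe residue (mid-plane, id 5)
    has detergent but no water within 5 A in every frame, and the surface
    probe (cap, id 21) the reverse — the qualitative detergent/water count
    inversion between buried and exposed interface positions.  Returns the
    ensemble and a dict naming the probe residues.  Deterministic per seed.
    """
    if probe_layout != "default":
        raise ValueError("only the default probe layout is implemented")
    if n_detergent < 1 or n_water < 1:
        raise ValidationError("counts must be positive")
    if box_edge < 95.0:
        raise ValidationError("box too small for the constructed geometry (needs >= 95 A)")
    rng = np.random.default_rng(seed)
    center = box_edge / 2.0

    names, resids, resnames, classes, coords = [], [], [], [], []

    def add(name, resid, resname, mol_class, xyz):
        names.append(name)
        resids.append(resid)
        resnames.append(resname)
        classes.append(mol_class)
        coords.append(xyz)

    # protein: mid-plane ring (residues 1-20) + solvent-exposed cap (21-24)
    for i in range(20):
        th = 2.0 * np.pi * i / 20.0
        add("CA", i + 1, "ALA", "protein", [12.0 * np.cos(th), 12.0 * np.sin(th), 0.0])
    for i in range(4):
        th = 2.0 * np.pi * i / 4.0
        add("CA", 21 + i, "GLY", "protein", [8.0 * np.cos(th), 8.0 * np.sin(th), 18.0])
    buried_probe, surface_probe = 5, 21  # cap residue 21 sits at (8, 0, 18)
    probe_angle = 2.0 * np.pi * (buried_probe - 1) / 20.0

    # detergent belt: 3-atom molecules at radii 15/17.5/20, |z| <= 5
    for j in range(n_detergent):
        th = 2.0 * np.pi * j / n_detergent
        z = 0.0 if j == 0 else float(rng.uniform(-5.0, 5.0))
        ang = probe_angle if j == 0 else th  # molecule 0 pinned beside the buried probe
        for rad, aname in ((15.0, "C1"), (17.5, "C2"), (20.0, "C3")):
            add(aname, j + 1, "DDM", "detergent",
                [rad * np.cos(ang), rad * np.sin(ang), z])

    # waters: slabs above and below, plus one pinned beside the surface probe
    add("O", 1, "HOH", "water", [8.0, 0.0, 21.0])
    for w in range(1, n_water):
        side = 1.0 if rng.random() < 0.5 else -1.0
        r = float(rng.uniform(0.0, 40.0))
        th = float(rng.uniform(0.0, 2.0 * np.pi))
        z = side * float(rng.uniform(14.0, 40.0))
        add("O", w + 1, "HOH", "water", [r * np.cos(th), r * np.sin(th), z])

    # ions in the outer solvent shell
    for k in range(8):
        for ion in ("NA", "CL"):
            r = float(rng.uniform(25.0, 40.0))
            th = float(rng.uniform(0.0, 2.0 * np.pi))
            z = float(rng.uniform(25.0, 40.0)) * (1.0 if k % 2 else -1.0)
            add(ion, k + 1 if ion == "NA" else k + 9, ion, "ion",
                [r * np.cos(th), r * np.sin(th), z])

    base = np.asarray(coords) + center
    frames = np.stack([base + 0.15 * rng.standard_normal(base.shape)
                       for _ in range(n_frames)])
    atoms = pd.DataFrame({"name": names, "resid": resids,
                          "resname": resnames, "mol_class": classes})
    box = np.tile([box_edge] * 3, (n_frames, 1)).astype(float)
    traj = TrajectoryEnsemble(frames=frames, atoms=atoms, box=box)
    probes = {"buried_probe": buried_probe, "surface_probe": surface_probe,
              "n_detergent": n_detergent, "n_water": n_water}
    return traj, probes
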