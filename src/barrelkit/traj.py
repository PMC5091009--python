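"""Post-analysis of protein-detergent trajectories.

Implements the standard rigid-body toolkit: Kabsch least-squares
superposition (proper rotation via SVD with determinant correction),
per-frame RMSD against a reference frame, mass-weighted radius of gyration,
per-residue RMSF with crystallographic B-factor export B = (8 pi^2 / 3) *
RMSF^2, and solvation-shell counting: the number of distinct detergent or
water molecules with at least one atom within a cutoff (default 5 A, closed
boundary) of a probe residue, frame by frame.  Minimum-image distances are
used for orthorhombic periodic boxes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TrajectoryEnsemble, ValidationError

__all__ = ["SelectionSpec", "TrajMetrics", "VicinityCounts",
           "kabsch_superpose", "rmsd_series", "radius_of_gyration", "rg_series",
           "rmsf", "bfactor_from_rmsf", "vicinity_counts", "compute_metrics",
           "ATOMIC_MASSES"]

BFACTOR_CONST = 8.0 * np.pi ** 2 / 3.0

# standard atomic masses (u) looked up from the element guessed off the atom name
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "FE": 55.845, "ZN": 65.38,
}

_TWO_LETTER = ("NA", "CL", "MG", "FE", "ZN", "BR")


def guess_element(atom_name: str) -> str:
    name = atom_name.strip().upper()
    if name[:2] in _TWO_LETTER and (len(name) == 2 or not name[2:].isalpha()):
        return name[:2]
    for ch in name:
        if ch.isalpha():
            return ch
    raise ValidationError(f"cannot guess element for atom name {atom_name!r}")


def atom_masses(atoms: pd.DataFrame) -> np.ndarray:
    return np.array([ATOMIC_MASSES.get(guess_element(n), 12.011) for n in atoms["name"]])


@dataclass(frozen=True)
class SelectionSpec:
    """Atom selection: 1-based inclusive residue range, atom-name set, and/or
    molecule class; criteria are combined with AND."""

    residue_range: tuple[int, int] | None = None
    atom_names: frozenset | None = None
    molecule_class: str | None = None
    exclude_residues: tuple[int, int] | None = None

    def resolve(self, atoms: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(atoms), dtype=bool)
        if self.molecule_class is not None:
            mask &= (atoms["mol_class"] == self.molecule_class).to_numpy()
        if self.residue_range is not None:
            lo, hi = self.residue_range
            mask &= (atoms["resid"] >= lo).to_numpy() & (atoms["resid"] <= hi).to_numpy()
        if self.exclude_residues is not None:
            lo, hi = self.exclude_residues
            mask &= ~((atoms["resid"] >= lo).to_numpy() & (atoms["resid"] <= hi).to_numpy())
        if self.atom_names is not None:
            names = set(self.atom_names)
            mask &= atoms["name"].isin(names).to_numpy()
        if not mask.any():
            raise ValidationError(f"selection {self} matches no atoms")
        return mask


PROTEIN_HEAVY = SelectionSpec(molecule_class="protein")  # heavy-atom filter at use site


@dataclass
class TrajMetrics:
    rmsd: np.ndarray          # per-frame, A
    rg: np.ndarray            # per-frame, A
    rmsf: pd.Series           # per-residue, A (index = resid)
    bfactor: pd.Series        # per-residue, A^2


@dataclass
class VicinityCounts:
    counts: np.ndarray        # per-frame molecule counts
    cutoff: float
    probe_residue: int
    target_class: str

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")


# --- Kabsch superposition --------------------------------------------------

def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation R, translation t, post-fit RMSD) with det(R) = +1 and
    mobile' = mobile @ R.T + t.  Requires >= 3 paired, non-collinear atoms.
    """
    ref = np.asarray(reference, float)
    mob = np.asarray(mobile, float)
    if ref.shape != mob.shape:
        raise ValidationError(f"paired atom sets differ in shape: {ref.shape} vs {mob.shape}")
    if ref.ndim != 2 or ref.shape[1] != 3 or ref.shape[0] < 3:
        raise ValidationError("need >= 3 atoms of 3 coordinates each")

    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    if (np.linalg.matrix_rank(ref_c, tol=1e-9) < 2
            or np.linalg.matrix_rank(mob_c, tol=1e-9) < 2):
        raise ValidationError("degenerate (collinear) atom set: superposition ill-defined")

    H = mob_c.T @ ref_c
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref.mean(axis=0) - mob.mean(axis=0) @ R.T
    moved = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_series(traj: TrajectoryEnsemble, reference_frame: int = 0,
                selection: SelectionSpec | None = None) -> np.ndarray:
    """Per-frame Kabsch-fit RMSD against a reference frame over a selection."""
    if not 0 <= reference_frame < traj.n_frames:
        raise ValidationError(f"reference frame {reference_frame} out of range")
    sel = (selection or SelectionSpec(molecule_class="protein")).resolve(traj.atoms)
    ref = traj.frames[reference_frame][sel]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch_superpose(ref, traj.frames[f][sel])
    return out


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """R_g = sqrt(sum m |r - r_com|^2 / sum m); unit masses when None."""
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[0] < 1:
        raise ValidationError("empty coordinate selection")
    m = np.ones(coords.shape[0]) if masses is None else np.asarray(masses, float)
    com = np.average(coords, axis=0, weights=m)
    return float(np.sqrt(np.average(np.sum((coords - com) ** 2, axis=1), weights=m)))


def rg_series(traj: TrajectoryEnsemble, selection: SelectionSpec | None = None,
              mass_weighted: bool = True) -> np.ndarray:
    sel = (selection or SelectionSpec(molecule_class="protein")).resolve(traj.atoms)
    masses = atom_masses(traj.atoms[sel]) if mass_weighted else None
    return np.array([radius_of_gyration(traj.frames[f][sel], masses)
                     for f in range(traj.n_frames)])


def rmsf(traj: TrajectoryEnsemble, selection: SelectionSpec | None = None,
         fit_first: bool = True) -> pd.Series:
    """Per-residue RMSF about the time-average position.

    Frames are optionally superposed (Kabsch) onto the first frame over the
    selection before averaging; the residue value is the mean of its atoms'
    fluctuations.
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF needs >= 2 frames")
    sel = (selection or SelectionSpec(molecule_class="protein")).resolve(traj.atoms)
    coords = traj.frames[:, sel, :].copy()
    if fit_first:
        ref = coords[0]
        for f in range(traj.n_frames):
            R, t, _ = kabsch_superpose(ref, coords[f])
            coords[f] = coords[f] @ R.T + t
    mean_pos = coords.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=2), axis=0))
    resids = traj.atoms.loc[sel, "resid"].to_numpy()
    return pd.Series(fluct).groupby(resids).mean().rename("rmsf")


def bfactor_from_rmsf(rmsf_values) -> pd.Series | np.ndarray:
    """Crystallographic B-factor B = (8 pi^2 / 3) * RMSF^2 (A^2)."""
    return BFACTOR_CONST * rmsf_values ** 2


def compute_metrics(traj: TrajectoryEnsemble, selection: SelectionSpec | None = None,
                    reference_frame: int = 0, mass_weighted: bool = True) -> TrajMetrics:
    """Bundle RMSD series, R_g series, per-residue RMSF and B-factors."""
    fluct = rmsf(traj, selection)
    return TrajMetrics(
        rmsd=rmsd_series(traj, reference_frame, selection),
        rg=rg_series(traj, selection, mass_weighted),
        rmsf=fluct,
        bfactor=bfactor_from_rmsf(fluct).rename("bfactor"),
    )


# --- solvation-shell counting ---------------------------------------------

def _min_image_dists2(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Squared pairwise distances (len(a) x len(b)); minimum image if box given."""
    diff = a[:, None, :] - b[None, :, :]
    if box is not None:
        diff -= box * np.round(diff / box)
    return np.sum(diff ** 2, axis=2)


def vicinity_counts(traj: TrajectoryEnsemble, probe_residue: int,
                    target_class: str, cutoff: float = 5.0,
                    include_hydrogens: bool = False) -> VicinityCounts:
    """Count target molecules near a probe residue, frame by frame.

    A target molecule is counted once per frame when *any* of its atoms lies
    within ``cutoff`` (closed boundary, <=) of any atom of the probe residue.
    By default only heavy atoms enter the distance test.  The minimum-image
    convention is applied for frames that carry an orthorhombic box.
    """
    atoms = traj.atoms
    heavy = np.array([guess_element(n) != "H" for n in atoms["name"]]) \
        if not include_hydrogens else np.ones(len(atoms), bool)

    probe_mask = ((atoms["resid"] == probe_residue).to_numpy()
                  & (atoms["mol_class"] == "protein").to_numpy() & heavy)
    if not probe_mask.any():
        raise ValidationError(f"probe residue {probe_residue} not found in the protein")
    target_mask = (atoms["mol_class"] == target_class).to_numpy() & heavy
    if not target_mask.any():
        raise ValidationError(f"no atoms of molecule class {target_class!r}")
    mol_ids = atoms.loc[target_mask, "mol_id"].to_numpy()

    if traj.box is None:
        extent = np.ptp(traj.frames.reshape(-1, 3), axis=0)
        if np.any(extent > 1e4):
            warnings.warn("no box given but coordinates span > 1e4 A; "
                          "periodic wrapping may be missing")

    counts = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        box = traj.box[f] if traj.box is not None else None
        d2 = _min_image_dists2(traj.frames[f][probe_mask],
                               traj.frames[f][target_mask], box)
        near = np.any(d2 <= cutoff ** 2, axis=0)
        counts[f] = len(np.unique(mol_ids[near]))
    return VicinityCounts(counts=counts, cutoff=cutoff,
                          probe_residue=probe_residue, target_class=target_class)
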