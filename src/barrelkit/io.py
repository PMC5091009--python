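"""Shared domain types, file I/O, configuration and logging.

Every measurement the pipeline consumes is a small tabular file (CSV with a
header row; ``#`` lines are comments), a FASTA sequence, a PDB topology, or a
multi-frame XYZ coordinate file.  Units are explicit: concentrations in molar
(``_M`` suffix; ``_mM`` accepted and converted), temperatures stored in kelvin
internally (``temperature_C`` columns converted on read), voltages in mV,
conductances in nS, coordinates in angstrom.

Energy conventions: folding free energies in kcal/mol with
R = 1.987e-3 kcal/(mol K); channel-gating energies in kJ/mol with
F = 96485 C/mol.  Conversions are always explicit, never implicit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL", "R_J", "FARADAY", "KELVIN_OFFSET",
    "Arm", "SignalKind", "ResponseKind",
    "TitrationCurve", "KineticTrace", "MeltCurve", "WavelengthScan",
    "GatingRamp", "InsertionEvents", "QuenchSeries", "PhotonDecay",
    "SequenceRecord", "TrajectoryEnsemble", "DilutionStep", "FitResult",
    "ValidationError", "SchemaError", "FitError",
    "read_table", "read_fasta", "read_pdb_topology",
    "read_xyz_frames", "write_xyz_frames",
    "dilution_chain", "write_report", "read_report",
    "load_config", "file_digest", "get_logger",
]

# --- constants -------------------------------------------------------------

R_KCAL = 1.987e-3          # gas constant, kcal/(mol K)
R_J = 8.314462618          # gas constant, J/(mol K)
FARADAY = 96485.0          # Faraday constant, C/mol
KELVIN_OFFSET = 273.15

# residue-name -> molecule-class mapping for trajectory topologies
DEFAULT_CLASS_MAP = {
    "DDM": "detergent",
    "HOH": "water", "SOL": "water", "TIP3": "water", "WAT": "water",
    "NA": "ion", "CL": "ion", "SOD": "ion", "CLA": "ion", "K": "ion",
}

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s: %(message)s"


def get_logger(name: str = "barrelkit") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file, for run provenance logging."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# --- errors ----------------------------------------------------------------

class ValidationError(ValueError):
    """An input record violates one of its documented invariants."""


class SchemaError(ValueError):
    """A table is missing a required column or has an unknown schema."""


class FitError(RuntimeError):
    """A fit could not be performed or did not describe a transition."""


# --- enums -----------------------------------------------------------------

class Arm(str, Enum):
    FOLDING = "folding"
    UNFOLDING = "unfolding"


class SignalKind(str, Enum):
    FLUORESCENCE_INTENSITY = "fluorescence_intensity"
    ANISOTROPY = "anisotropy"
    ELLIPTICITY = "ellipticity"


class ResponseKind(str, Enum):
    STEADY_STATE = "steady_state"
    LIFETIME = "lifetime"


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def _require_strictly_increasing(arr: np.ndarray, name: str) -> None:
    if np.any(np.diff(arr) <= 0):
        raise ValidationError(f"{name} must be strictly increasing (duplicates or disorder found)")


# --- domain types ----------------------------------------------------------

@dataclass
class TitrationCurve:
    """Signal vs denaturant concentration for one arm of an equilibrium experiment.

    ``denaturant`` is in molar GdnHCl; sorting is canonicalized on
    construction and duplicated concentrations are rejected.
    """

    denaturant: np.ndarray
    signal: np.ndarray
    arm: Arm = Arm.UNFOLDING
    signal_kind: SignalKind = SignalKind.FLUORESCENCE_INTENSITY
    incubation_h: float | None = None

    def __post_init__(self):
        self.denaturant = _as_float_array(self.denaturant, "denaturant")
        self.signal = _as_float_array(self.signal, "signal")
        if self.denaturant.size != self.signal.size:
            raise ValidationError("denaturant and signal must have equal length")
        if np.any(self.denaturant < 0):
            raise ValidationError("denaturant concentrations must be non-negative")
        order = np.argsort(self.denaturant)
        self.denaturant = self.denaturant[order]
        self.signal = self.signal[order]
        _require_strictly_increasing(self.denaturant, "denaturant")
        self.arm = Arm(self.arm)
        self.signal_kind = SignalKind(self.signal_kind)

    def __len__(self) -> int:
        return self.denaturant.size


@dataclass
class KineticTrace:
    """Time-stamped signal following a mixing event (manual or stopped flow)."""

    time: np.ndarray
    signal: np.ndarray
    signal_kind: SignalKind = SignalKind.FLUORESCENCE_INTENSITY
    dead_time: float = 0.0
    denaturant: float | None = None

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        self.signal = _as_float_array(self.signal, "signal")
        if self.time.size != self.signal.size:
            raise ValidationError("time and signal must have equal length")
        if self.time.size and self.time[0] < 0:
            raise ValidationError("time must start at >= 0")
        _require_strictly_increasing(self.time, "time")
        self.signal_kind = SignalKind(self.signal_kind)

    def __len__(self) -> int:
        return self.time.size


@dataclass
class MeltCurve:
    """Far-UV CD thermal melt: molar ellipticity (deg cm^2/dmol) vs temperature (K)."""

    temperature: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self):
        self.temperature = _as_float_array(self.temperature, "temperature")
        self.ellipticity = _as_float_array(self.ellipticity, "ellipticity")
        if self.temperature.size != self.ellipticity.size:
            raise ValidationError("temperature and ellipticity must have equal length")
        _require_strictly_increasing(self.temperature, "temperature")

    def __len__(self) -> int:
        return self.temperature.size

    @property
    def span(self) -> float:
        return float(self.temperature[-1] - self.temperature[0])


@dataclass
class WavelengthScan:
    """Far-UV CD wavelength scan: molar ellipticity vs wavelength (nm)."""

    wavelength: np.ndarray
    ellipticity: np.ndarray

    def __post_init__(self):
        self.wavelength = _as_float_array(self.wavelength, "wavelength")
        self.ellipticity = _as_float_array(self.ellipticity, "ellipticity")
        if self.wavelength.size != self.ellipticity.size:
            raise ValidationError("wavelength and ellipticity must have equal length")
        _require_strictly_increasing(self.wavelength, "wavelength")


@dataclass
class GatingRamp:
    """Multichannel membrane conductance vs applied voltage from a triangular ramp."""

    voltage: np.ndarray       # mV
    conductance: np.ndarray   # nS
    ramp_rate: float | None = None  # mV/s, metadata

    def __post_init__(self):
        self.voltage = _as_float_array(self.voltage, "voltage")
        self.conductance = _as_float_array(self.conductance, "conductance")
        if self.voltage.size != self.conductance.size:
            raise ValidationError("voltage and conductance must have equal length")
        if np.any(self.conductance < 0):
            raise ValidationError("conductance must be non-negative")


@dataclass
class InsertionEvents:
    """Single-channel insertion conductance increments (nS) at fixed holding voltage."""

    steps: np.ndarray

    def __post_init__(self):
        self.steps = _as_float_array(self.steps, "steps")
        if np.any(self.steps <= 0):
            raise ValidationError("all insertion steps must be positive")

    def __len__(self) -> int:
        return self.steps.size


@dataclass
class QuenchSeries:
    """Acrylamide quenching series: F or <tau> vs quencher concentration."""

    quencher: np.ndarray
    response: np.ndarray
    response_kind: ResponseKind = ResponseKind.STEADY_STATE
    absorbance_ex: np.ndarray | None = None
    absorbance_em: np.ndarray | None = None

    def __post_init__(self):
        self.quencher = _as_float_array(self.quencher, "quencher")
        self.response = _as_float_array(self.response, "response")
        if self.quencher.size != self.response.size:
            raise ValidationError("quencher and response must have equal length")
        if np.any(self.quencher < 0):
            raise ValidationError("quencher concentrations must be non-negative")
        if not np.any(self.quencher == 0):
            raise ValidationError("series must include the quencher = 0 reference point")
        if np.any(self.response <= 0):
            raise ValidationError("response values must be positive")
        self.response_kind = ResponseKind(self.response_kind)
        for attr in ("absorbance_ex", "absorbance_em"):
            val = getattr(self, attr)
            if val is not None:
                arr = _as_float_array(val, attr)
                if arr.size != self.quencher.size:
                    raise ValidationError(f"{attr} must match series length")
                if np.any(arr < 0):
                    raise ValidationError(f"{attr} must be non-negative")
                setattr(self, attr, arr)


@dataclass
class PhotonDecay:
    """TCSPC histogram: photon counts vs time (ns)."""

    time: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.time = _as_float_array(self.time, "time")
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("counts must be integers")
        self.counts = counts.astype(float)
        if self.time.size != self.counts.size:
            raise ValidationError("time and counts must have equal length")
        _require_strictly_increasing(self.time, "time")


_CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SequenceRecord:
    """One-letter amino-acid sequence with identifier."""

    id: str
    residues: str
    allow_x: bool = False

    def __post_init__(self):
        self.residues = self.residues.upper()
        allowed = _CANONICAL_AA | ({"X"} if self.allow_x else set())
        bad = [(i + 1, c) for i, c in enumerate(self.residues) if c not in allowed]
        if bad:
            pos, letter = bad[0]
            raise ValidationError(
                f"non-canonical residue {letter!r} at position {pos} in sequence {self.id!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames of a protein-detergent-water system.

    ``atoms`` is a static table with columns ``name`` (atom name), ``resid``
    (1-based residue number), ``resname`` and ``mol_class`` (protein,
    detergent, water or ion); a ``mol_id`` column identifying distinct
    molecules is derived on construction (one molecule per (class, resid)
    pair, the whole protein counting as one molecule).  ``frames`` has shape
    (n_frames, n_atoms, 3) in angstrom; ``box`` holds per-frame orthorhombic
    edge lengths or None.
    """

    frames: np.ndarray
    atoms: pd.DataFrame
    box: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValidationError("coordinates must be finite")
        required = {"name", "resid", "resname", "mol_class"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise SchemaError(f"atom table missing columns: {sorted(missing)}")
        if len(self.atoms) != self.frames.shape[1]:
            raise ValidationError("atom table length must match frame atom count")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.frames.shape[0], 3):
                raise ValidationError("box must have shape (n_frames, 3)")
        if "mol_id" not in self.atoms.columns:
            atoms = self.atoms.copy()
            keys = []
            for cls, resid in zip(atoms["mol_class"], atoms["resid"]):
                keys.append(("protein", 0) if cls == "protein" else (cls, int(resid)))
            _, mol_ids = np.unique(
                np.array([f"{c}:{r}" for c, r in keys]), return_inverse=True)
            atoms["mol_id"] = mol_ids
            self.atoms = atoms

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class DilutionStep:
    """One dilution with a fold factor > 1 (e.g. 5-fold)."""

    factor: float
    label: str = ""

    def __post_init__(self):
        if not self.factor > 1:
            raise ValidationError(f"dilution factor must be > 1, got {self.factor}")


@dataclass
class FitResult:
    """Generic fitted-parameter container used by the report writer."""

    name: str
    parameters: dict[str, float]
    standard_errors: dict[str, float] = field(default_factory=dict)
    residual_norm: float = float("nan")
    converged: bool = True
    n_points: int = 0

    def __post_init__(self):
        if self.converged:
            for key, val in self.parameters.items():
                if not math.isfinite(val):
                    raise ValidationError(
                        f"converged fit {self.name!r} has non-finite parameter {key!r}")


# --- tabular readers -------------------------------------------------------

_TABLE_SCHEMAS = {
    "titration": (TitrationCurve, {"gdnhcl_M": "denaturant", "signal": "signal"}),
    "kinetic": (KineticTrace, {"time_s": "time", "signal": "signal"}),
    "melt": (MeltCurve, {"ellipticity": "ellipticity"}),  # temperature handled specially
    "scan": (WavelengthScan, {"wavelength_nm": "wavelength", "ellipticity": "ellipticity"}),
    "gating": (GatingRamp, {"voltage_mV": "voltage", "conductance_nS": "conductance"}),
    "insertions": (InsertionEvents, {"step_nS": "steps"}),
    "quench": (QuenchSeries, {"quencher_M": "quencher", "response": "response"}),
    "decay": (PhotonDecay, {"time_ns": "time", "counts": "counts"}),
}


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, comment="#", sep=None, engine="python")


def read_table(path: str | Path, schema: str, **metadata):
    """Read a measurement CSV/TSV into its typed record.

    ``schema`` is one of: titration, kinetic, melt, scan, gating, insertions,
    quench, decay.  Extra keyword arguments (``arm``, ``signal_kind``,
    ``dead_time`` ...) are forwarded to the record constructor.  Melt tables
    may carry ``temperature_C`` or ``temperature_K``; Celsius is converted.
    Quench tables may carry optional ``absorbance_ex``/``absorbance_em``.
    """
    if schema not in _TABLE_SCHEMAS:
        raise SchemaError(f"unknown table schema {schema!r}; known: {sorted(_TABLE_SCHEMAS)}")
    cls, colmap = _TABLE_SCHEMAS[schema]
    df = _read_csv(path)
    kwargs = dict(metadata)
    if schema == "melt":
        if "temperature_K" in df.columns:
            kwargs["temperature"] = df["temperature_K"].to_numpy(float)
        elif "temperature_C" in df.columns:
            kwargs["temperature"] = df["temperature_C"].to_numpy(float) + KELVIN_OFFSET
        else:
            raise SchemaError("melt table requires a temperature_C or temperature_K column")
    if schema == "quench":
        for col, attr in (("absorbance_ex", "absorbance_ex"), ("absorbance_em", "absorbance_em")):
            if col in df.columns:
                kwargs[attr] = df[col].to_numpy(float)
    if schema == "titration" and "gdnhcl_mM" in df.columns and "gdnhcl_M" not in df.columns:
        df = df.rename(columns={"gdnhcl_mM": "gdnhcl_M"})
        df["gdnhcl_M"] = df["gdnhcl_M"] / 1000.0
    for col, attr in colmap.items():
        if col not in df.columns:
            raise SchemaError(f"table {path} missing required column {col!r} for schema {schema!r}")
        kwargs[attr] = df[col].to_numpy(float)
    return cls(**kwargs)


def read_fasta(path: str | Path, allow_x: bool = False) -> list[SequenceRecord]:
    """Read sequences from a FASTA file (via Biopython)."""
    from Bio import SeqIO
    records = [SequenceRecord(id=rec.id, residues=str(rec.seq), allow_x=allow_x)
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValidationError(f"no sequences found in {path}")
    return records


# --- structure / trajectory I/O -------------------------------------------

def read_pdb_topology(path: str | Path,
                      class_map: Mapping[str, str] | None = None) -> TrajectoryEnsemble:
    """Read a PDB file as topology + first frame.

    Molecule classes are inferred from residue names through ``class_map``
    (default: DDM->detergent, HOH/SOL/TIP3->water, NA/CL->ion, else protein).
    """
    import biotite.structure.io.pdb as pdb

    class_map = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    pdb_file = pdb.PDBFile.read(str(path))
    structure = pdb_file.get_structure(model=1)
    atoms = pd.DataFrame({
        "name": structure.atom_name,
        "resid": structure.res_id.astype(int),
        "resname": structure.res_name,
        "mol_class": [class_map.get(rn, "protein") for rn in structure.res_name],
    })
    coords = np.asarray(structure.coord, dtype=float)[None, :, :]
    return TrajectoryEnsemble(frames=coords, atoms=atoms)


def read_xyz_frames(path: str | Path, topology: TrajectoryEnsemble | None = None,
                    class_map: Mapping[str, str] | None = None) -> TrajectoryEnsemble:
    """Read a multi-frame XYZ file.

    Dialect: repeated blocks of ``n_atoms``, a comment line (optionally
    ``box <a> <b> <c>`` carrying orthorhombic edges in angstrom), then
    ``name x y z`` atom lines.  If ``topology`` is given its atom table is
    reused (atom count must match); otherwise atom names double as residue
    names with one residue per atom.
    """
    lines = Path(path).read_text().splitlines()
    frames, boxes, names = [], [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1].strip()
        box = None
        if comment.lower().startswith("box"):
            box = [float(x) for x in comment.split()[1:4]]
        frame_names, coords = [], []
        for line in lines[i + 2:i + 2 + n]:
            parts = line.split()
            frame_names.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if names is None:
            names = frame_names
        frames.append(coords)
        boxes.append(box)
        i += 2 + n
    frames_arr = np.asarray(frames, dtype=float)
    box_arr = None
    if all(b is not None for b in boxes) and boxes:
        box_arr = np.asarray(boxes, dtype=float)
    if topology is not None:
        if len(topology.atoms) != frames_arr.shape[1]:
            raise ValidationError("topology atom count does not match XYZ frames")
        atoms = topology.atoms
    else:
        class_map = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
        atoms = pd.DataFrame({
            "name": names,
            "resid": np.arange(1, len(names) + 1),
            "resname": names,
            "mol_class": [class_map.get(n, "protein") for n in names],
        })
    return TrajectoryEnsemble(frames=frames_arr, atoms=atoms, box=box_arr)


def write_xyz_frames(traj: TrajectoryEnsemble, path: str | Path) -> None:
    """Write a TrajectoryEnsemble in the multi-frame XYZ dialect (round-trips
    with :func:`read_xyz_frames` at 12 significant digits)."""
    out = []
    names = traj.atoms["name"].tolist()
    for f in range(traj.n_frames):
        out.append(str(traj.n_atoms))
        if traj.box is not None:
            a, b, c = traj.box[f]
            out.append(f"box {a:.12g} {b:.12g} {c:.12g}")
        else:
            out.append(f"frame {f}")
        for name, (x, y, z) in zip(names, traj.frames[f]):
            out.append(f"{name} {x:.12g} {y:.12g} {z:.12g}")
    Path(path).write_text("\n".join(out) + "\n")


# --- dilution arithmetic ---------------------------------------------------

def dilution_chain(initial: float, steps: Iterable[DilutionStep | float]) -> float:
    """Final concentration after a chain of dilutions: initial / prod(factors).

    Steps may be DilutionStep records or bare fold factors.  Order-invariant
    by product commutativity.  E.g. 6 M through 10x then 5x leaves 0.12 M
    residual denaturant; 19.5 mM detergent through 5x gives 3.9 mM.
    """
    if initial < 0:
        raise ValidationError("initial concentration must be non-negative")
    total = 1.0
    for step in steps:
        factor = step.factor if isinstance(step, DilutionStep) else float(step)
        if not factor > 1:
            raise ValidationError(f"dilution factor must be > 1, got {factor}")
        total *= factor
    return initial / total


# --- fit report writer -----------------------------------------------------

def write_report(results: Sequence[FitResult] | Mapping[str, FitResult],
                 path: str | Path) -> tuple[Path, Path]:
    """Write a collection of FitResults as CSV + JSON summary files.

    ``path`` is a stem; ``<stem>.csv`` and ``<stem>.json`` are produced with
    deterministic column ordering.  Values round-trip at full float precision
    through the JSON file.
    """
    if isinstance(results, Mapping):
        results = list(results.values())
    results = list(results)
    if not results:
        raise ValidationError("cannot write a report for an empty result collection")
    stem = Path(path)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")

    param_names = sorted({k for r in results for k in r.parameters})
    rows = []
    for r in results:
        row = {"name": r.name, "converged": r.converged,
               "residual_norm": r.residual_norm, "n_points": r.n_points}
        for p in param_names:
            row[p] = r.parameters.get(p, float("nan"))
            row[f"{p}_stderr"] = r.standard_errors.get(p, float("nan"))
        rows.append(row)
    cols = ["name", "converged", "residual_norm", "n_points"]
    for p in param_names:
        cols += [p, f"{p}_stderr"]
    pd.DataFrame(rows)[cols].to_csv(csv_path, index=False)

    payload = [{
        "name": r.name,
        "parameters": r.parameters,
        "standard_errors": r.standard_errors,
        "residual_norm": r.residual_norm,
        "converged": r.converged,
        "n_points": r.n_points,
    } for r in results]
    json_path.write_text(json.dumps(payload, indent=2))
    return csv_path, json_path


def read_report(json_path: str | Path) -> list[FitResult]:
    """Read back a JSON fit report written by :func:`write_report`."""
    payload = json.loads(Path(json_path).read_text())
    return [FitResult(**entry) for entry in payload]


# --- configuration ---------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML key-value config file used to pre-set CLI flags."""
    import yaml
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise SchemaError("config file must be a key-value mapping")
    return data
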