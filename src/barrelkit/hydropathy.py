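"""Sliding-window hydropathy profiles on protein sequences.

Three residue scales are embedded:

* ``kyte_doolittle`` — the classic hydropathy index (positive = hydrophobic).
* ``wimley_white_interfacial`` — experimental water-to-POPC-interface
  transfer free energies (kcal/mol, charged side-chain forms for D/E/K/R,
  neutral His; negative = favorable partitioning into the interface).
* ``transmembrane_tendency`` — statistical transmembrane propensity
  (positive = transmembrane-favoring).

Windowed values are arithmetic means assigned to the window *center*, with
1-based residue coordinates, so a profile position lines up directly with a
residue number of interest (e.g. an interfacial tryptophan).  Because the
scales live on incompatible axes, profiles can be min-max or z-score
normalized for overlay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SequenceRecord, ValidationError

__all__ = ["SCALES", "HydropathyProfile", "window_hydropathy", "normalize_profile"]

KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# water -> POPC interface transfer dG, kcal/mol (charged D/E/K/R, neutral H)
WIMLEY_WHITE_INTERFACIAL = {
    "A": 0.17, "R": 0.81, "N": 0.42, "D": 1.23, "C": -0.24,
    "Q": 0.58, "E": 2.02, "G": 0.01, "H": 0.17, "I": -0.31,
    "L": -0.56, "K": 0.99, "M": -0.23, "F": -1.13, "P": 0.45,
    "S": 0.13, "T": 0.14, "W": -1.85, "Y": -0.94, "V": 0.07,
}

TRANSMEMBRANE_TENDENCY = {
    "A": 0.38, "R": -2.57, "N": -1.62, "D": -3.27, "C": -0.30,
    "Q": -1.84, "E": -2.90, "G": -0.19, "H": -1.44, "I": 1.97,
    "L": 1.82, "K": -3.46, "M": 1.40, "F": 1.98, "P": -1.44,
    "S": -0.53, "T": -0.32, "W": 1.53, "Y": 0.49, "V": 1.46,
}

SCALES: dict[str, dict[str, float]] = {
    "kyte_doolittle": KYTE_DOOLITTLE,
    "wimley_white_interfacial": WIMLEY_WHITE_INTERFACIAL,
    "transmembrane_tendency": TRANSMEMBRANE_TENDENCY,
}

for _name, _table in SCALES.items():
    assert len(_table) == 20, f"scale {_name} must map exactly the 20 canonical residues"


@dataclass
class HydropathyProfile:
    positions: np.ndarray   # 1-based window-center residue indices
    values: np.ndarray
    scale: str
    window: int

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise ValidationError("positions and values must have equal length")
        if self.window % 2 == 0:
            raise ValidationError("window must be odd")

    def __len__(self) -> int:
        return self.values.size


def window_hydropathy(seq: SequenceRecord | str, scale: str | dict[str, float],
                      window: int = 9, unknown_value: float | None = None
                      ) -> HydropathyProfile:
    """Mean scale value over a sliding window of odd length (default 9).

    The value at center position p averages residues p-(w-1)/2 ... p+(w-1)/2;
    centers run from (w+1)/2 to L-(w-1)/2 (1-based), giving L - w + 1 points.
    Unknown residues raise an error naming the position unless
    ``unknown_value`` supplies a neutral substitute (with a warning).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else str(seq).upper()
    scale_name = scale if isinstance(scale, str) else "custom"
    if isinstance(scale, str):
        if scale not in SCALES:
            raise ValidationError(f"unknown scale {scale!r}; known: {sorted(SCALES)}")
        table = SCALES[scale]
    else:
        table = scale
    if window % 2 == 0 or window < 1:
        raise ValidationError("window must be a positive odd integer")
    L = len(residues)
    if L < window:
        raise ValidationError(f"sequence length {L} is shorter than window {window}")

    values = np.empty(L)
    for i, res in enumerate(residues):
        if res in table:
            values[i] = table[res]
        elif unknown_value is not None:
            import warnings
            warnings.warn(f"unknown residue {res!r} at position {i + 1}; "
                          f"using neutral value {unknown_value}")
            values[i] = unknown_value
        else:
            raise ValidationError(f"unknown residue {res!r} at position {i + 1}")

    kernel = np.ones(window) / window
    means = np.convolve(values, kernel, mode="valid")
    half = (window - 1) // 2
    positions = np.arange(half + 1, L - half + 1)
    return HydropathyProfile(positions=positions, values=means,
                             scale=scale_name, window=window)


def normalize_profile(profile: HydropathyProfile, method: str = "minmax"
                      ) -> HydropathyProfile:
    """Normalize a profile for overlay: minmax to [0, 1] or zscore to (0, 1)."""
    v = profile.values
    if method == "minmax":
        lo, hi = float(np.min(v)), float(np.max(v))
        if hi == lo:
            raise ValidationError("cannot min-max normalize a constant profile")
        out = (v - lo) / (hi - lo)
    elif method == "zscore":
        if v.size < 2:
            raise ValidationError("need >= 2 points for z-score normalization")
        sd = float(np.std(v, ddof=0))
        if sd == 0:
            raise ValidationError("cannot z-score a constant profile")
        out = (v - float(np.mean(v))) / sd
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return HydropathyProfile(positions=profile.positions.copy(), values=out,
                             scale=profile.scale, window=profile.window)
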