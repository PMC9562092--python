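"""Static 2-D scalp positions for the international 10-20 system.

Coordinates are the usual flattened top view of the head: x grows toward
the right ear, y toward the nasion, and the outermost electrode ring sits
on the unit circle.  They are shipped as a static table so topographic
summaries need no external montage files.
"""

from __future__ import annotations

import numpy as np

# label -> (x, y); approximate equidistant 10-20/10-10 projection
MONTAGE_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fpz": (0.00, 1.00), "Fp2": (0.31, 0.95),
    "AF7": (-0.54, 0.81), "AF3": (-0.26, 0.79), "AFz": (0.00, 0.80),
    "AF4": (0.26, 0.79), "AF8": (0.54, 0.81),
    "F7": (-0.80, 0.59), "F5": (-0.59, 0.57), "F3": (-0.40, 0.56),
    "F1": (-0.20, 0.55), "Fz": (0.00, 0.55), "F2": (0.20, 0.55),
    "F4": (0.40, 0.56), "F6": (0.59, 0.57), "F8": (0.80, 0.59),
    "FT7": (-0.95, 0.31), "FC5": (-0.72, 0.30), "FC3": (-0.48, 0.29),
    "FC1": (-0.24, 0.28), "FCz": (0.00, 0.28), "FC2": (0.24, 0.28),
    "FC4": (0.48, 0.29), "FC6": (0.72, 0.30), "FT8": (0.95, 0.31),
    "T7": (-1.00, 0.00), "C5": (-0.75, 0.00), "C3": (-0.50, 0.00),
    "C1": (-0.25, 0.00), "Cz": (0.00, 0.00), "C2": (0.25, 0.00),
    "C4": (0.50, 0.00), "C6": (0.75, 0.00), "T8": (1.00, 0.00),
    "TP7": (-0.95, -0.31), "CP5": (-0.72, -0.30), "CP3": (-0.48, -0.29),
    "CP1": (-0.24, -0.28), "CPz": (0.00, -0.28), "CP2": (0.24, -0.28),
    "CP4": (0.48, -0.29), "CP6": (0.72, -0.30), "TP8": (0.95, -0.31),
    "P7": (-0.80, -0.59), "P5": (-0.59, -0.57), "P3": (-0.40, -0.56),
    "P1": (-0.20, -0.55), "Pz": (0.00, -0.55), "P2": (0.20, -0.55),
    "P4": (0.40, -0.56), "P6": (0.59, -0.57), "P8": (0.80, -0.59),
    "PO7": (-0.54, -0.81), "PO3": (-0.26, -0.79), "POz": (0.00, -0.80),
    "PO4": (0.26, -0.79), "PO8": (0.54, -0.81),
    "O1": (-0.31, -0.95), "Oz": (0.00, -1.00), "O2": (0.31, -0.95),
}

#: Default 32-channel set.  The recorded montage is not fixed by the task
#: design, so the channel list is configurable; this default covers the
#: prefrontal electrodes analysed for the P2 component (Fp1, Fpz, Fp2,
#: AF3, AF4) plus a whole-head 10-20 grid including the midline chain.
DEFAULT_32 = [
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FCz", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CPz", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz",
]


def positions_for(labels: list[str]) -> np.ndarray:
    """Return an (n, 2) array of 2-D positions for *labels*.

    Raises ``KeyError`` for labels absent from the shipped 10-20 table.
    """
    out = np.empty((len(labels), 2), dtype=float)
    for i, lab in enumerate(labels):
        key = _normalize(lab)
        if key not in MONTAGE_2D:
            raise KeyError(f"no 10-20 position for channel {lab!r}")
        out[i] = MONTAGE_2D[key]
    return out


def is_midline(label: str) -> bool:
    """True for midline electrodes (Fpz, AFz, Fz, FCz, Cz, CPz, Pz, POz, Oz)."""
    return label.strip().lower().endswith("z")


def _normalize(label: str) -> str:
    low = label.strip().lower()
    for key in MONTAGE_2D:
        if key.lower() == low:
            return key
    return label.strip()
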