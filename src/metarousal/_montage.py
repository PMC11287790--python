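"""64-channel 10-20 montage names with approximate 2D scalp positions.

Positions are schematic top-view coordinates on the unit disk (x: left
negative, y: front positive).  They are used only to build spatial noise
covariance and component topographies for the synthetic epoch generator;
no claim of geometric accuracy is made.
"""

from __future__ import annotations

import re

import numpy as np

BIOSEMI64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]

# default reduced montage used by the synthetic generator (speed); includes
# both analysis ROIs and >= 8 posterior channels
DEFAULT_CHANNELS = [
    "Fz", "F1", "F2", "FCz", "Cz", "C1", "C2", "CPz", "CP1", "CP2",
    "Pz", "P1", "P2", "POz", "PO3", "PO4", "PO7", "PO8", "Oz", "O1", "O2",
]

_ROW_Y = {
    "Fp": 0.95, "AF": 0.75, "F": 0.55, "FT": 0.30, "FC": 0.30, "T": 0.0,
    "C": 0.0, "TP": -0.30, "CP": -0.30, "P": -0.55, "PO": -0.75, "O": -0.95,
    "I": -1.05,
}

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


def channel_positions(names: list[str]) -> np.ndarray:
    """(n, 2) schematic x/y positions for 10-20 style channel names."""
    pos = np.zeros((len(names), 2))
    for i, name in enumerate(names):
        m = _LABEL_RE.match(name)
        if m is None:
            raise ValueError(f"cannot parse channel name {name!r}")
        row, num = m.groups()
        row_key = row if row in _ROW_Y else row.upper()
        if row_key not in _ROW_Y:
            raise ValueError(f"unknown channel row {row!r} in {name!r}")
        y = _ROW_Y[row_key]
        if num == "z":
            x = 0.0
        else:
            k = int(num)
            side = -1.0 if k % 2 == 1 else 1.0
            x = side * 0.16 * ((k + 1) // 2)
        pos[i] = (x, y)
    return pos
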