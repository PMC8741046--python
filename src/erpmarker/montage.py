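"""64-channel 10-10 montage with normalized scalp coordinates.

Channel locations are expressed on two arbitrary-unit axes, each spanning
[-1, 1]: a left-right axis (negative = left hemisphere, 0 = midline) and a
posterior-anterior axis (-1 = most posterior row, +1 = most anterior row).
Coordinates are derived deterministically from the 10-10 channel names, so
the layout carries the topological structure real electrode caps have
(homologous pairs mirrored across the midline, rows ordered front to back)
without pretending to be a digitized head model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# 64-channel cap: 62 scalp electrodes + the two mastoids (TP9/TP10).
# FCz is absent (used as the recording reference).
CHANNEL_NAMES: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T7", "T8", "P7", "P8", "Fz", "Cz", "Pz", "Oz",
    "FC1", "FC2", "CP1", "CP2", "FC5", "FC6", "CP5", "CP6", "TP9", "TP10",
    "FT9", "FT10", "F1", "F2", "C1", "C2", "P1", "P2", "AF3", "AF4",
    "FC3", "FC4", "CP3", "CP4", "PO3", "PO4", "F5", "F6", "C5", "C6",
    "P5", "P6", "AF7", "AF8", "FT7", "FT8", "TP7", "TP8", "PO7", "PO8",
    "Fpz", "AFz", "CPz", "POz",
)

MASTOIDS: tuple[str, str] = ("TP9", "TP10")

# Posterior-anterior coordinate per 10-10 row prefix, most anterior first.
_ROW_PA = {
    "Fp": 1.0, "AF": 0.75, "F": 0.5, "FT": 0.25, "FC": 0.25,
    "T": 0.0, "C": 0.0, "TP": -0.25, "CP": -0.25,
    "P": -0.5, "PO": -0.75, "O": -1.0,
}

# Left-right magnitude per 10-10 index digit (odd = left, even = right).
_IDX_LR = {1: 0.2, 2: 0.2, 3: 0.45, 4: 0.45, 5: 0.65, 6: 0.65,
           7: 0.85, 8: 0.85, 9: 1.0, 10: 1.0}


@dataclass(frozen=True)
class Montage:
    """Electrode layout: names plus (left-right, posterior-anterior) coordinates."""

    channel_names: tuple[str, ...]
    lr_coord: np.ndarray  # shape (n_channels,), in [-1, 1]
    pa_coord: np.ndarray  # shape (n_channels,), in [-1, 1]
    mastoids: tuple[str, str] = MASTOIDS
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {name: i for i, name in enumerate(self.channel_names)}
        )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self._index[name]

    @property
    def mastoid_indices(self) -> tuple[int, int]:
        return self.index(self.mastoids[0]), self.index(self.mastoids[1])

    @property
    def scalp_mask(self) -> np.ndarray:
        """Boolean mask of non-mastoid (analysis) channels."""
        mask = np.ones(self.n_channels, dtype=bool)
        mask[list(self.mastoid_indices)] = False
        return mask

    def positions(self) -> np.ndarray:
        """(n_channels, 2) array of (lr, pa) coordinates."""
        return np.column_stack([self.lr_coord, self.pa_coord])


def _parse_channel(name: str) -> tuple[float, float]:
    if name.endswith("z"):
        row = name[:-1]
        return 0.0, _ROW_PA[row]
    i = 0
    while i < len(name) and not name[i].isdigit():
        i += 1
    row, idx = name[:i], int(name[i:])
    sign = -1.0 if idx % 2 == 1 else 1.0
    return sign * _IDX_LR[idx], _ROW_PA[row]


def build_montage() -> Montage:
    """Deterministic 64-channel layout with coordinates in [-1, 1]."""
    lr = np.empty(len(CHANNEL_NAMES))
    pa = np.empty(len(CHANNEL_NAMES))
    for i, name in enumerate(CHANNEL_NAMES):
        lr[i], pa[i] = _parse_channel(name)
    return Montage(CHANNEL_NAMES, lr, pa)


# Nine scalp regions: anterior/central/posterior x left/midline/right,
# partitioning the 62 non-mastoid channels by their coordinates.
REGION_NAMES: tuple[str, ...] = (
    "anterior_left", "anterior_midline", "anterior_right",
    "central_left", "central_midline", "central_right",
    "posterior_left", "posterior_midline", "posterior_right",
)


def scalp_regions(montage: Montage) -> dict[str, list[str]]:
    """Map every non-mastoid channel into exactly one of nine scalp regions.

    Rows with posterior-anterior coordinate >= 0.4 are anterior (Fp/AF/F),
    <= -0.4 posterior (P/PO/O), the rest central; laterality by the sign of
    the left-right coordinate.
    """
    regions: dict[str, list[str]] = {name: [] for name in REGION_NAMES}
    for i, name in enumerate(montage.channel_names):
        if name in montage.mastoids:
            continue
        pa = montage.pa_coord[i]
        lr = montage.lr_coord[i]
        row = "anterior" if pa >= 0.4 else ("posterior" if pa <= -0.4 else "central")
        col = "midline" if lr == 0 else ("left" if lr < 0 else "right")
        regions[f"{row}_{col}"].append(name)
    return regions
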