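"""Electrode montage and topographic site grids.

The recording layout is the 19-channel international 10-20 scalp montage
(Fp1..O2, linked-ears reference) plus four electro-oculogram (EOG) sites:
above and below the left eye and beyond the outer canthus of each eye.
Scalp positions are schematic 2-D head coordinates (nose up, unit head
radius) used for head-map plotting and for the spatial profiles of the
synthetic component templates.

Topographic statistics run on 3 x 3 site grids: sagittal rows
(frontal / central / parietal) crossed with lateral columns
(left / midline / right).  The core grid uses F3/Fz/F4, C3/Cz/C4 and
P3/Pz/P4.  Components with a temporal focus (Processing Negativity) use a
variant where the hemispheric pairs are swapped outward to F7/8, T7/8 and
P7/8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCALP_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

EOG_CHANNELS: tuple[str, ...] = ("VEOGU", "VEOGL", "HEOGL", "HEOGR")

# Schematic 2-D positions (x: left -> right, y: back -> front), unit head.
_POSITIONS: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.80, 0.59), "F3": (-0.43, 0.54), "Fz": (0.0, 0.51),
    "F4": (0.43, 0.54), "F8": (0.80, 0.59),
    "T7": (-0.99, 0.0), "C3": (-0.51, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.51, 0.0), "T8": (0.99, 0.0),
    "P7": (-0.80, -0.59), "P3": (-0.43, -0.54), "Pz": (0.0, -0.51),
    "P4": (0.43, -0.54), "P8": (0.80, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

SAGITTAL_ROWS = ("frontal", "central", "parietal")
LATERAL_COLS = ("left", "midline", "right")


@dataclass(frozen=True)
class SiteGrid:
    """3 x 3 channel assignment: sagittal rows x lateral columns."""

    cells: tuple[tuple[str, str, str], ...]
    variant: str = "core"

    def __post_init__(self) -> None:
        flat = [ch for row in self.cells for ch in row]
        if len(self.cells) != 3 or any(len(r) != 3 for r in self.cells):
            raise ValueError("site grid must be 3 x 3")
        if len(set(flat)) != 9:
            raise ValueError("site grid must name 9 distinct channels")

    @property
    def channels(self) -> list[str]:
        return [ch for row in self.cells for ch in row]

    def as_array(self) -> np.ndarray:
        return np.array(self.cells, dtype=object)


CORE_GRID = SiteGrid(
    cells=(("F3", "Fz", "F4"), ("C3", "Cz", "C4"), ("P3", "Pz", "P4")),
    variant="core",
)

# PN focuses at temporal sites: the hemispheric pairs are replaced by the
# outer electrode rows (midline column unchanged).
TEMPORAL_GRID = SiteGrid(
    cells=(("F7", "Fz", "F8"), ("T7", "Cz", "T8"), ("P7", "Pz", "P8")),
    variant="temporal-for-PN",
)


@dataclass(frozen=True)
class Montage:
    """10-20 scalp montage with EOG sites and schematic head layout."""

    scalp_channels: tuple[str, ...] = SCALP_CHANNELS
    eog_channels: tuple[str, ...] = EOG_CHANNELS
    positions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_POSITIONS)
    )

    def __post_init__(self) -> None:
        if len(self.scalp_channels) != 19:
            raise ValueError("montage must have exactly 19 scalp channels")
        missing = [c for c in self.scalp_channels if c not in self.positions]
        if missing:
            raise ValueError(f"missing layout positions for {missing}")
        coords = [self.positions[c] for c in self.scalp_channels]
        if len(set(coords)) != len(coords):
            raise ValueError("layout coordinates must be unique")
        for grid in (CORE_GRID, TEMPORAL_GRID):
            unknown = [c for c in grid.channels if c not in self.scalp_channels]
            if unknown:
                raise ValueError(f"grid references unknown channels {unknown}")

    @property
    def all_channels(self) -> list[str]:
        return list(self.scalp_channels) + list(self.eog_channels)

    def coords(self, channels: list[str] | tuple[str, ...] | None = None) -> np.ndarray:
        """(n, 2) array of layout coordinates for the given scalp channels."""
        if channels is None:
            channels = self.scalp_channels
        return np.array([self.positions[c] for c in channels], dtype=float)

    def scalp_index(self, channel: str) -> int:
        return self.scalp_channels.index(channel)

    def grid(self, variant: str = "core") -> SiteGrid:
        if variant == "core":
            return CORE_GRID
        if variant in ("temporal", "temporal-for-PN"):
            return TEMPORAL_GRID
        raise ValueError(f"unknown grid variant {variant!r}")


def default_montage() -> Montage:
    return Montage()
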