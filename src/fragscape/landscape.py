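"""Core grid containers shared by every spatial stage.

The whole package works on rectangular cell grids addressed ``(row, col)``,
0-based, with row 0 the top (north) row.  A :class:`BinaryLandscape` holds the
foreground/background mask (foreground = the focal class, e.g. farmland)
together with the cell size; every downstream module consumes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The seven foreground structural classes, in canonical order.
MSPA_CLASSES: tuple[str, ...] = (
    "core",
    "islet",
    "bridge",
    "loop",
    "perforation",
    "edge",
    "branch",
)

#: All labels a classified cell can carry (background + the seven classes).
ALL_LABELS: tuple[str, ...] = ("background",) + MSPA_CLASSES

#: Default label -> integer code mapping (background is always 0).
DEFAULT_CODES: dict[str, int] = {label: i for i, label in enumerate(ALL_LABELS)}


@dataclass(frozen=True)
class ClassCodeScheme:
    """Bijection between the 8 labels and distinct small-integer codes.

    Background must map to 0.  Used when structural class maps are written to
    or read from raster files.
    """

    codes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CODES))

    def __post_init__(self) -> None:
        if set(self.codes) != set(ALL_LABELS):
            missing = set(ALL_LABELS) - set(self.codes)
            extra = set(self.codes) - set(ALL_LABELS)
            raise ValueError(
                f"scheme must cover exactly the labels {ALL_LABELS}; "
                f"missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        values = list(self.codes.values())
        if len(set(values)) != len(values):
            raise ValueError("class codes must be distinct")
        if self.codes["background"] != 0:
            raise ValueError("background code must be 0")

    def encode(self, label: str) -> int:
        return self.codes[label]

    def decode(self, code: int) -> str:
        for label, c in self.codes.items():
            if c == code:
                return label
        raise KeyError(f"code {code} not in scheme")

    @property
    def inverse(self) -> dict[int, str]:
        return {c: label for label, c in self.codes.items()}


@dataclass
class BinaryLandscape:
    """A rectangular foreground/background cell grid with a physical cell size.

    Parameters
    ----------
    grid
        2-D boolean array; ``True`` = foreground cell.
    cell_size
        Side length of a cell in meters (default 30 m, i.e. 0.09 ha cells).
    """

    grid: np.ndarray
    cell_size: float = 30.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.grid)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("grid must be a 2-D array with at least one cell")
        if arr.dtype != bool:
            arr = arr.astype(bool)
        self.grid = arr
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def n_cells(self) -> int:
        return self.grid.size

    @property
    def cell_area_ha(self) -> float:
        """Area of one cell in hectares (0.09 ha for 30 m cells)."""
        return self.cell_size**2 / 10_000.0

    @property
    def area_ha(self) -> float:
        return self.n_cells * self.cell_area_ha

    @property
    def foreground_cells(self) -> int:
        return int(self.grid.sum())

    @property
    def foreground_fraction(self) -> float:
        return self.foreground_cells / self.n_cells

    def copy(self) -> "BinaryLandscape":
        return BinaryLandscape(self.grid.copy(), self.cell_size)
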