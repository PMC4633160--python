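"""Geometry of the single-cell deposition matrix.

A flow sorter deposits one bacterium per lattice node onto a dark charcoal
agar plate.  The node lattice ("matrix") is an ``n_rows x n_cols`` grid with
a fixed centre-to-centre pitch, about 500 um on the instrument this package
models.  Plates are laid out at a 1:1.5 row:column aspect so they match the
footprint of standard micro-well plates, and large matrices are sub-formatted
into blocks so that hit colonies can be located by (block, row, col) when
picking.

Conventions used throughout the package:

* grid coordinates are 0-based ``(row, col)``, row-major;
* the physical origin is the top-left node, with y increasing downward to
  match raster-image indexing;
* physical distances are micrometres unless a name says otherwise.

The physical span of a layout is a fencepost quantity:
``width = (n_cols - 1) * pitch``, ``height = (n_rows - 1) * pitch``.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "GridPosition",
    "PlateLayout",
    "make_layout",
    "position_coords",
    "assign_blocks",
    "density",
    "expected_colonies",
]


@dataclass(frozen=True)
class GridPosition:
    """One matrix node; ``block_id`` is set once blocks are assigned."""

    row: int
    col: int
    block_id: int | None = None


@dataclass(frozen=True)
class PlateLayout:
    """Deposition-matrix geometry shared by every pipeline stage.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape; ``n_points = n_rows * n_cols``.
    pitch_um
        Centre-to-centre node spacing in micrometres.
    origin_um
        Physical ``(x, y)`` position of node (row 0, col 0).
    block_rows, block_cols
        Sub-format block shape, or ``None`` when the plate is unblocked.
        Edge blocks may be ragged.
    """

    n_rows: int
    n_cols: int
    pitch_um: float = 500.0
    origin_um: tuple[float, float] = (0.0, 0.0)
    block_rows: int | None = None
    block_cols: int | None = None

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("layout needs at least one row and one column")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")
        if (self.block_rows is None) != (self.block_cols is None):
            raise ValueError("block_rows and block_cols must be set together")
        if self.block_rows is not None and (self.block_rows < 1 or self.block_cols < 1):
            raise ValueError("block dimensions must be >= 1")
        object.__setattr__(self, "origin_um", tuple(float(v) for v in self.origin_um))

    # -- derived geometry ----------------------------------------------------

    @property
    def n_points(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def aspect(self) -> float:
        """Column:row ratio (the paper-style 1:1.5 aspect is 1.5)."""
        return self.n_cols / self.n_rows

    @property
    def width_um(self) -> float:
        return (self.n_cols - 1) * self.pitch_um

    @property
    def height_um(self) -> float:
        return (self.n_rows - 1) * self.pitch_um

    @property
    def has_blocks(self) -> bool:
        return self.block_rows is not None

    @property
    def n_block_cols(self) -> int | None:
        if not self.has_blocks:
            return None
        return math.ceil(self.n_cols / self.block_cols)

    @property
    def n_blocks(self) -> int | None:
        if not self.has_blocks:
            return None
        return math.ceil(self.n_rows / self.block_rows) * self.n_block_cols

    def block_id(self, row: int, col: int) -> int | None:
        """Block index of a node, row-major over the block grid."""
        if not self.has_blocks:
            return None
        return (row // self.block_rows) * self.n_block_cols + (col // self.block_cols)

    def positions(self) -> Iterator[GridPosition]:
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield GridPosition(row, col, self.block_id(row, col))

    def nominal_density_per_cm2(self) -> float | None:
        """Matrix density over the fencepost span; ``None`` for degenerate spans."""
        if self.width_um == 0 or self.height_um == 0:
            return None
        return density(self.n_points, self.width_um / 1000.0, self.height_um / 1000.0)

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["origin_um"] = list(self.origin_um)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            pitch_um=float(d.get("pitch_um", 500.0)),
            origin_um=tuple(d.get("origin_um", (0.0, 0.0))),
            block_rows=d.get("block_rows"),
            block_cols=d.get("block_cols"),
        )

    def save(self, path: str | Path) -> Path:
        """Write the layout as YAML (or JSON when the suffix is ``.json``)."""
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PlateLayout":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def _ratio_distance(n_cols: int, n_rows: int, aspect: Fraction) -> Fraction:
    """Symmetric multiplicative distance of col/row from the target aspect.

    Exact rational arithmetic so genuine ties (e.g. 50x81 vs 54x75 for 4,050
    points at aspect 1.5) are detected and broken deterministically.
    """
    x = Fraction(n_cols, n_rows) / aspect
    return max(x, 1 / x)


def make_layout(
    n_points: int,
    aspect_ratio: float = 1.5,
    pitch_um: float = 500.0,
    *,
    origin_um: tuple[float, float] = (0.0, 0.0),
    max_aspect_error: float = 2.0,
) -> PlateLayout:
    """Factor ``n_points`` into the grid whose col:row ratio best matches the aspect.

    All printed plate formats factor exactly (384 = 16x24, 3,750 = 50x75,
    25,350 = 130x195, 4,050 = 50x81), so the grid is an exact integer
    factorisation rather than a rectangle padded with empty nodes.  Ties in
    ratio distance are broken toward more columns.  When even the best
    factorisation is off by more than ``max_aspect_error`` times the requested
    aspect (e.g. a large prime count), a ``ValueError`` names the nearest
    achievable factorisations.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if aspect_ratio <= 0:
        raise ValueError("aspect_ratio must be positive")
    aspect = Fraction(aspect_ratio).limit_denominator(10**6)
    pairs = []
    for r in range(1, math.isqrt(n_points) + 1):
        if n_points % r == 0:
            c = n_points // r
            pairs.append((r, c))
            if c != r:
                pairs.append((c, r))
    # smallest ratio distance wins; ties go to the more-column factorisation
    pairs.sort(key=lambda rc: (_ratio_distance(rc[1], rc[0], aspect), -rc[1]))
    best_rows, best_cols = pairs[0]
    best_err = _ratio_distance(best_cols, best_rows, aspect)
    if float(best_err) > max_aspect_error:
        nearest = ", ".join(f"{r}x{c}" for r, c in pairs[:3])
        raise ValueError(
            f"no factorisation of {n_points} is within {max_aspect_error}x of "
            f"aspect {aspect_ratio}; nearest achievable: {nearest}"
        )
    return PlateLayout(best_rows, best_cols, pitch_um=pitch_um, origin_um=origin_um)


def position_coords(layout: PlateLayout, pos: GridPosition) -> tuple[float, float]:
    """Physical ``(x, y)`` of a grid node in micrometres."""
    if not (0 <= pos.row < layout.n_rows and 0 <= pos.col < layout.n_cols):
        raise ValueError(
            f"position ({pos.row}, {pos.col}) outside "
            f"{layout.n_rows}x{layout.n_cols} layout"
        )
    ox, oy = layout.origin_um
    return (ox + pos.col * layout.pitch_um, oy + pos.row * layout.pitch_um)


def assign_blocks(layout: PlateLayout, block_rows: int, block_cols: int) -> PlateLayout:
    """Return the layout sub-formatted into ``block_rows x block_cols`` blocks.

    Every node belongs to exactly one block
    (``block_id = (row // block_rows) * ceil(n_cols/block_cols) + col // block_cols``);
    blocks at the right/bottom edges may be ragged.
    """
    if block_rows < 1 or block_cols < 1:
        raise ValueError("block dimensions must be >= 1")
    return replace(layout, block_rows=block_rows, block_cols=block_cols)


def density(
    n_colonies: int, width_mm: float, height_mm: float, *, rounded: bool = False
) -> float | int:
    """Colony density in colonies/cm^2 over a ``width_mm x height_mm`` area.

    Full precision is returned by default; ``rounded=True`` gives the
    nearest-integer report style (1,300 colonies in 22x15 mm -> 394).
    """
    if width_mm <= 0 or height_mm <= 0:
        raise ValueError("plate area must be positive")
    if n_colonies < 0:
        raise ValueError("n_colonies must be non-negative")
    d = n_colonies / (width_mm * height_mm / 100.0)
    return round(d) if rounded else d


def expected_colonies(n_positions: int, viability: float) -> int:
    """Expected colony count at a given deposition viability (default era: 94%)."""
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    if not 0.0 <= viability <= 1.0:
        raise ValueError("viability must lie in [0, 1]")
    return round(n_positions * viability)
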