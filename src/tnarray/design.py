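"""Combinatorial pooling geometry for arrayed mutant libraries.

An ordered library lives in a grid of multi-well plates: ``grid_rows x
grid_cols`` plates, each with ``plate_rows x plate_cols`` wells.  Every well
belongs to exactly four pools, one per coordinate axis:

* ``WELL_COL``  -- all wells sharing a well column, across every plate;
* ``WELL_ROW``  -- all wells sharing a well row, across every plate;
* ``PLATE_COL`` -- every well of every plate in one column of the plate grid;
* ``PLATE_ROW`` -- every well of every plate in one row of the plate grid.

Sequencing each pool and intersecting the four axes uniquely identifies the
well that holds a given insertion mutant.  The classic geometry is a 19 x 19
grid of 96-well (8 x 12) plates: 34,656 wells addressed by
12 + 8 + 19 + 19 = 58 pools.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Mapping

__all__ = [
    "AXES",
    "DesignError",
    "AddressError",
    "WellAddress",
    "PoolingDesign",
    "build_design",
    "pools_for_well",
    "capacity",
    "row_label",
    "row_index",
]

#: Axis identifiers in canonical order (also the column order of count tables).
AXES = ("WELL_COL", "WELL_ROW", "PLATE_COL", "PLATE_ROW")

_PREFIX = {"WELL_COL": "WC", "WELL_ROW": "WR", "PLATE_COL": "PC", "PLATE_ROW": "PR"}


class DesignError(ValueError):
    """Raised for an invalid pooling geometry."""


class AddressError(ValueError):
    """Raised for a well address outside the design bounds."""


def row_label(i: int) -> str:
    """1-based row index -> spreadsheet-style letter label (1 -> A, 27 -> AA)."""
    if i < 1:
        raise ValueError(f"row index must be >= 1, got {i}")
    out = ""
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("A") + rem) + out
    return out


def row_index(label: str) -> int:
    """Letter label -> 1-based row index (A -> 1, H -> 8, AA -> 27)."""
    label = label.strip().upper()
    if not label or not label.isalpha():
        raise ValueError(f"not a row label: {label!r}")
    i = 0
    for ch in label:
        i = i * 26 + (ord(ch) - ord("A") + 1)
    return i


@dataclass(frozen=True, order=True)
class WellAddress:
    """A single well: plate-grid coordinates plus within-plate coordinates.

    All four coordinates are 1-based; ``well_row`` is stored numerically and
    rendered as a letter (``well_row_label``) following 96-well convention.
    """

    plate_row: int
    plate_col: int
    well_row: int
    well_col: int

    @property
    def well_row_label(self) -> str:
        return row_label(self.well_row)

    def __str__(self) -> str:  # e.g. P03-07:B9
        return (
            f"P{self.plate_row:02d}-{self.plate_col:02d}"
            f":{self.well_row_label}{self.well_col}"
        )


@dataclass(frozen=True)
class PoolingDesign:
    """Geometry of the plate grid and the four pooling axes.

    Parameters
    ----------
    grid_rows, grid_cols:
        Shape of the higher-order plate array.
    plate_rows, plate_cols:
        Wells per plate (8 x 12 for a 96-well plate).
    occupied_plates:
        Optional subset of ``(plate_row, plate_col)`` pairs actually used;
        ``None`` means the full grid.  Pools of absent plates simply receive
        no members.
    """

    grid_rows: int
    grid_cols: int
    plate_rows: int
    plate_cols: int
    occupied_plates: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        for name in ("grid_rows", "grid_cols", "plate_rows", "plate_cols"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise DesignError(f"{name} must be a positive integer, got {v!r}")
        if self.occupied_plates is not None:
            occ = tuple(sorted(set(map(tuple, self.occupied_plates))))
            for pr, pc in occ:
                if not (1 <= pr <= self.grid_rows and 1 <= pc <= self.grid_cols):
                    raise DesignError(f"occupied plate {(pr, pc)} outside grid")
            if not occ:
                raise DesignError("occupied_plates must not be empty when given")
            object.__setattr__(self, "occupied_plates", occ)

    # -- axis geometry -----------------------------------------------------

    def axis_size(self, axis: str) -> int:
        return {
            "WELL_COL": self.plate_cols,
            "WELL_ROW": self.plate_rows,
            "PLATE_COL": self.grid_cols,
            "PLATE_ROW": self.grid_rows,
        }[axis]

    def pool_name(self, axis: str, coord: int) -> str:
        size = self.axis_size(axis)
        if not 1 <= coord <= size:
            raise AddressError(f"{axis} coordinate {coord} outside 1..{size}")
        if axis == "WELL_ROW":
            return _PREFIX[axis] + row_label(coord)
        width = max(2, len(str(size)))
        return f"{_PREFIX[axis]}{coord:0{width}d}"

    @property
    def pools_by_axis(self) -> Mapping[str, tuple[str, ...]]:
        return {
            axis: tuple(
                self.pool_name(axis, c) for c in range(1, self.axis_size(axis) + 1)
            )
            for axis in AXES
        }

    @property
    def pools(self) -> tuple[str, ...]:
        """All pool identifiers, WELL_COL then WELL_ROW then PLATE_COL then PLATE_ROW."""
        by_axis = self.pools_by_axis
        return tuple(itertools.chain.from_iterable(by_axis[a] for a in AXES))

    @property
    def n_pools(self) -> int:
        return self.plate_cols + self.plate_rows + self.grid_cols + self.grid_rows

    def axis_coord(self, pool: str) -> tuple[str, int]:
        """Inverse of :meth:`pool_name`: pool identifier -> (axis, coordinate)."""
        for axis, prefix in _PREFIX.items():
            if pool.startswith(prefix):
                body = pool[len(prefix):]
                coord = row_index(body) if axis == "WELL_ROW" else int(body)
                if 1 <= coord <= self.axis_size(axis):
                    return axis, coord
        raise AddressError(f"unknown pool identifier {pool!r}")

    # -- wells -------------------------------------------------------------

    @property
    def capacity(self) -> int:
        """Number of wells (respecting the occupied-plate subset, if any)."""
        n_plates = (
            self.grid_rows * self.grid_cols
            if self.occupied_plates is None
            else len(self.occupied_plates)
        )
        return n_plates * self.plate_rows * self.plate_cols

    def plate_occupied(self, plate_row: int, plate_col: int) -> bool:
        if self.occupied_plates is None:
            return 1 <= plate_row <= self.grid_rows and 1 <= plate_col <= self.grid_cols
        return (plate_row, plate_col) in self.occupied_plates

    def validate_well(self, well: WellAddress) -> None:
        ok = (
            1 <= well.plate_row <= self.grid_rows
            and 1 <= well.plate_col <= self.grid_cols
            and 1 <= well.well_row <= self.plate_rows
            and 1 <= well.well_col <= self.plate_cols
            and self.plate_occupied(well.plate_row, well.plate_col)
        )
        if not ok:
            raise AddressError(f"well {well} outside design bounds")

    def iter_wells(self) -> Iterator[WellAddress]:
        """Wells in plate order: plate row, plate column, well row, well column."""
        plates = (
            self.occupied_plates
            if self.occupied_plates is not None
            else tuple(
                itertools.product(
                    range(1, self.grid_rows + 1), range(1, self.grid_cols + 1)
                )
            )
        )
        for pr, pc in plates:
            for wr in range(1, self.plate_rows + 1):
                for wc in range(1, self.plate_cols + 1):
                    yield WellAddress(pr, pc, wr, wc)

    def pools_for_well(self, well: WellAddress) -> frozenset[str]:
        """The four pools a well belongs to, one per axis."""
        self.validate_well(well)
        return frozenset(
            (
                self.pool_name("WELL_COL", well.well_col),
                self.pool_name("WELL_ROW", well.well_row),
                self.pool_name("PLATE_COL", well.plate_col),
                self.pool_name("PLATE_ROW", well.plate_row),
            )
        )

    def well_from_coords(
        self, well_col: int, well_row: int, plate_col: int, plate_row: int
    ) -> WellAddress:
        well = WellAddress(plate_row, plate_col, well_row, well_col)
        self.validate_well(well)
        return well

    def well_from_pools(self, pools: frozenset[str] | set[str]) -> WellAddress:
        """Intersect one pool per axis back into the unique well address."""
        coords: dict[str, int] = {}
        for pool in pools:
            axis, coord = self.axis_coord(pool)
            if axis in coords:
                raise AddressError(f"two pools on axis {axis}")
            coords[axis] = coord
        if set(coords) != set(AXES):
            raise AddressError(f"need one pool per axis, got {sorted(pools)}")
        return self.well_from_coords(
            coords["WELL_COL"], coords["WELL_ROW"], coords["PLATE_COL"], coords["PLATE_ROW"]
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "plate_rows": self.plate_rows,
            "plate_cols": self.plate_cols,
        }
        if self.occupied_plates is not None:
            d["occupied_plates"] = [list(p) for p in self.occupied_plates]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PoolingDesign":
        occ = d.get("occupied_plates")
        return cls(
            grid_rows=int(d["grid_rows"]),
            grid_cols=int(d["grid_cols"]),
            plate_rows=int(d["plate_rows"]),
            plate_cols=int(d["plate_cols"]),
            occupied_plates=None if occ is None else tuple(tuple(p) for p in occ),
        )


def build_design(
    grid_rows: int,
    grid_cols: int,
    plate_rows: int,
    plate_cols: int,
    occupied_plates: tuple[tuple[int, int], ...] | None = None,
) -> PoolingDesign:
    """Construct a :class:`PoolingDesign`; raises :class:`DesignError` on bad dims."""
    return PoolingDesign(grid_rows, grid_cols, plate_rows, plate_cols, occupied_plates)


def pools_for_well(design: PoolingDesign, well: WellAddress) -> frozenset[str]:
    return design.pools_for_well(well)


def capacity(design: PoolingDesign) -> int:
    return design.capacity
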