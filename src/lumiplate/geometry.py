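"""LED-lattice and labware geometry.

The stimulation device is a 32 x 64 RGB LED matrix with a 3 mm pitch
(physical active area 192 x 96 mm).  Multiwell plates are laid on top of
the matrix, aligned to its upper-left corner; illumination targets given
as plate-level keywords (a well address, a row, a whole plate, ...) are
resolved here into concrete sets of LED coordinates.

Coordinate conventions
----------------------
* LED indices are 0-based, row-major, origin at the matrix top-left.
* Physical positions are millimetres from the same top-left corner;
  x runs along columns, y along rows.  The LED at (row, col) has its
  centre at ``(pitch*col + pitch/2, pitch*row + pitch/2)``.
* Wells are addressed 1-based, letter (row) + number (column); both
  "A2" and "A02" are accepted.

The 3 mm pitch aligns exactly with the 9 mm pitch of a 96-well plate, so
every 96-well well sits over a 2 x 2 block of LEDs.  Other plate formats
have pitches that are not multiples of 3 mm; by default each well centre
is therefore snapped to the nearest point of the 3 mm sub-lattice of
2 x 2-cell midpoints ("per-well snapping") so that all wells of a format
receive congruent LED patterns.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "MatrixSpec",
    "PlateFormat",
    "Placement",
    "LedSet",
    "Well",
    "Row",
    "Column",
    "Plate",
    "Whole",
    "Rect",
    "Circle",
    "LedList",
    "TargetSpec",
    "GeometryError",
    "AddressError",
    "EmptyTargetWarning",
    "load_registry",
    "default_registry",
    "default_placement",
    "parse_well_address",
    "format_well_address",
    "led_center",
    "well_center",
    "resolve_target",
    "validate_placement",
    "outline_set",
    "led_set_to_csv",
    "led_set_to_plate_map",
]


class GeometryError(ValueError):
    """Invalid geometric input (out-of-bounds index, bad placement...)."""


class AddressError(GeometryError):
    """Well address does not exist in the plate format."""


class EmptyTargetWarning(UserWarning):
    """A target resolved to an empty LED set."""


LedSet = frozenset  # of (row, col) int pairs


@dataclass(frozen=True)
class MatrixSpec:
    """Physical description of the LED matrix.

    Defaults describe the 32 x 64, 3 mm pitch RGB module used by the
    device: 256 intensity levels per channel, blue calibrated to a
    maximum power density of 135 uW/cm2, with peak emission wavelengths
    620-630 nm (red), 520-525 nm (green) and 465-470 nm (blue).
    """

    n_rows: int = 32
    n_cols: int = 64
    pitch_mm: float = 3.0
    channels: tuple[str, ...] = ("red", "green", "blue")
    intensity_levels: int = 256
    max_power_uW_cm2: Mapping[str, float] = field(
        default_factory=lambda: {"blue": 135.0}
    )
    peak_wavelength_nm: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "red": (620.0, 630.0),
            "green": (520.0, 525.0),
            "blue": (465.0, 470.0),
        }
    )

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise GeometryError("matrix dimensions must be positive")
        if self.pitch_mm <= 0:
            raise GeometryError("pitch_mm must be positive")
        if self.intensity_levels != 256:
            raise GeometryError("the hardware exposes exactly 256 intensity levels")
        for ch, p in self.max_power_uW_cm2.items():
            if p < 0:
                raise GeometryError(f"negative power density for channel {ch!r}")

    @property
    def n_leds(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def width_mm(self) -> float:
        return self.n_cols * self.pitch_mm

    @property
    def height_mm(self) -> float:
        return self.n_rows * self.pitch_mm

    def in_bounds(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


@dataclass(frozen=True)
class PlateFormat:
    """Well-array geometry of one labware format (ANSI/SLAS-style)."""

    name: str
    n_well_rows: int
    n_well_cols: int
    well_pitch_mm: float
    well_diameter_mm: float
    geometry_kind: Literal["circular_well", "dish", "flask"] = "circular_well"

    def __post_init__(self) -> None:
        if self.well_diameter_mm <= 0:
            raise GeometryError("well diameter must be positive")
        if self.geometry_kind == "circular_well" and (
            self.well_pitch_mm < self.well_diameter_mm
        ):
            raise GeometryError("well pitch must be >= well diameter")
        if self.n_well_rows <= 0 or self.n_well_cols <= 0:
            raise GeometryError("well counts must be positive")

    @property
    def n_wells(self) -> int:
        return self.n_well_rows * self.n_well_cols

    def addresses(self) -> list[str]:
        """All well addresses in row-major order ("A01", "A02", ...)."""
        return [
            format_well_address(r, c)
            for r in range(self.n_well_rows)
            for c in range(self.n_well_cols)
        ]

    def has_address(self, row_idx: int, col_idx: int) -> bool:
        return 0 <= row_idx < self.n_well_rows and 0 <= col_idx < self.n_well_cols


@dataclass(frozen=True)
class Placement:
    """A plate positioned on the matrix.

    ``origin_offset_mm`` is the (x, y) position of the *nominal* centre
    of well A1, measured from the matrix top-left corner.  Under
    ``per_well_snap`` every well centre is independently moved to the
    nearest lattice point with both coordinates a multiple of the LED
    pitch (a 2 x 2-cell midpoint); ``rigid`` keeps nominal centres.
    """

    plate: PlateFormat
    origin_offset_mm: tuple[float, float]
    snap_mode: Literal["per_well_snap", "rigid"] = "per_well_snap"

    def __post_init__(self) -> None:
        x, y = self.origin_offset_mm
        if not (math.isfinite(x) and math.isfinite(y)):
            raise GeometryError("origin offset must be finite")


# ---------------------------------------------------------------------------
# Target keywords (tagged union)


@dataclass(frozen=True)
class Well:
    address: str


@dataclass(frozen=True)
class Row:
    letter: str


@dataclass(frozen=True)
class Column:
    number: int


@dataclass(frozen=True)
class Plate:
    pass


@dataclass(frozen=True)
class Whole:
    pass


@dataclass(frozen=True)
class Rect:
    well_a: str
    well_b: str


@dataclass(frozen=True)
class Circle:
    center_mm: tuple[float, float]
    radius_mm: float


@dataclass(frozen=True)
class LedList:
    coords: tuple[tuple[int, int], ...]


TargetSpec = Union[Well, Row, Column, Plate, Whole, Rect, Circle, LedList]


# ---------------------------------------------------------------------------
# Well addressing

_ADDRESS_RE = re.compile(r"^([A-Z])([0-9]{1,2})$")


def parse_well_address(address: str) -> tuple[int, int]:
    """Parse "A2"/"A02" into 0-based (row, col) well indices."""
    m = _ADDRESS_RE.match(address.strip().upper())
    if not m:
        raise AddressError(f"malformed well address: {address!r}")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2)) - 1
    if col < 0:
        raise AddressError(f"well column must be >= 1: {address!r}")
    return row, col


def format_well_address(row_idx: int, col_idx: int) -> str:
    return f"{chr(ord('A') + row_idx)}{col_idx + 1:02d}"


# ---------------------------------------------------------------------------
# Plate registry

_DEFAULT_REGISTRY: dict[str, PlateFormat] | None = None


def load_registry(source) -> dict[str, PlateFormat]:
    """Load a plate registry from a YAML mapping (path, file or text).

    Layout::

        plates:
          96-well: {n_well_rows: 8, n_well_cols: 12, well_pitch_mm: 9.0,
                    well_diameter_mm: 6.38, geometry_kind: circular_well}
    """
    if hasattr(source, "read"):
        data = yaml.safe_load(source)
    elif "\n" in str(source):  # inline YAML text
        data = yaml.safe_load(str(source))
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    plates = {}
    for name, spec in data["plates"].items():
        plates[name] = PlateFormat(name=name, **spec)
    return plates


def default_registry() -> dict[str, PlateFormat]:
    """The built-in registry: 6/12/24/48/96-well plates and a 100 mm dish.

    96-well dimensions (9 mm pitch, 6.38 mm well diameter) are anchored to
    the device's characterization; the remaining formats use common
    ANSI/SLAS-footprint catalogue values and can be overridden via
    :func:`load_registry`.
    """
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        text = resources.files("lumiplate").joinpath("data/plates.yaml").read_text()
        data = yaml.safe_load(text)
        _DEFAULT_REGISTRY = {
            name: PlateFormat(name=name, **spec) for name, spec in data["plates"].items()
        }
    return dict(_DEFAULT_REGISTRY)


def _snap_to_lattice(value_mm: float, pitch_mm: float) -> float:
    # nearest multiple of the pitch; numpy round => half-to-even tie-break
    return float(np.round(value_mm / pitch_mm) * pitch_mm)


def default_placement(
    plate: PlateFormat,
    matrix: MatrixSpec | None = None,
    snap_mode: Literal["per_well_snap", "rigid"] = "per_well_snap",
) -> Placement:
    """Corner-aligned placement: well A1 half a well diameter from the
    matrix top-left corner, snapped to the nearest 2 x 2-cell midpoint.

    For the 96-well format this puts A1 at (3.0, 3.0) mm, which centres
    a 2 x 2 LED block in every well.  The 0.19 mm overhang of the
    6.38 mm well past the matrix edge loses no assigned LED.
    """
    matrix = matrix or MatrixSpec()
    half = plate.well_diameter_mm / 2.0
    origin = (
        _snap_to_lattice(half, matrix.pitch_mm),
        _snap_to_lattice(half, matrix.pitch_mm),
    )
    return Placement(plate=plate, origin_offset_mm=origin, snap_mode=snap_mode)


# ---------------------------------------------------------------------------
# Coordinate operations


def led_center(matrix: MatrixSpec, row: int, col: int) -> tuple[float, float]:
    """Physical (x, y) centre of an LED, in mm from the top-left corner."""
    if not matrix.in_bounds(row, col):
        raise GeometryError(f"LED index out of bounds: ({row}, {col})")
    p = matrix.pitch_mm
    return (p * col + p / 2.0, p * row + p / 2.0)


def well_center(
    placement: Placement,
    address: str,
    matrix: MatrixSpec | None = None,
) -> tuple[float, float]:
    """Physical (x, y) centre of a well, after snapping if enabled."""
    matrix = matrix or MatrixSpec()
    row, col = parse_well_address(address)
    plate = placement.plate
    if not plate.has_address(row, col):
        raise AddressError(f"well {address!r} does not exist on {plate.name}")
    ox, oy = placement.origin_offset_mm
    x = ox + col * plate.well_pitch_mm
    y = oy + row * plate.well_pitch_mm
    if placement.snap_mode == "per_well_snap":
        x = _snap_to_lattice(x, matrix.pitch_mm)
        y = _snap_to_lattice(y, matrix.pitch_mm)
    return (x, y)


def _leds_in_circle(
    cx: float,
    cy: float,
    radius_mm: float,
    matrix: MatrixSpec,
    clip: bool = True,
) -> set[tuple[int, int]]:
    """LEDs whose centres lie strictly within the circle.

    With ``clip=False`` out-of-bounds lattice points are included, which
    lets callers detect truncation by the matrix boundary.
    """
    p = matrix.pitch_mm
    r2 = radius_mm * radius_mm
    c_lo = math.floor((cx - radius_mm) / p - 0.5)
    c_hi = math.ceil((cx + radius_mm) / p + 0.5)
    r_lo = math.floor((cy - radius_mm) / p - 0.5)
    r_hi = math.ceil((cy + radius_mm) / p + 0.5)
    out = set()
    for row in range(r_lo, r_hi + 1):
        y = p * row + p / 2.0
        dy2 = (y - cy) ** 2
        for col in range(c_lo, c_hi + 1):
            x = p * col + p / 2.0
            if (x - cx) ** 2 + dy2 < r2:
                if clip and not matrix.in_bounds(row, col):
                    continue
                out.add((row, col))
    return out


def _well_leds(
    placement: Placement,
    address: str,
    matrix: MatrixSpec,
    clip: bool = True,
) -> set[tuple[int, int]]:
    cx, cy = well_center(placement, address, matrix)
    radius = placement.plate.well_diameter_mm / 2.0
    return _leds_in_circle(cx, cy, radius, matrix, clip=clip)


def resolve_target(
    target: TargetSpec,
    placement: Placement | None = None,
    matrix: MatrixSpec | None = None,
) -> LedSet:
    """Resolve a target keyword to the set of LED (row, col) coordinates.

    A well covers every LED whose centre lies strictly within the well
    radius of the (snapped) well centre; rows, columns, rectangles and
    the whole plate are unions of wells.  An empty resolution emits an
    :class:`EmptyTargetWarning` rather than failing silently.
    """
    matrix = matrix or MatrixSpec()

    def need_placement() -> Placement:
        if placement is None:
            raise GeometryError(f"target {target!r} requires a plate placement")
        return placement

    if isinstance(target, Whole):
        leds = {
            (r, c) for r in range(matrix.n_rows) for c in range(matrix.n_cols)
        }
    elif isinstance(target, Well):
        leds = _well_leds(need_placement(), target.address, matrix)
    elif isinstance(target, Row):
        pl = need_placement()
        row_idx = ord(target.letter.upper()) - ord("A")
        if not 0 <= row_idx < pl.plate.n_well_rows:
            raise AddressError(f"row {target.letter!r} does not exist on {pl.plate.name}")
        leds = set()
        for col in range(pl.plate.n_well_cols):
            leds |= _well_leds(pl, format_well_address(row_idx, col), matrix)
    elif isinstance(target, Column):
        pl = need_placement()
        col_idx = target.number - 1
        if not 0 <= col_idx < pl.plate.n_well_cols:
            raise AddressError(f"column {target.number} does not exist on {pl.plate.name}")
        leds = set()
        for row in range(pl.plate.n_well_rows):
            leds |= _well_leds(pl, format_well_address(row, col_idx), matrix)
    elif isinstance(target, Plate):
        pl = need_placement()
        leds = set()
        for addr in pl.plate.addresses():
            leds |= _well_leds(pl, addr, matrix)
    elif isinstance(target, Rect):
        pl = need_placement()
        r1, c1 = parse_well_address(target.well_a)
        r2, c2 = parse_well_address(target.well_b)
        leds = set()
        for r in range(min(r1, r2), max(r1, r2) + 1):
            for c in range(min(c1, c2), max(c1, c2) + 1):
                if pl.plate.has_address(r, c):
                    leds |= _well_leds(pl, format_well_address(r, c), matrix)
                else:
                    raise AddressError(
                        f"rectangle corner spans nonexistent well "
                        f"{format_well_address(r, c)} on {pl.plate.name}"
                    )
    elif isinstance(target, Circle):
        leds = _leds_in_circle(
            target.center_mm[0], target.center_mm[1], target.radius_mm, matrix
        )
    elif isinstance(target, LedList):
        for row, col in target.coords:
            if not matrix.in_bounds(row, col):
                raise GeometryError(f"explicit LED out of bounds: ({row}, {col})")
        leds = set(target.coords)
    else:
        raise GeometryError(f"unknown target keyword: {target!r}")

    if not leds:
        warnings.warn(
            f"target {target!r} resolved to an empty LED set", EmptyTargetWarning
        )
    return frozenset(leds)


# ---------------------------------------------------------------------------
# Placement validation and plate outline


@dataclass(frozen=True)
class PlacementFinding:
    kind: Literal["empty_well", "truncated_well", "overlap"]
    placement_index: int
    detail: str


@dataclass
class PlacementReport:
    findings: list[PlacementFinding]

    @property
    def ok(self) -> bool:
        return not self.findings


def validate_placement(
    placements: Sequence[Placement],
    matrix: MatrixSpec | None = None,
) -> PlacementReport:
    """Check placements for empty wells, boundary truncation and
    cross-plate LED sharing (e.g. two plates under one mask)."""
    matrix = matrix or MatrixSpec()
    findings: list[PlacementFinding] = []
    claimed: dict[tuple[int, int], int] = {}
    for i, pl in enumerate(placements):
        plate_leds: set[tuple[int, int]] = set()
        for addr in pl.plate.addresses():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyTargetWarning)
                full = _well_leds(pl, addr, matrix, clip=False)
            clipped = {rc for rc in full if matrix.in_bounds(*rc)}
            if not clipped:
                findings.append(
                    PlacementFinding("empty_well", i, f"well {addr} has no LEDs")
                )
            elif len(clipped) < len(full):
                findings.append(
                    PlacementFinding(
                        "truncated_well",
                        i,
                        f"well {addr} loses {len(full) - len(clipped)} LED(s) "
                        "past the matrix boundary",
                    )
                )
            plate_leds |= clipped
        for rc in sorted(plate_leds):
            if rc in claimed and claimed[rc] != i:
                findings.append(
                    PlacementFinding(
                        "overlap",
                        i,
                        f"LED {rc} also claimed by placement {claimed[rc]}",
                    )
                )
            else:
                claimed[rc] = i
    return PlacementReport(findings)


def outline_set(
    placement: Placement, matrix: MatrixSpec | None = None
) -> LedSet:
    """Perimeter LEDs of the bounding rectangle of the plate's well LEDs.

    Used as an alignment aid: the outline is displayed on the matrix so
    the operator can position the plate in a dark incubator.
    """
    matrix = matrix or MatrixSpec()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptyTargetWarning)
        all_leds = resolve_target(Plate(), placement, matrix)
    if not all_leds:
        return frozenset()
    rows = [r for r, _ in all_leds]
    cols = [c for _, c in all_leds]
    r0, r1, c0, c1 = min(rows), max(rows), min(cols), max(cols)
    perim = {
        (r, c)
        for r in range(r0, r1 + 1)
        for c in range(c0, c1 + 1)
        if r in (r0, r1) or c in (c0, c1)
    }
    return frozenset(perim)


# ---------------------------------------------------------------------------
# Exports


def led_set_to_csv(leds: Iterable[tuple[int, int]]) -> str:
    """Serialize an LED set as ``row,col`` lines (sorted, with header)."""
    lines = ["row,col"]
    lines += [f"{r},{c}" for r, c in sorted(leds)]
    return "\n".join(lines) + "\n"


def led_set_to_plate_map(
    leds: Iterable[tuple[int, int]], matrix: MatrixSpec | None = None
) -> str:
    """Plain-text map of the matrix: '#' for member LEDs, '.' otherwise."""
    matrix = matrix or MatrixSpec()
    members = set(leds)
    rows = []
    for r in range(matrix.n_rows):
        rows.append(
            "".join("#" if (r, c) in members else "." for c in range(matrix.n_cols))
        )
    return "\n".join(rows) + "\n"
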