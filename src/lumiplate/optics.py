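"""Sample-plane irradiance, homogeneity, spillover and light dose.

Each LED is modelled as a generalized-Lambertian point emitter whose
radiant intensity falls off as cos^m of the emission angle.  At height
``h`` above the matrix and lateral offset ``r`` from the LED axis, a
single full-intensity LED contributes an irradiance

    E(r, h) = S * h^(m+1) / (r^2 + h^2)^((m+3)/2)

(the cos^m angular profile times the cos/d^2 projection onto the
horizontal sample plane).  ``S`` is fixed by calibration so that one
full-intensity LED produces the measured on-axis power density at the
calibration height — by default 135 uW/cm2 for blue at 2 mm, the
sample-to-matrix distance of a standard 96-well plate.  Multiple LEDs
superpose linearly.

The single exponent ``m`` is the only free shape parameter (default 1);
it can be fitted with :func:`calibrate_emission` so the model reproduces
a measured within-well inhomogeneity, e.g. the characteristic 25 %
centre-to-edge variation of a 96-well well at 2 mm.

Irradiance integrals are evaluated by summation on a regular grid
(default 0.25 mm resolution), which is deterministic and accurate to
well below the model's own uncertainty.
"""

from __future__ import annotations

import csv
import io
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import geometry
from .geometry import (
    EmptyTargetWarning,
    MatrixSpec,
    Placement,
    TargetSpec,
    led_center,
    resolve_target,
    well_center,
)
from .program import Color, Command, Program
from .scheduler import FrameTimeline

__all__ = [
    "EmissionModel",
    "IrradianceField",
    "WellDoseReport",
    "OpticsError",
    "CalibrationError",
    "irradiance_field",
    "homogeneity",
    "block_homogeneity",
    "spillover",
    "spillover_at",
    "calibrate_emission",
    "well_dose",
    "dose_at_calibration",
    "gradient_program",
]


#: Default within-well inhomogeneity target for :func:`calibrate_emission`,
#: the characteristic measured centre-to-edge variation of a 96-well well
#: at its 2 mm working distance.  Note that an isolated 2 x 2 block of
#: cos^m point emitters cannot be this uniform at 2 mm for any m >= 0
#: (the reachable floor is V ~= 0.47), so calibrating to this target at
#: 2 mm raises :class:`CalibrationError`; see the methods documentation.
DEFAULT_V_TARGET = 0.25


class OpticsError(ValueError):
    pass


class CalibrationError(OpticsError):
    pass


@dataclass(frozen=True)
class EmissionModel:
    """Generalized-Lambertian emitter with on-axis calibration.

    Parameters
    ----------
    exponent_m:
        Angular order of the cos^m profile; larger m = narrower beam.
    calib_power_uW_cm2:
        Per-channel on-axis irradiance (uW/cm2) of one full-intensity
        LED at the calibration height.  Only channels listed here can be
        converted to physical units; by default only blue is calibrated.
    calib_height_mm:
        Height of the calibration plane above the LED matrix.
    """

    exponent_m: float = 1.0
    calib_power_uW_cm2: Mapping[str, float] = field(
        default_factory=lambda: {"blue": 135.0}
    )
    calib_height_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.exponent_m < 0:
            raise OpticsError("exponent_m must be >= 0")
        if self.calib_height_mm <= 0:
            raise OpticsError("calibration height must be positive")
        if not any(p > 0 for p in self.calib_power_uW_cm2.values()):
            raise OpticsError("at least one channel needs a positive calibration")

    def channel_power(self, channel: str) -> float:
        try:
            return self.calib_power_uW_cm2[channel]
        except KeyError:
            raise OpticsError(f"channel {channel!r} has no calibration") from None

    def kernel(self, dx_mm, dy_mm, h_mm: float, channel: str = "blue"):
        """Irradiance (uW/cm2) of one full-intensity LED at lateral
        offset (dx, dy) and height h."""
        if h_mm <= 0:
            raise OpticsError("height above the matrix must be positive")
        m = self.exponent_m
        s = self.channel_power(channel) * self.calib_height_mm**2
        d2 = np.asarray(dx_mm) ** 2 + np.asarray(dy_mm) ** 2 + h_mm**2
        return s * h_mm ** (m + 1) / d2 ** ((m + 3) / 2.0)


@dataclass
class IrradianceField:
    """Irradiance sampled on a regular grid over a sample-plane window.

    ``values[j, i]`` is the irradiance (uW/cm2) at
    ``x = x0 + (i + 0.5) * res_mm``, ``y = y0 + (j + 0.5) * res_mm``.
    """

    values: np.ndarray
    x0_mm: float
    y0_mm: float
    res_mm: float
    h_mm: float
    channel: str

    @property
    def x_mm(self) -> np.ndarray:
        return self.x0_mm + (np.arange(self.values.shape[1]) + 0.5) * self.res_mm

    @property
    def y_mm(self) -> np.ndarray:
        return self.y0_mm + (np.arange(self.values.shape[0]) + 0.5) * self.res_mm

    def interp(self, x_mm, y_mm):
        """Bilinear interpolation of the field at arbitrary points."""
        x = (np.asarray(x_mm, dtype=float) - self.x0_mm) / self.res_mm - 0.5
        y = (np.asarray(y_mm, dtype=float) - self.y0_mm) / self.res_mm - 0.5
        ny, nx = self.values.shape
        i0 = np.clip(np.floor(x).astype(int), 0, nx - 2)
        j0 = np.clip(np.floor(y).astype(int), 0, ny - 2)
        fx = np.clip(x - i0, 0.0, 1.0)
        fy = np.clip(y - j0, 0.0, 1.0)
        v = self.values
        return (
            v[j0, i0] * (1 - fx) * (1 - fy)
            + v[j0, i0 + 1] * fx * (1 - fy)
            + v[j0 + 1, i0] * (1 - fx) * fy
            + v[j0 + 1, i0 + 1] * fx * fy
        )

    def integrate(self, mask: np.ndarray | None = None) -> float:
        """Integrated irradiance x area (uW/cm2 * mm2) over the window
        (or over a boolean mask on the grid)."""
        cell = self.res_mm**2
        if mask is None:
            return float(self.values.sum() * cell)
        return float(self.values[mask].sum() * cell)

    def to_csv(self) -> str:
        out = io.StringIO()
        np.savetxt(out, self.values, fmt="%.6g", delimiter=",")
        return out.getvalue()

    def to_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        extent = (
            self.x0_mm,
            self.x0_mm + self.values.shape[1] * self.res_mm,
            self.y0_mm + self.values.shape[0] * self.res_mm,
            self.y0_mm,
        )
        im = ax.imshow(self.values, extent=extent, cmap="viridis")
        fig.colorbar(im, ax=ax, label="irradiance (uW/cm$^2$)")
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


def irradiance_field(
    frame: np.ndarray,
    h_mm: float,
    model: EmissionModel | None = None,
    window: tuple[float, float, float, float] | None = None,
    res_mm: float = 0.25,
    matrix: MatrixSpec | None = None,
    channel: str = "blue",
) -> IrradianceField:
    """Simulate the sample-plane irradiance of one displayed frame.

    ``frame`` is a (n_rows, n_cols, 3) intensity grid; ``window`` is
    (x0, y0, x1, y1) in mm (default: the whole matrix).  Each lit LED
    contributes its kernel scaled by intensity/255; contributions add.
    """
    model = model or EmissionModel()
    matrix = matrix or MatrixSpec()
    if h_mm <= 0:
        raise OpticsError("height above the matrix must be positive")
    if window is None:
        window = (0.0, 0.0, matrix.width_mm, matrix.height_mm)
    x0, y0, x1, y1 = window
    if x1 <= x0 or y1 <= y0:
        raise OpticsError(f"degenerate window {window}")
    ch_idx = matrix.channels.index(channel)
    nx = max(1, round((x1 - x0) / res_mm))
    ny = max(1, round((y1 - y0) / res_mm))
    xs = x0 + (np.arange(nx) + 0.5) * res_mm
    ys = y0 + (np.arange(ny) + 0.5) * res_mm
    X, Y = np.meshgrid(xs, ys)
    values = np.zeros((ny, nx), dtype=float)
    levels = np.asarray(frame)[:, :, ch_idx]
    rows, cols = np.nonzero(levels)
    for r, c in zip(rows.tolist(), cols.tolist()):
        lx, ly = led_center(matrix, r, c)
        values += (levels[r, c] / 255.0) * model.kernel(X - lx, Y - ly, h_mm, channel)
    return IrradianceField(values, x0, y0, res_mm, h_mm, channel)


# ---------------------------------------------------------------------------
# Homogeneity


def homogeneity(
    field: IrradianceField,
    well_center_mm: tuple[float, float],
    well_radius_mm: float,
    n_boundary: int = 360,
) -> float:
    """Within-well inhomogeneity V = 1 - min(edge)/centre, in [0, 1].

    V = 0 means perfectly uniform illumination across the well; V = 0.25
    means the darkest point on the well edge receives 25 % less light
    than the well centre.
    """
    cx, cy = well_center_mm
    x_lo, x_hi = field.x0_mm, field.x0_mm + field.values.shape[1] * field.res_mm
    y_lo, y_hi = field.y0_mm, field.y0_mm + field.values.shape[0] * field.res_mm
    if (
        cx - well_radius_mm < x_lo
        or cx + well_radius_mm > x_hi
        or cy - well_radius_mm < y_lo
        or cy + well_radius_mm > y_hi
    ):
        raise OpticsError("well footprint extends outside the field window")
    center = float(field.interp(cx, cy))
    if center <= 0:
        raise OpticsError("zero irradiance at the well centre: V undefined")
    theta = np.linspace(0.0, 2.0 * np.pi, n_boundary, endpoint=False)
    edge = field.interp(
        cx + well_radius_mm * np.cos(theta), cy + well_radius_mm * np.sin(theta)
    )
    v = 1.0 - float(np.min(edge)) / center
    return float(np.clip(v, 0.0, 1.0))


def block_homogeneity(
    model: EmissionModel,
    h_mm: float,
    well_radius_mm: float,
    pitch_mm: float = 3.0,
    channel: str = "blue",
    n_boundary: int = 720,
) -> float:
    """V for an isolated 2 x 2 LED block centred in a circular well.

    Evaluates the emission kernel directly (no grid), which makes it
    cheap enough to sit inside the calibration bisection loop.
    """
    half = pitch_mm / 2.0
    offsets = [(-half, -half), (-half, half), (half, -half), (half, half)]

    def total(x, y):
        return sum(model.kernel(x - ox, y - oy, h_mm, channel) for ox, oy in offsets)

    center = float(total(0.0, 0.0))
    theta = np.linspace(0.0, 2.0 * np.pi, n_boundary, endpoint=False)
    edge = total(well_radius_mm * np.cos(theta), well_radius_mm * np.sin(theta))
    v = 1.0 - float(np.min(edge)) / center
    return float(np.clip(v, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Spillover


def _well_masks(
    field: IrradianceField, placement: Placement, matrix: MatrixSpec
) -> dict[str, np.ndarray]:
    X, Y = np.meshgrid(field.x_mm, field.y_mm)
    r2 = (placement.plate.well_diameter_mm / 2.0) ** 2
    masks = {}
    for addr in placement.plate.addresses():
        cx, cy = well_center(placement, addr, matrix)
        masks[addr] = (X - cx) ** 2 + (Y - cy) ** 2 < r2
    return masks


def spillover(
    field: IrradianceField,
    placement: Placement,
    source_well: str,
    matrix: MatrixSpec | None = None,
) -> float:
    """Fraction of in-well light landing outside the source well.

    With only the source well's LEDs lit, integrates the field over
    every well footprint; returns (other wells) / (all wells).  The
    field window must cover all well footprints.
    """
    matrix = matrix or MatrixSpec()
    masks = _well_masks(field, placement, matrix)
    if source_well not in masks:
        src_row, src_col = geometry.parse_well_address(source_well)
        source_well = geometry.format_well_address(src_row, src_col)
    total = sum(field.integrate(m) for m in masks.values())
    if total <= 0:
        return 0.0
    own = field.integrate(masks[source_well])
    return float((total - own) / total)


def spillover_at(
    model: EmissionModel,
    placement: Placement,
    source_well: str,
    h_mm: float,
    res_mm: float = 0.25,
    matrix: MatrixSpec | None = None,
    channel: str = "blue",
) -> float:
    """Spillover of one fully lit well at height h (builds the field)."""
    matrix = matrix or MatrixSpec()
    frame = np.zeros((matrix.n_rows, matrix.n_cols, 3), dtype=np.uint8)
    leds = resolve_target(geometry.Well(source_well), placement, matrix)
    ch_idx = matrix.channels.index(channel)
    for r, c in leds:
        frame[r, c, ch_idx] = 255
    window = _plate_window(placement, matrix)
    field = irradiance_field(frame, h_mm, model, window, res_mm, matrix, channel)
    return spillover(field, placement, source_well, matrix)


def _plate_window(
    placement: Placement, matrix: MatrixSpec
) -> tuple[float, float, float, float]:
    """Bounding window of all well footprints (may overhang the matrix)."""
    radius = placement.plate.well_diameter_mm / 2.0
    centers = [
        well_center(placement, addr, matrix) for addr in placement.plate.addresses()
    ]
    xs = [c[0] for c in centers]
    ys = [c[1] for c in centers]
    return (
        min(xs) - radius,
        min(ys) - radius,
        max(xs) + radius,
        max(ys) + radius,
    )


# ---------------------------------------------------------------------------
# Calibration


def calibrate_emission(
    v_target: float = DEFAULT_V_TARGET,
    h_mm: float = 2.0,
    well_radius_mm: float = 3.19,
    model: EmissionModel | None = None,
    m_range: tuple[float, float] = (0.0, 200.0),
    tol: float = 1e-3,
) -> EmissionModel:
    """Fit the angular exponent m so a 2 x 2 block centred in a well of
    the given radius shows inhomogeneity ``v_target`` at height h.

    The default target geometry is the 96-well well (radius 3.19 mm) at
    its 2 mm working distance, for which the characteristic measured
    value is V = 0.25.  Solved by bisection (V is increasing in m:
    a narrower beam is more centre-weighted); raises
    :class:`CalibrationError` when the target is outside the reachable
    range for m in ``m_range``.
    """
    if not 0.0 < v_target < 1.0:
        raise CalibrationError(f"V target {v_target} outside (0, 1)")
    base = model or EmissionModel()
    lo, hi = m_range

    def v_of(m: float) -> float:
        return block_homogeneity(replace(base, exponent_m=m), h_mm, well_radius_mm)

    v_lo, v_hi = v_of(lo), v_of(hi)
    if not v_lo <= v_target <= v_hi:
        raise CalibrationError(
            f"V target {v_target} unreachable: V({lo}) = {v_lo:.4f}, "
            f"V({hi}) = {v_hi:.4f}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        v_mid = v_of(mid)
        if abs(v_mid - v_target) <= tol:
            return replace(base, exponent_m=mid)
        if v_mid < v_target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection failed to converge")


# ---------------------------------------------------------------------------
# Dose accounting


@dataclass
class WellDoseReport:
    """Per-well illumination summary of a compiled program.

    dose (mJ/cm2) integrates the mean in-well irradiance over every
    second of the timeline, so light spilling over from neighbouring
    wells is counted toward the receiving well.
    """

    h_mm: float
    channel: str
    wells: dict[str, dict] = field(default_factory=dict)

    def to_csv(self) -> str:
        out = io.StringIO()
        writer = csv.writer(out, lineterminator="\n")
        writer.writerow(
            [
                "well",
                "lit_seconds",
                "mean_irradiance_uW_cm2",
                "dose_mJ_cm2",
                "homogeneity",
                "spillover",
            ]
        )
        for addr in sorted(self.wells):
            w = self.wells[addr]
            writer.writerow(
                [
                    addr,
                    w["lit_seconds"],
                    f"{w['mean_irradiance_uW_cm2']:.6g}",
                    f"{w['dose_mJ_cm2']:.6g}",
                    "" if w["homogeneity"] is None else f"{w['homogeneity']:.4f}",
                    "" if w["spillover"] is None else f"{w['spillover']:.4f}",
                ]
            )
        return out.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            {"h_mm": self.h_mm, "channel": self.channel, "wells": self.wells},
            indent=2,
        )


def well_dose(
    timeline: FrameTimeline,
    model: EmissionModel | None = None,
    placement: Placement | None = None,
    h_mm: float = 2.0,
    res_mm: float = 0.5,
    channel: str = "blue",
    with_spillover: bool = True,
) -> WellDoseReport:
    """Integrate per-well light dose over a compiled timeline.

    For every second with any LED lit, the irradiance over each well
    footprint is simulated on a well-local grid and averaged; dose is
    the sum of those means x 1 s (uW/cm2 * s = 1e-3 mJ/cm2).  Identical
    frames (repeated pulses) are simulated only once.
    """
    if placement is None:
        raise OpticsError("well_dose requires a plate placement")
    model = model or EmissionModel()
    matrix = timeline.matrix
    addresses = placement.plate.addresses()
    radius = placement.plate.well_diameter_mm / 2.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptyTargetWarning)
        own_leds = {
            a: resolve_target(geometry.Well(a), placement, matrix)
            for a in addresses
        }

    # per-well local grid over the footprint bounding box: resolves the
    # sharply peaked near field at small h without a huge plate-wide grid
    margin = 3 * res_mm
    local = {}
    for a in addresses:
        cx, cy = well_center(placement, a, matrix)
        x0 = cx - radius - margin
        y0 = cy - radius - margin
        n = max(1, round(2 * (radius + margin) / res_mm))
        xs = x0 + (np.arange(n) + 0.5) * res_mm
        ys = y0 + (np.arange(n) + 0.5) * res_mm
        X, Y = np.meshgrid(xs, ys)
        mask = (X - cx) ** 2 + (Y - cy) ** 2 < radius**2
        local[a] = (x0, y0, X.ravel(), Y.ravel(), mask)

    def frame_means(plane: np.ndarray) -> tuple[np.ndarray, dict]:
        rows, cols = np.nonzero(plane)
        lx = matrix.pitch_mm * cols + matrix.pitch_mm / 2.0
        ly = matrix.pitch_mm * rows + matrix.pitch_mm / 2.0
        weights = plane[rows, cols] / 255.0
        means = np.zeros(len(addresses))
        fields = {}
        for i, a in enumerate(addresses):
            x0, y0, X, Y, mask = local[a]
            d2 = (X[None, :] - lx[:, None]) ** 2 + (Y[None, :] - ly[:, None]) ** 2
            m = model.exponent_m
            s = model.channel_power(channel) * model.calib_height_mm**2
            contrib = (
                s * h_mm ** (m + 1) / (d2 + h_mm**2) ** ((m + 3) / 2.0)
            ) * weights[:, None]
            values = contrib.sum(axis=0).reshape(mask.shape)
            means[i] = values[mask].mean() if mask.any() else 0.0
            fields[a] = IrradianceField(values, x0, y0, res_mm, h_mm, channel)
        return means, fields

    frame_cache: dict[bytes, tuple[np.ndarray, np.ndarray, dict]] = {}
    sums = {addr: 0.0 for addr in addresses}  # all received light -> dose
    sums_direct = {addr: 0.0 for addr in addresses}
    lit = {addr: 0 for addr in addresses}  # seconds with own LEDs driven
    peak = {addr: (0.0, None) for addr in addresses}  # (mean, field)

    ch_idx = matrix.channels.index(channel)
    for t in timeline.lit_seconds:
        frame = timeline.frames[t]
        plane = frame[:, :, ch_idx]
        key = plane.tobytes()
        cached = frame_cache.get(key)
        if cached is None:
            means, fields = frame_means(plane)
            direct = np.array(
                [any(plane[r, c] > 0 for r, c in own_leds[a]) for a in addresses]
            )
            frame_cache[key] = (means, direct, fields)
            cached = (means, direct, fields)
        means, direct, fields = cached
        for a, mean, is_direct in zip(addresses, means, direct):
            sums[a] += float(mean)
            if is_direct:
                sums_direct[a] += float(mean)
                lit[a] += 1
                if mean > peak[a][0]:
                    peak[a] = (float(mean), fields[a])

    # spillover per unique well-LED pattern (wells are congruent under
    # per-well snapping, so usually one field suffices)
    spill: dict[str, float | None] = {a: None for a in addresses}
    if with_spillover:
        shape_cache: dict[frozenset, float] = {}
        for a in addresses:
            if lit[a] == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", EmptyTargetWarning)
                leds = resolve_target(geometry.Well(a), placement, matrix)
            if not leds:
                continue
            r0 = min(r for r, _ in leds)
            c0 = min(c for _, c in leds)
            shape = frozenset((r - r0, c - c0) for r, c in leds)
            if shape not in shape_cache:
                shape_cache[shape] = spillover_at(
                    model, placement, a, h_mm, res_mm, matrix, channel
                )
            spill[a] = shape_cache[shape]

    report = WellDoseReport(h_mm=h_mm, channel=channel)
    radius = placement.plate.well_diameter_mm / 2.0
    for a in addresses:
        homog = None
        if peak[a][1] is not None:
            cx, cy = well_center(placement, a, matrix)
            try:
                homog = homogeneity(peak[a][1], (cx, cy), radius)
            except OpticsError:
                homog = None
        report.wells[a] = {
            "lit_seconds": lit[a],
            "mean_irradiance_uW_cm2": sums_direct[a] / lit[a] if lit[a] else 0.0,
            "dose_mJ_cm2": sums[a] * 1e-3,
            "homogeneity": homog,
            "spillover": spill[a],
        }
    return report


def dose_at_calibration(
    seconds: float,
    model: EmissionModel | None = None,
    channel: str = "blue",
    level: int = 255,
) -> float:
    """Dose (mJ/cm2) of a uniform exposure at the calibration point.

    135 uW/cm2 for 10 s is 1.35 mJ/cm2; dose is linear in duration and
    in intensity level.
    """
    model = model or EmissionModel()
    if not 0 <= level <= 255:
        raise OpticsError(f"intensity level {level} outside 0-255")
    return model.channel_power(channel) * (level / 255.0) * seconds * 1e-3


# ---------------------------------------------------------------------------
# Gradients


def gradient_program(
    region: TargetSpec,
    axis: str,
    start_level: int,
    end_level: int,
    color_channel: str = "blue",
    placement: Placement | None = None,
    matrix: MatrixSpec | None = None,
    start_s: int = 0,
    duration_s: int = 1,
) -> Program:
    """Linear intensity gradient across a region, one command per LED
    column (axis 'x') or row (axis 'y').

    Levels are interpolated between ``start_level`` and ``end_level``
    over the region's extent and rounded to the 256 hardware levels, so
    the sequence is monotone along the axis.
    """
    matrix = matrix or MatrixSpec()
    if axis not in ("x", "y"):
        raise OpticsError(f"axis must be 'x' or 'y', got {axis!r}")
    for lvl in (start_level, end_level):
        if not 0 <= lvl <= 255:
            raise OpticsError(f"gradient level {lvl} outside 0-255")
    if color_channel not in matrix.channels:
        raise OpticsError(f"unknown channel {color_channel!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptyTargetWarning)
        leds = resolve_target(region, placement, matrix)
    if not leds:
        raise OpticsError("gradient region resolves to no LEDs")
    key = (lambda rc: rc[1]) if axis == "x" else (lambda rc: rc[0])
    lines: dict[int, list[tuple[int, int]]] = {}
    for rc in leds:
        lines.setdefault(key(rc), []).append(rc)
    positions = sorted(lines)
    n = len(positions)
    commands = []
    for i, pos in enumerate(positions):
        frac = i / (n - 1) if n > 1 else 0.0
        level = round(start_level + (end_level - start_level) * frac)
        color = Color(**{color_channel: level})
        commands.append(
            Command(
                target=geometry.LedList(tuple(sorted(lines[pos]))),
                start_s=start_s,
                duration_s=duration_s,
                color=color,
            )
        )
    return Program(commands=commands, name=f"gradient-{axis}")
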