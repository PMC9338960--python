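"""Parse, validate and serialize csv illumination programs.

An illumination program is a csv file in which each line is one command:
a target keyword, a start time, a duration, a per-channel intensity, an
optional repetition rule and an optional operator message.  The dialect
used here has the fixed header::

    target,start,duration,red,green,blue,repeats,interval,message,buzzer

* ``target`` — a well address ("A02"/"A2"), a row letter ("D"), a column
  number ("5"), "Plate", "Whole", a well rectangle ("Rec_A1_D4"), a
  circle in mm ("Cir_x_y_r"), or explicit LEDs ("LED_row_col", several
  joined with '+').
* ``start``/``duration``/``interval`` — integer seconds or "HH:MM:SS".
  The firmware's minimum pulse is 1 s, so durations below 1 s are
  rejected (not rounded: silent rounding would distort dose accounting).
* ``red``/``green``/``blue`` — integers 0-255 (256 hardware levels);
  blank means 0.
* ``repeats`` — either a pulse count (integer >= 1) or, when written as
  a time ("HH:MM:SS"), the absolute end time of the loop: pulse k starts
  at ``start + k*interval`` for every k with that start strictly before
  the end time (end-exclusive), i.e. ``ceil((end - start)/interval)``
  pulses.  A 3 s pulse every 5 min with end time 01:00:00 therefore
  fires 12 times.
* ``message``/``buzzer`` — an operator message shown on the control unit
  at the command's start, counting down for the command's duration; the
  buzzer flag sounds at the deadline.

Lines starting with '#' are comments; '#!' comments carry program
metadata (``#! name: ...``, ``#! plate: 96-well``).  Both ',' and ';'
separators are accepted (spreadsheet-locale tolerance).

The explicit-LED, rectangle and circle spellings are this package's own
documented syntax and are not guaranteed portable to any particular
firmware dialect.
"""

from __future__ import annotations

import csv
import io
import json
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

from . import geometry
from .geometry import (
    AddressError,
    Circle,
    Column,
    EmptyTargetWarning,
    LedList,
    MatrixSpec,
    Placement,
    Plate,
    Rect,
    Row,
    TargetSpec,
    Well,
    Whole,
    parse_well_address,
)

__all__ = [
    "Color",
    "NAMED_COLORS",
    "Command",
    "Program",
    "ProgramParseError",
    "MinimumPulseError",
    "IntensityRangeError",
    "TargetSyntaxError",
    "TimeFormatError",
    "parse_target",
    "serialize_target",
    "parse_time_s",
    "format_time_s",
    "parse_program",
    "serialize_program",
    "validate_program",
    "program_to_json",
]

DIALECT_COLUMNS = (
    "target",
    "start",
    "duration",
    "red",
    "green",
    "blue",
    "repeats",
    "interval",
    "message",
    "buzzer",
)
_REQUIRED_COLUMNS = ("target", "start", "duration")


class ProgramParseError(ValueError):
    """Parse/validation failure; carries the offending line and column."""

    def __init__(self, message: str, line: int | None = None, column: str | None = None):
        self.line = line
        self.column = column
        where = ""
        if line is not None:
            where = f" (line {line}" + (f", column {column!r})" if column else ")")
        super().__init__(message + where)


class MinimumPulseError(ProgramParseError):
    """Duration below the 1 s firmware minimum."""


class IntensityRangeError(ProgramParseError):
    """Channel intensity outside the 0-255 hardware range."""


class TargetSyntaxError(ProgramParseError):
    """Unparseable target keyword."""


class TimeFormatError(ProgramParseError):
    """Malformed or sub-second time value."""


@dataclass(frozen=True)
class Color:
    """Per-channel intensity, 0-255 (the hardware's 256 levels)."""

    red: int = 0
    green: int = 0
    blue: int = 0

    def __post_init__(self) -> None:
        for name in ("red", "green", "blue"):
            v = getattr(self, name)
            if not isinstance(v, int) or not 0 <= v <= 255:
                raise IntensityRangeError(
                    f"{name} intensity {v!r} outside 0-255", column=name
                )

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.red, self.green, self.blue)

    @property
    def is_off(self) -> bool:
        return self.as_tuple() == (0, 0, 0)


NAMED_COLORS = {
    "red": Color(255, 0, 0),
    "green": Color(0, 255, 0),
    "blue": Color(0, 0, 255),
    "white": Color(255, 255, 255),
    "cyan": Color(0, 255, 255),
    "magenta": Color(255, 0, 255),
    "yellow": Color(255, 255, 0),
}


@dataclass(frozen=True)
class Command:
    """One illumination command (one csv line)."""

    target: TargetSpec
    start_s: int
    duration_s: int
    color: Color
    repeat_count: int = 1
    repeat_interval_s: int = 0
    message: str | None = None
    buzzer: bool = False

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise ProgramParseError(f"negative start time {self.start_s}")
        if self.duration_s < 1:
            raise MinimumPulseError(
                f"duration {self.duration_s} s below the 1 s minimum pulse"
            )
        if self.repeat_count < 1:
            raise ProgramParseError(f"repeat count must be >= 1, got {self.repeat_count}")
        # a repeat interval shorter than the pulse (self-overlap) is not an
        # error here: validate_program reports it as a finding so a whole
        # program can be checked in one pass

    @property
    def self_overlapping(self) -> bool:
        return self.repeat_count > 1 and self.repeat_interval_s < self.duration_s

    @property
    def end_s(self) -> int:
        """Off-time of the last pulse."""
        return self.start_s + (self.repeat_count - 1) * self.repeat_interval_s + self.duration_s

    def pulse_starts(self) -> list[int]:
        return [
            self.start_s + k * self.repeat_interval_s for k in range(self.repeat_count)
        ]


@dataclass
class Program:
    """An ordered list of commands plus descriptive metadata."""

    commands: list[Command] = field(default_factory=list)
    name: str = ""
    plate_format: str = ""
    placement_note: str = ""
    #: shared endpoint of a reverse (simultaneous-fixation) schedule;
    #: may lie after the last off-time because stimulation-to-fixation
    #: intervals are measured to this time, not to the last pulse
    fixation_horizon_s: int | None = None

    @property
    def horizon_s(self) -> int:
        """Last off-time over all commands (0 for an empty program)."""
        return max((c.end_s for c in self.commands), default=0)


# ---------------------------------------------------------------------------
# Target syntax

_LED_RE = re.compile(r"^LED_(\d+)_(\d+)$", re.IGNORECASE)
_REC_RE = re.compile(r"^REC_([A-Z]\d{1,2})_([A-Z]\d{1,2})$", re.IGNORECASE)
_CIR_RE = re.compile(
    r"^CIR_([0-9.]+)_([0-9.]+)_([0-9.]+)$", re.IGNORECASE
)
_WELL_RE = re.compile(r"^[A-Z]\d{1,2}$", re.IGNORECASE)


def parse_target(text: str) -> TargetSpec:
    """Parse a target keyword from its csv spelling."""
    t = text.strip()
    if not t:
        raise TargetSyntaxError("empty target", column="target")
    upper = t.upper()
    if upper == "WHOLE":
        return Whole()
    if upper == "PLATE":
        return Plate()
    if "+" in t or _LED_RE.match(t):
        coords = []
        for part in t.split("+"):
            m = _LED_RE.match(part.strip())
            if not m:
                raise TargetSyntaxError(f"bad LED spec {part!r}", column="target")
            coords.append((int(m.group(1)), int(m.group(2))))
        return LedList(tuple(coords))
    m = _REC_RE.match(t)
    if m:
        return Rect(m.group(1).upper(), m.group(2).upper())
    m = _CIR_RE.match(t)
    if m:
        return Circle(
            (float(m.group(1)), float(m.group(2))), float(m.group(3))
        )
    if _WELL_RE.match(t):
        row, col = parse_well_address(upper)
        return Well(geometry.format_well_address(row, col))
    if len(upper) == 1 and upper.isalpha():
        return Row(upper)
    if upper.isdigit():
        return Column(int(upper))
    raise TargetSyntaxError(f"unrecognized target keyword {text!r}", column="target")


def serialize_target(target: TargetSpec) -> str:
    if isinstance(target, Whole):
        return "Whole"
    if isinstance(target, Plate):
        return "Plate"
    if isinstance(target, Well):
        return target.address
    if isinstance(target, Row):
        return target.letter
    if isinstance(target, Column):
        return str(target.number)
    if isinstance(target, Rect):
        return f"Rec_{target.well_a}_{target.well_b}"
    if isinstance(target, Circle):
        x, y = target.center_mm
        return f"Cir_{x:g}_{y:g}_{target.radius_mm:g}"
    if isinstance(target, LedList):
        return "+".join(f"LED_{r}_{c}" for r, c in target.coords)
    raise TargetSyntaxError(f"unknown target type {target!r}")


# ---------------------------------------------------------------------------
# Time syntax

_HMS_RE = re.compile(r"^(\d+):([0-5]?\d):([0-5]?\d)$")


def parse_time_s(text: str, line: int | None = None, column: str | None = None) -> int:
    """Integer seconds from "123" or "HH:MM:SS"; sub-second values rejected."""
    t = text.strip()
    m = _HMS_RE.match(t)
    if m:
        h, mi, s = (int(g) for g in m.groups())
        return h * 3600 + mi * 60 + s
    try:
        value = float(t)
    except ValueError:
        raise TimeFormatError(f"malformed time {text!r}", line, column) from None
    if value != int(value):
        raise TimeFormatError(
            f"sub-second time {text!r} not representable at 1 s resolution",
            line,
            column,
        )
    if value < 0:
        raise TimeFormatError(f"negative time {text!r}", line, column)
    return int(value)


def format_time_s(seconds: int) -> str:
    h, rem = divmod(seconds, 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


# ---------------------------------------------------------------------------
# csv parsing

_TRUTHY = {"1", "true", "yes", "on", "y"}
_FALSY = {"", "0", "false", "no", "off", "n"}


def _split_header(line: str) -> tuple[list[str], str]:
    """Detect the separator (',' vs ';') from the header line."""
    for sep in (",", ";"):
        fields = [f.strip().lower() for f in line.split(sep)]
        if "target" in fields:
            return fields, sep
    raise ProgramParseError(
        "header must contain a 'target' column separated by ',' or ';'", line=1
    )


def _parse_intensity(raw: str, column: str, line: int) -> int:
    if raw.strip() == "":
        return 0
    try:
        v = int(raw)
    except ValueError:
        raise IntensityRangeError(
            f"intensity {raw!r} is not an integer", line, column
        ) from None
    if not 0 <= v <= 255:
        raise IntensityRangeError(f"intensity {v} outside 0-255", line, column)
    return v


def parse_program(text: str) -> Program:
    """Parse csv text into a :class:`Program`.

    Raises a :class:`ProgramParseError` subclass naming the offending
    line and column on any violation.
    """
    meta: dict[str, str] = {}
    header: list[str] | None = None
    sep = ","
    commands: list[Command] = []

    for line_no, raw_line in enumerate(text.splitlines(), start=1):
        line = raw_line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#!"):
                body = line[2:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip().lower()] = value.strip()
            continue
        if header is None:
            header, sep = _split_header(line)
            unknown = [c for c in header if c not in DIALECT_COLUMNS]
            if unknown:
                raise ProgramParseError(
                    f"unknown column(s) {unknown}", line=line_no
                )
            missing = [c for c in _REQUIRED_COLUMNS if c not in header]
            if missing:
                raise ProgramParseError(
                    f"missing required column(s) {missing}", line=line_no
                )
            continue

        row = next(csv.reader(io.StringIO(line), delimiter=sep))
        if len(row) > len(header):
            raise ProgramParseError(
                f"{len(row)} fields but {len(header)} columns", line=line_no
            )
        fields = dict(zip(header, (f.strip() for f in row)))

        def get(col: str, default: str = "") -> str:
            return fields.get(col, default)

        target = _reraise_with_line(parse_target, get("target"), line_no)
        start = parse_time_s(get("start", "0") or "0", line_no, "start")
        dur_text = get("duration")
        if dur_text == "":
            raise ProgramParseError("missing duration", line_no, "duration")
        # catch sub-second durations before the integer-time check so the
        # user sees the firmware constraint, not a generic time error
        if not _HMS_RE.match(dur_text):
            try:
                subsecond = 0 < float(dur_text) < 1
            except ValueError:
                subsecond = False
            if subsecond:
                raise MinimumPulseError(
                    f"duration {dur_text} s below the 1 s minimum pulse",
                    line_no,
                    "duration",
                )
        duration = parse_time_s(dur_text, line_no, "duration")
        color = Color(
            _parse_intensity(get("red"), "red", line_no),
            _parse_intensity(get("green"), "green", line_no),
            _parse_intensity(get("blue"), "blue", line_no),
        )
        interval_text = get("interval")
        interval = (
            parse_time_s(interval_text, line_no, "interval") if interval_text else 0
        )
        repeats_text = get("repeats")
        if repeats_text == "":
            repeats = 1
        elif ":" in repeats_text:
            # absolute end time of the loop, end-exclusive
            end_time = parse_time_s(repeats_text, line_no, "repeats")
            if interval <= 0:
                raise ProgramParseError(
                    "loop end time given but no interval", line_no, "interval"
                )
            if end_time <= start:
                raise ProgramParseError(
                    f"loop end time {repeats_text} not after start", line_no, "repeats"
                )
            repeats = math.ceil((end_time - start) / interval)
        else:
            try:
                repeats = int(repeats_text)
            except ValueError:
                raise ProgramParseError(
                    f"repeats {repeats_text!r} is neither a count nor a time",
                    line_no,
                    "repeats",
                ) from None
        message = get("message") or None
        buzzer_text = get("buzzer").lower()
        if buzzer_text in _TRUTHY:
            buzzer = True
        elif buzzer_text in _FALSY:
            buzzer = False
        else:
            raise ProgramParseError(
                f"buzzer flag {buzzer_text!r} not understood", line_no, "buzzer"
            )
        try:
            commands.append(
                Command(
                    target=target,
                    start_s=start,
                    duration_s=duration,
                    color=color,
                    repeat_count=repeats,
                    repeat_interval_s=interval,
                    message=message,
                    buzzer=buzzer,
                )
            )
        except ProgramParseError as exc:
            raise type(exc)(str(exc), line=line_no) from None

    if header is None and commands == [] and not meta:
        if text.strip():
            raise ProgramParseError("no header line found", line=1)
    fixation = meta.get("fixation_horizon")
    return Program(
        commands=commands,
        name=meta.get("name", ""),
        plate_format=meta.get("plate", ""),
        placement_note=meta.get("placement", ""),
        fixation_horizon_s=int(fixation) if fixation else None,
    )


def _reraise_with_line(fn, arg, line_no):
    try:
        return fn(arg)
    except ProgramParseError as exc:
        raise type(exc)(str(exc), line=line_no, column=exc.column) from None
    except AddressError as exc:
        raise TargetSyntaxError(str(exc), line=line_no, column="target") from None


def serialize_program(program: Program) -> str:
    """Serialize a program to csv; round-trips through parse_program."""
    out = io.StringIO()
    if program.name:
        out.write(f"#! name: {program.name}\n")
    if program.plate_format:
        out.write(f"#! plate: {program.plate_format}\n")
    if program.placement_note:
        out.write(f"#! placement: {program.placement_note}\n")
    if program.fixation_horizon_s is not None:
        out.write(f"#! fixation_horizon: {program.fixation_horizon_s}\n")
    writer = csv.writer(out, lineterminator="\n")
    writer.writerow(DIALECT_COLUMNS)
    for cmd in program.commands:
        writer.writerow(
            [
                serialize_target(cmd.target),
                cmd.start_s,
                cmd.duration_s,
                cmd.color.red,
                cmd.color.green,
                cmd.color.blue,
                cmd.repeat_count if cmd.repeat_count > 1 else "",
                cmd.repeat_interval_s if cmd.repeat_count > 1 else "",
                cmd.message or "",
                "1" if cmd.buzzer else "",
            ]
        )
    return out.getvalue()


def program_to_json(program: Program) -> str:
    """JSON export of the parsed program for machine consumption."""
    payload = {
        "name": program.name,
        "plate_format": program.plate_format,
        "horizon_s": program.horizon_s,
        "commands": [
            {
                "target": serialize_target(c.target),
                "start_s": c.start_s,
                "duration_s": c.duration_s,
                "color": c.color.as_tuple(),
                "repeat_count": c.repeat_count,
                "repeat_interval_s": c.repeat_interval_s,
                "message": c.message,
                "buzzer": c.buzzer,
            }
            for c in program.commands
        ],
    }
    return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Whole-program validation


@dataclass(frozen=True)
class ProgramFinding:
    kind: str
    command_index: int | None
    detail: str


@dataclass
class ProgramReport:
    findings: list[ProgramFinding]
    placement_report: "geometry.PlacementReport | None" = None

    @property
    def ok(self) -> bool:
        return not self.findings and (
            self.placement_report is None or self.placement_report.ok
        )


def validate_program(
    program: Program,
    placement: Placement | None = None,
    matrix: MatrixSpec | None = None,
) -> ProgramReport:
    """Collect every violation in one report: empty or nonexistent
    targets, self-overlapping repeats, and placement findings."""
    matrix = matrix or MatrixSpec()
    findings: list[ProgramFinding] = []
    for i, cmd in enumerate(program.commands):
        if cmd.repeat_count > 1 and cmd.repeat_interval_s < cmd.duration_s:
            findings.append(
                ProgramFinding(
                    "self_overlap",
                    i,
                    f"interval {cmd.repeat_interval_s} s < duration {cmd.duration_s} s",
                )
            )
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", EmptyTargetWarning)
                leds = geometry.resolve_target(cmd.target, placement, matrix)
            if not leds:
                findings.append(
                    ProgramFinding(
                        "empty_target", i, f"{serialize_target(cmd.target)} lights no LED"
                    )
                )
        except AddressError as exc:
            findings.append(ProgramFinding("bad_address", i, str(exc)))
        except geometry.GeometryError as exc:
            findings.append(ProgramFinding("bad_target", i, str(exc)))
    placement_report = None
    if placement is not None:
        placement_report = geometry.validate_placement([placement], matrix)
    return ProgramReport(findings, placement_report)
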